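# miclens

Analysis toolkit for **Mendelian-inconsistent calls (MIC)** in parent–child
trio sequencing data, plus a synthetic trio-cohort simulator with ground
truth.

At a biallelic diploid autosomal site, each trio member's genotype is coded
0 (hom-ref), 1 (het) or 2 (hom-alt). Exactly 12 of the 27
(child, mother, father) combinations violate Mendelian transmission; eight
of them are compatible with a hemizygous deletion inherited by the child
from one parent (four maternal, four paternal). miclens:

- detects and classifies MIC from a multi-sample VCF + PED pedigree,
  applying per-call DP/GQ/AB quality filters (`mic_core`);
- annotates MIC with repeat class, offset within SINEs, alignability,
  and the normalized maternal/paternal read-depth ratio (`annotate`);
- selects high-confidence inherited-deletion candidate MIC (unique
  alignability, directional depth ratio) and clusters them into candidate
  deletion regions (`delcand`);
- groups trios by parental ancestry (k-means + silhouette rule on PC
  coordinates), aggregates MIC counts in tiling 1 Mb windows, and runs PCA
  to expose windows whose deletion-signature MIC load stratifies
  populations; writes per-population bedGraph MIC tracks (`popwindows`);
- flags candidate de novo mutations that recur as MIC across trios or look
  like inherited-deletion artifacts (`flag_denovo`);
- simulates trio cohorts with inherited hemizygous deletions
  (population-specific frequencies), genotype errors concentrated in
  repeats / low-alignability sequence / homopolymer runs, and true de novo
  SNVs, emitting VCF/PED/BED/bedGraph inputs plus a truth set
  (`synthetic_data`).

## CLI

All stages are subcommands of `miclens`:

```bash
# synthetic cohort with ground truth
miclens simulate --seed 17 --out-dir sim/

# MIC detection + classification
miclens classify --vcf sim/cohort.vcf --ped sim/cohort.ped \
    --coverage-table sim/coverage.tsv --out mic.tsv

# context annotation
miclens annotate --mic mic.tsv --repeats sim/repeats.bed \
    --alignability sim/alignability.bedGraph \
    --coverage-table sim/coverage.tsv --ped sim/cohort.ped \
    --out mic.annot.tsv --summary summary.tsv

# inherited-deletion candidate regions
miclens delcand --mic mic.annot.tsv --category maternal \
    --min-align 1.0 --max-gap 10000 --min-size 2 --out regions.bed

# ancestry grouping, window PCA, population tracks
miclens popwindows --mic mic.annot.tsv --ped sim/cohort.ped \
    --ancestry sim/ancestry_pcs.tsv --chrom-sizes sim/chrom.sizes \
    --window 1000000 --out-prefix pop_

# de novo candidate flagging
miclens flag-denovo --candidates dn.tsv --tracks pop_EUR.bedGraph \
    --tracks pop_AMR.bedGraph --regions regions.bed --out report.tsv

# everything end to end on a fresh simulation, with a JSON report
miclens run-all --seed 17 --out-dir run/
```

`run-all` accepts a YAML `PipelineConfig` (`--config pipeline.yaml`) with
per-stage thresholds and an embedded simulation configuration.

## File formats

- VCF v4.2 with FORMAT `GT,DP,GQ,AD`; PED with father-before-mother column
  order; repeats as BED6+class or RepeatMasker-track TSV; alignability as
  bedGraph or fixedStep wig; per-population MIC tracks as bedGraph
  (chrom, pos−1, pos, number of trios with an MIC at the position).
- VCF positions are 1-based; all BED/bedGraph intervals 0-based half-open.
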