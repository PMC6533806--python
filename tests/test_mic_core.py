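"""Unit and property tests for trio genotype classification and filtering."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from miclens.mic_core import (
    CallMetrics,
    DeletionCategory,
    FilterConfig,
    GenotypeCode,
    SIGNATURES,
    Trio,
    TrioGenotypeTriple,
    apply_quality_filters,
    classify_signature,
    classify_variant,
    deletion_compatible_set,
    detect_mic,
    mendelian_consistent,
    read_ped,
    write_mic_tsv,
)
from tests.conftest import gt_field, write_toy_vcf


# ---------------------------------------------------------------------------
# independent oracles

def oracle_consistent(child: int, mother: int, father: int) -> bool:
    """Brute-force transmission enumeration: a parent coded 0 holds alleles
    (0,0), coded 1 holds (0,1), coded 2 holds (1,1); the child receives one
    allele from each parent."""
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    return any(
        a + b == child
        for a in alleles[mother]
        for b in alleles[father]
    )


def oracle_deletion_scenarios() -> dict[str, set[tuple[int, int, int]]]:
    """Enumerate every single-parent hemizygous-deletion scenario and keep the
    Mendelian-inconsistent called triples.

    A hemizygous sample is called homozygous for its remaining allele.  The
    child inherits the deleted haplotype, so it is hemizygous for the allele
    transmitted by the other parent.
    """
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    out: dict[str, set[tuple[int, int, int]]] = {"maternal": set(), "paternal": set()}
    for del_parent in ("maternal", "paternal"):
        for remaining in (0, 1):  # allele on the deleted parent's other haplotype
            for other_g in (0, 1, 2):
                for transmitted in alleles[other_g]:
                    del_parent_call = 2 * remaining
                    child_call = 2 * transmitted  # hemizygous, called homozygous
                    if del_parent == "maternal":
                        triple = (child_call, del_parent_call, other_g)
                    else:
                        triple = (child_call, other_g, del_parent_call)
                    if not oracle_consistent(*triple):
                        out[del_parent].add(triple)
    return out


ALL_TRIPLES = list(itertools.product((0, 1, 2), repeat=3))


# ---------------------------------------------------------------------------
# classifier vs oracle

def test_classifier_agrees_with_oracle_on_all_27():
    for triple in ALL_TRIPLES:
        assert mendelian_consistent(TrioGenotypeTriple(*triple)) == oracle_consistent(
            *triple
        ), triple


def test_exactly_12_inconsistent():
    inconsistent = [t for t in ALL_TRIPLES if not oracle_consistent(*t)]
    assert len(inconsistent) == 12
    assert {TrioGenotypeTriple(*t) for t in inconsistent} == set(SIGNATURES)


@pytest.mark.parametrize(
    "triple, ordinal",
    [
        ((0, 2, 0), 1), ((0, 2, 1), 2), ((2, 0, 1), 3), ((2, 0, 2), 4),
        ((0, 2, 2), 5), ((1, 0, 0), 6), ((1, 2, 2), 7), ((2, 0, 0), 8),
        ((0, 0, 2), 9), ((0, 1, 2), 10), ((2, 1, 0), 11), ((2, 2, 0), 12),
    ],
)
def test_signature_ordinals(triple, ordinal):
    sig = classify_signature(TrioGenotypeTriple(*triple))
    assert sig is not None and sig.ordinal == ordinal


@pytest.mark.parametrize(
    "triple, category",
    [
        ((0, 2, 1), DeletionCategory.MATERNAL_DEL),
        ((0, 1, 2), DeletionCategory.PATERNAL_DEL),
        ((2, 0, 0), DeletionCategory.NONE),
        ((1, 0, 0), DeletionCategory.NONE),
    ],
)
def test_deletion_categories(triple, category):
    sig = classify_signature(TrioGenotypeTriple(*triple))
    assert sig.deletion_category is category


def test_consistent_returns_none():
    for triple in [(0, 0, 0), (1, 1, 1), (1, 0, 1), (2, 1, 1)]:
        assert classify_signature(TrioGenotypeTriple(*triple)) is None


def test_missing_member_rejected():
    with pytest.raises(ValueError):
        mendelian_consistent(TrioGenotypeTriple(GenotypeCode.MISSING, 0, 0))
    with pytest.raises(ValueError):
        classify_signature(TrioGenotypeTriple(0, -1, 0))


def test_deletion_compatible_set_matches_scenario_oracle():
    scenarios = oracle_deletion_scenarios()
    assert scenarios["maternal"] == {(0, 2, 0), (0, 2, 1), (2, 0, 1), (2, 0, 2)}
    assert scenarios["paternal"] == {(0, 0, 2), (0, 1, 2), (2, 1, 0), (2, 2, 0)}
    delset = deletion_compatible_set()
    assert len(delset) == 8
    maternal = {tuple(s.triple) for s in delset if s.deletion_category is DeletionCategory.MATERNAL_DEL}
    paternal = {tuple(s.triple) for s in delset if s.deletion_category is DeletionCategory.PATERNAL_DEL}
    assert maternal == scenarios["maternal"]
    assert paternal == scenarios["paternal"]


def test_category_partition_4_4_4():
    cats = [s.deletion_category for s in SIGNATURES.values()]
    assert cats.count(DeletionCategory.MATERNAL_DEL) == 4
    assert cats.count(DeletionCategory.NONE) == 4
    assert cats.count(DeletionCategory.PATERNAL_DEL) == 4


def test_parent_swap_symmetry():
    """Swapping mother and father maps maternal signatures onto paternal ones
    and fixes the non-deletion set setwise."""
    for sig in SIGNATURES.values():
        c, m, f = sig.triple
        swapped = classify_signature(TrioGenotypeTriple(c, f, m))
        assert swapped is not None
        pairs = {
            DeletionCategory.MATERNAL_DEL: DeletionCategory.PATERNAL_DEL,
            DeletionCategory.PATERNAL_DEL: DeletionCategory.MATERNAL_DEL,
            DeletionCategory.NONE: DeletionCategory.NONE,
        }
        assert swapped.deletion_category is pairs[sig.deletion_category]


# ---------------------------------------------------------------------------
# variant classification

@pytest.mark.parametrize(
    "ref, alt, var_class, length",
    [("A", "G", "SNV", 0), ("A", "AT", "INSERTION", 1), ("ATT", "A", "DELETION", 2)],
)
def test_classify_variant(ref, alt, var_class, length):
    vc, n = classify_variant(ref, alt)
    assert vc.value == var_class and n == length


def test_classify_variant_symbolic_rejected():
    with pytest.raises(ValueError):
        classify_variant("A", "<DEL>")
    with pytest.raises(ValueError):
        classify_variant("A", "A[chr2:100[")


# ---------------------------------------------------------------------------
# quality filters

def _metrics(dp=40, gq=99, ad=(20, 20)):
    return CallMetrics(dp=dp, gq=gq, ad_ref=ad[0], ad_alt=ad[1])


def test_filter_boundaries_inclusive():
    ok, reasons = apply_quality_filters(_metrics(dp=10, gq=30, ad=(10, 0)), 0, 40.0)
    assert ok and reasons == []


def test_filter_dp_below_boundary():
    ok, reasons = apply_quality_filters(_metrics(dp=9, gq=99, ad=(9, 0)), 0, 40.0)
    assert not ok and reasons == ["DP"]


def test_ab_filter_only_on_hets():
    ok, _ = apply_quality_filters(_metrics(dp=40, gq=99, ad=(4, 36)), 2, 40.0)
    assert ok  # skewed AB on a hom-alt call passes
    ok, reasons = apply_quality_filters(_metrics(dp=40, gq=99, ad=(36, 4)), 1, 40.0)
    assert not ok and reasons == ["AB"]


def test_ab_boundary_inclusive():
    ok, _ = apply_quality_filters(_metrics(dp=40, gq=99, ad=(30, 10)), 1, 40.0)
    assert ok  # AB exactly 0.25


def test_undefined_ab_on_het_fails():
    ok, reasons = apply_quality_filters(_metrics(dp=40, gq=99, ad=(0, 0)), 1, 40.0)
    assert not ok and "AB undefined" in reasons


def test_nonpositive_coverage_rejected():
    with pytest.raises(ValueError):
        apply_quality_filters(_metrics(), 0, 0.0)


@given(
    dp=st.integers(0, 100),
    gq=st.integers(0, 99),
    ad_alt=st.integers(0, 100),
    genotype=st.sampled_from([0, 1, 2]),
    dp_frac=st.floats(0.0, 1.0),
    gq_min=st.integers(0, 99),
    ab_min=st.floats(0.0, 1.0),
    bump=st.floats(0.0, 0.5),
)
def test_filter_monotone_in_thresholds(dp, gq, ad_alt, genotype, dp_frac, gq_min, ab_min, bump):
    """Raising any threshold never turns a failing call into a passing one."""
    m = CallMetrics(dp=dp, gq=gq, ad_ref=max(dp - ad_alt, 0), ad_alt=min(ad_alt, dp))
    lo = FilterConfig(dp_fraction=dp_frac, gq_min=gq_min, ab_min=ab_min)
    hi = FilterConfig(
        dp_fraction=min(dp_frac + bump, 1.0),
        gq_min=min(gq_min + int(bump * 20), 99),
        ab_min=min(ab_min + bump, 1.0),
    )
    ok_lo, _ = apply_quality_filters(m, genotype, 40.0, lo)
    ok_hi, _ = apply_quality_filters(m, genotype, 40.0, hi)
    assert ok_hi <= ok_lo


# ---------------------------------------------------------------------------
# detection on toy VCFs

SAMPLES = ["c1", "m1", "f1", "c2", "m2", "f2", "c3", "m3", "f3"]


def _toy_ped(tmp_path):
    ped = tmp_path / "trios.ped"
    lines = []
    for i in (1, 2, 3):
        lines.append(f"fam{i}\tf{i}\t0\t0\t1\t0")
        lines.append(f"fam{i}\tm{i}\t0\t0\t2\t0")
        lines.append(f"fam{i}\tc{i}\tf{i}\tm{i}\t0\t0")
    ped.write_text("\n".join(lines) + "\n")
    return ped


COVERAGE = {s: 40.0 for s in SAMPLES}


def test_detect_single_violation(tmp_path):
    gts = ["0/1", "0/0", "0/0", "0/0", "0/1", "0/0", "1/1", "0/1", "1/1"]
    row = "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP:GQ:AD\t" + "\t".join(
        gt_field(g) for g in gts
    )
    vcf = write_toy_vcf(tmp_path / "t.vcf", SAMPLES, [row])
    trios = read_ped(_toy_ped(tmp_path))
    recs = list(detect_mic(vcf, trios, FilterConfig(), COVERAGE))
    assert len(recs) == 1
    assert recs[0].trio_id == "c1"
    assert recs[0].signature.ordinal == 6  # (1,0,0)


def test_detect_signature_one_passes_filters(tmp_path):
    gts = ["0/0", "1/1", "0/0"] + ["0/0"] * 6
    row = "chr1\t500\t.\tA\tG\t.\tPASS\t.\tGT:DP:GQ:AD\t" + "\t".join(
        gt_field(g) for g in gts
    )
    vcf = write_toy_vcf(tmp_path / "t.vcf", SAMPLES, [row])
    trios = read_ped(_toy_ped(tmp_path))
    recs = list(detect_mic(vcf, trios, FilterConfig(), COVERAGE))
    assert len(recs) == 1
    assert recs[0].signature.ordinal == 1
    assert recs[0].passed_filters


def test_detect_skips_non_autosome_missing_and_multiallelic(tmp_path):
    mic_gts = "\t".join(gt_field(g) for g in ["0/1", "0/0", "0/0"] + ["0/0"] * 6)
    missing = "\t".join(
        gt_field(g) if g else "./.:.:.:." for g in ["0/1", "", "0/0"] + ["0/0"] * 6
    )
    rows = [
        f"chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP:GQ:AD\t{mic_gts}",
        f"chrX\t200\t.\tA\tG\t.\tPASS\t.\tGT:DP:GQ:AD\t{mic_gts}",  # non-autosome
        f"chr1\t300\t.\tA\tG,T\t.\tPASS\t.\tGT:DP:GQ:AD\t" + "\t".join(
            f"{g}:40:99:40,0,0" for g in ["0/1", "0/0", "0/0"] + ["0/0"] * 6
        ),  # multi-allelic
        f"chr1\t400\t.\tA\tG\t.\tPASS\t.\tGT:DP:GQ:AD\t{missing}",  # missing mother
    ]
    vcf = write_toy_vcf(tmp_path / "t.vcf", SAMPLES, rows)
    trios = read_ped(_toy_ped(tmp_path))
    stats: dict = {}
    recs = list(detect_mic(vcf, trios, FilterConfig(), COVERAGE, stats=stats))
    assert len(recs) == 1
    assert stats["non_autosome"] == 1
    assert stats["multiallelic"] == 1
    assert stats["sites"] == 4


def test_detect_phased_genotypes_unphased(tmp_path):
    gts = "\t".join(gt_field(g) for g in ["0|1", "0|0", "0|0"] + ["0/0"] * 6)
    row = f"chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP:GQ:AD\t{gts}"
    vcf = write_toy_vcf(tmp_path / "t.vcf", SAMPLES, [row])
    trios = read_ped(_toy_ped(tmp_path))
    recs = list(detect_mic(vcf, trios, FilterConfig(), COVERAGE))
    assert len(recs) == 1 and recs[0].signature.ordinal == 6


def test_detect_missing_ped_sample_hard_error(tmp_path):
    row = "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP:GQ:AD\t" + "\t".join(
        [gt_field("0/0")] * 9
    )
    vcf = write_toy_vcf(tmp_path / "t.vcf", SAMPLES, [row])
    with pytest.raises(KeyError):
        list(detect_mic(vcf, [Trio("x", "nope", "m1", "f1")], FilterConfig(), COVERAGE))


def test_detect_failed_filter_record_kept_not_dropped(tmp_path):
    gts = [gt_field("0/1", dp=5, gq=20)] + [gt_field("0/0")] * 8
    row = "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP:GQ:AD\t" + "\t".join(gts)
    vcf = write_toy_vcf(tmp_path / "t.vcf", SAMPLES, [row])
    trios = read_ped(_toy_ped(tmp_path))
    recs = list(detect_mic(vcf, trios, FilterConfig(), COVERAGE))
    assert len(recs) == 1
    assert not recs[0].passed_filters
    assert any(r.startswith("child:") for r in recs[0].fail_reasons)


def test_filter_threshold_monotone_on_cohort(basic_cohort):
    cohort, paths, _, coverage = basic_cohort
    base = sum(
        r.passed_filters
        for r in detect_mic(paths["vcf"], cohort.trios, FilterConfig(), coverage)
    )
    stricter = sum(
        r.passed_filters
        for r in detect_mic(
            paths["vcf"],
            cohort.trios,
            FilterConfig(dp_fraction=0.5, gq_min=60, ab_min=0.4),
            coverage,
        )
    )
    assert stricter <= base


def test_write_mic_tsv_roundtrip(tmp_path, basic_cohort):
    from miclens.mic_core import read_mic_tsv

    cohort, paths, mic_path, coverage = basic_cohort
    df = read_mic_tsv(mic_path)
    assert (df["signature_ordinal"].between(1, 12)).all()
    assert set(df["deletion_category"]) <= {"MATERNAL_DEL", "NONE", "PATERNAL_DEL"}
    # signature string matches ordinal
    for _, row in df.head(50).iterrows():
        trip = TrioGenotypeTriple(*(int(x) for x in row["signature"].split(",")))
        assert SIGNATURES[trip].ordinal == row["signature_ordinal"]
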