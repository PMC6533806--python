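"""Detection and classification of Mendelian-inconsistent calls (MIC) in trios.

A genotype call at a biallelic diploid site is coded 0 (homozygous
reference), 1 (heterozygous) or 2 (homozygous alternate).  For an ordered
trio (child, mother, father) exactly 12 of the 27 code combinations violate
Mendelian transmission; each violating combination is a *signature* with a
fixed ordinal and a deletion category:

* ordinals 1-4 are compatible with a maternally inherited hemizygous
  deletion (the child inherited a deleted maternal haplotype, so the
  mother's and/or child's calls are hemizygous loci miscalled as
  homozygous),
* ordinals 5-8 are not explainable by a single-parent deletion,
* ordinals 9-12 mirror 1-4 for a paternally inherited deletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCode",
    "TrioGenotypeTriple",
    "DeletionCategory",
    "MicSignature",
    "VariantClass",
    "VariantSite",
    "CallMetrics",
    "FilterConfig",
    "MicRecord",
    "Trio",
    "CONSISTENT",
    "SIGNATURES",
    "mendelian_consistent",
    "classify_signature",
    "deletion_compatible_set",
    "classify_variant",
    "apply_quality_filters",
    "detect_mic",
    "read_ped",
    "compute_mean_coverage",
    "read_coverage_table",
    "write_mic_tsv",
    "read_mic_tsv",
    "MIC_TSV_COLUMNS",
]


class GenotypeCode(IntEnum):
    """Coded unphased diploid genotype; MISSING never enters the classifier."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = -1


class TrioGenotypeTriple(NamedTuple):
    """Ordered (child, mother, father) genotype codes at one site."""

    child: int
    mother: int
    father: int

    def __str__(self) -> str:  # "c,m,f" string form, robust to ordinal drift
        return f"{self.child},{self.mother},{self.father}"


class DeletionCategory(str, Enum):
    MATERNAL_DEL = "MATERNAL_DEL"
    NONE = "NONE"
    PATERNAL_DEL = "PATERNAL_DEL"


@dataclass(frozen=True)
class MicSignature:
    ordinal: int
    triple: TrioGenotypeTriple
    deletion_category: DeletionCategory

    def __str__(self) -> str:
        return str(self.triple)


#: Sentinel returned by :func:`classify_signature` for consistent triples.
CONSISTENT = None

# Fixed ordinal <-> triple map.  1-4 maternal-deletion-compatible, 5-8
# deletion-incompatible, 9-12 paternal-deletion-compatible.
_SIGNATURE_TRIPLES: Sequence[tuple[int, int, int]] = (
    (0, 2, 0), (0, 2, 1), (2, 0, 1), (2, 0, 2),
    (0, 2, 2), (1, 0, 0), (1, 2, 2), (2, 0, 0),
    (0, 0, 2), (0, 1, 2), (2, 1, 0), (2, 2, 0),
)


def _category_for_ordinal(ordinal: int) -> DeletionCategory:
    if ordinal <= 4:
        return DeletionCategory.MATERNAL_DEL
    if ordinal <= 8:
        return DeletionCategory.NONE
    return DeletionCategory.PATERNAL_DEL


#: triple -> MicSignature for the 12 inconsistent combinations.
SIGNATURES: Mapping[TrioGenotypeTriple, MicSignature] = {
    TrioGenotypeTriple(*t): MicSignature(
        ordinal=i + 1,
        triple=TrioGenotypeTriple(*t),
        deletion_category=_category_for_ordinal(i + 1),
    )
    for i, t in enumerate(_SIGNATURE_TRIPLES)
}

SIGNATURES_BY_ORDINAL: Mapping[int, MicSignature] = {
    s.ordinal: s for s in SIGNATURES.values()
}

# Alleles a parent with the given coded genotype can transmit (0=ref, 1=alt).
_TRANSMISSIBLE = {0: (0,), 1: (0, 1), 2: (1,)}


def _check_called(triple: TrioGenotypeTriple) -> None:
    for member, code in zip(("child", "mother", "father"), triple):
        if code not in (0, 1, 2):
            raise ValueError(
                f"{member} genotype {code!r} is missing or invalid; the "
                "classifier only accepts fully called triples"
            )


def mendelian_consistent(triple: TrioGenotypeTriple) -> bool:
    """True iff the child genotype can arise from one transmitted allele per parent."""
    triple = TrioGenotypeTriple(*triple)
    _check_called(triple)
    return any(
        a + b == triple.child
        for a in _TRANSMISSIBLE[triple.mother]
        for b in _TRANSMISSIBLE[triple.father]
    )


def classify_signature(triple: TrioGenotypeTriple) -> MicSignature | None:
    """Map a triple to its MicSignature, or :data:`CONSISTENT` (None)."""
    triple = TrioGenotypeTriple(*triple)
    _check_called(triple)
    sig = SIGNATURES.get(triple)
    if sig is None and not mendelian_consistent(triple):
        raise AssertionError(f"inconsistent triple {triple} missing from table")
    return sig


def deletion_compatible_set() -> frozenset[MicSignature]:
    """The 8 signatures explainable by a single-parent hemizygous deletion."""
    return frozenset(
        s
        for s in SIGNATURES.values()
        if s.deletion_category is not DeletionCategory.NONE
    )


# Vectorized lookup table: LUT[c, m, f] = signature ordinal, 0 = consistent.
_SIG_LUT = np.zeros((3, 3, 3), dtype=np.int8)
for _t, _s in SIGNATURES.items():
    _SIG_LUT[_t.child, _t.mother, _t.father] = _s.ordinal


class VariantClass(str, Enum):
    SNV = "SNV"
    INSERTION = "INSERTION"
    DELETION = "DELETION"


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    var_class: VariantClass
    indel_len: int


def classify_variant(ref: str, alt: str) -> tuple[VariantClass, int]:
    """Classify a biallelic REF/ALT pair by allele lengths.

    Raises ValueError for symbolic alleles (``<DEL>``, breakends); callers
    are expected to count and skip those sites.
    """
    if not ref or not alt:
        raise ValueError("empty allele string")
    if alt.startswith("<") or "[" in alt or "]" in alt or alt == "*":
        raise ValueError(f"symbolic alternate allele {alt!r}")
    if len(ref) == len(alt):
        if len(ref) != 1:
            # same-length MNP: treat as SNV-class with zero indel length
            return VariantClass.SNV, 0
        return VariantClass.SNV, 0
    if len(alt) > len(ref):
        return VariantClass.INSERTION, len(alt) - len(ref)
    return VariantClass.DELETION, len(ref) - len(alt)


@dataclass(frozen=True)
class CallMetrics:
    """Per-sample call-level metrics read from the VCF FORMAT fields."""

    dp: int
    gq: int
    ad_ref: int
    ad_alt: int

    @property
    def ab(self) -> float | None:
        """Alt-read fraction; None when no informative reads."""
        total = self.ad_ref + self.ad_alt
        if total <= 0:
            return None
        return self.ad_alt / total


@dataclass
class FilterConfig:
    """Quality thresholds; all inclusive (>= passes).

    ``dp_fraction`` is a fraction of the per-sample mean coverage; the AB
    threshold applies to heterozygous calls only unless
    ``apply_ab_to_het_only`` is cleared.
    """

    dp_fraction: float = 0.25
    gq_min: int = 30
    ab_min: float = 0.25
    apply_ab_to_het_only: bool = True

    def validate(self) -> None:
        if not 0 <= self.dp_fraction:
            raise ValueError("dp_fraction must be >= 0")
        if self.gq_min < 0:
            raise ValueError("gq_min must be >= 0")
        if not 0 <= self.ab_min <= 1:
            raise ValueError("ab_min must be in [0, 1]")


def apply_quality_filters(
    metrics: CallMetrics,
    genotype: int,
    sample_mean_coverage: float,
    cfg: FilterConfig | None = None,
) -> tuple[bool, list[str]]:
    """Evaluate one call against the DP/GQ/AB thresholds.

    Returns (pass, reasons); ``reasons`` lists every failed criterion.
    """
    cfg = cfg or FilterConfig()
    if sample_mean_coverage <= 0:
        raise ValueError("sample mean coverage must be positive")
    reasons: list[str] = []
    if metrics.dp < cfg.dp_fraction * sample_mean_coverage:
        reasons.append("DP")
    if metrics.gq < cfg.gq_min:
        reasons.append("GQ")
    ab_applies = (genotype == GenotypeCode.HET) or not cfg.apply_ab_to_het_only
    if ab_applies:
        ab = metrics.ab
        if ab is None:
            reasons.append("AB undefined")
        elif ab < cfg.ab_min:
            reasons.append("AB")
    return (not reasons), reasons


@dataclass
class MicRecord:
    """One Mendelian violation in one trio at one site."""

    trio_id: str
    site: VariantSite
    signature: MicSignature
    child: CallMetrics
    mother: CallMetrics
    father: CallMetrics
    passed_filters: bool
    fail_reasons: list[str] = field(default_factory=list)


class Trio(NamedTuple):
    trio_id: str
    child: str
    mother: str
    father: str


def read_ped(path: str | Path) -> list[Trio]:
    """Read a 6-column PED file and return complete trios.

    PED column order is family, individual, father, mother, sex, phenotype
    (father before mother) while all trio ordering in this package is
    (child, mother, father).  Rows whose father or mother is '0' or '.' are
    not children of a complete trio and are skipped.
    """
    trios: list[Trio] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"malformed PED line: {line!r}")
            fam, child, father, mother = parts[:4]
            if father in ("0", ".") or mother in ("0", "."):
                continue
            if child in seen:
                raise ValueError(f"duplicate child {child!r} in PED")
            if len({child, mother, father}) != 3:
                raise ValueError(f"trio for child {child!r} reuses a sample id")
            seen.add(child)
            trios.append(Trio(trio_id=child, child=child, mother=mother, father=father))
    if not trios:
        raise ValueError(f"no complete trios found in {path}")
    return trios


_AUTOSOME_NAMES = {str(i) for i in range(1, 23)}


def is_autosome(chrom: str) -> bool:
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return name in _AUTOSOME_NAMES


def _open_vcf(path: str | Path):
    from cyvcf2 import VCF

    return VCF(str(path), gts012=True)


def compute_mean_coverage(
    vcf_path: str | Path, samples: Iterable[str] | None = None
) -> dict[str, float]:
    """Mean FORMAT/DP over called autosomal sites, per sample (first pass)."""
    vcf = _open_vcf(vcf_path)
    names = list(vcf.samples)
    totals = np.zeros(len(names), dtype=np.float64)
    counts = np.zeros(len(names), dtype=np.int64)
    for v in vcf:
        if not is_autosome(v.CHROM):
            continue
        dp = v.format("DP")
        if dp is None:
            continue
        dp = dp.reshape(len(names)).astype(np.float64)
        called = v.gt_types != 3  # 3 = unknown under gts012
        ok = called & np.isfinite(dp) & (dp >= 0)
        totals[ok] += dp[ok]
        counts[ok] += 1
    vcf.close()
    means = {n: (totals[i] / counts[i] if counts[i] else 0.0) for i, n in enumerate(names)}
    if samples is not None:
        means = {s: means[s] for s in samples}
    return means


def read_coverage_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV (sample, mean coverage); a header line is tolerated."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            try:
                out[parts[0]] = float(parts[1])
            except ValueError:
                continue  # header
    if not out:
        raise ValueError(f"no coverage rows parsed from {path}")
    return out


def _metrics_from_arrays(idx, dp, gq, ad) -> CallMetrics:
    def _clean(x) -> int:
        x = int(x)
        return x if x >= 0 else 0

    return CallMetrics(
        dp=_clean(dp[idx]),
        gq=_clean(gq[idx]),
        ad_ref=_clean(ad[idx, 0]),
        ad_alt=_clean(ad[idx, 1]),
    )


def detect_mic(
    vcf_path: str | Path,
    trios: Sequence[Trio],
    cfg: FilterConfig | None = None,
    coverage: Mapping[str, float] | None = None,
    stats: dict | None = None,
) -> Iterator[MicRecord]:
    """Stream MicRecords from a multi-sample VCF.

    One record is yielded per (trio, autosomal biallelic site) whose triple
    is Mendelian-inconsistent.  Records failing quality filters in any trio
    member are yielded with ``passed_filters=False`` rather than dropped.
    Sites with a missing genotype in any trio member are skipped for that
    trio; non-autosomes, multi-allelic and symbolic sites are skipped
    entirely (counted in ``stats``).
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    if coverage is None:
        coverage = compute_mean_coverage(vcf_path)
    vcf = _open_vcf(vcf_path)
    sample_idx = {name: i for i, name in enumerate(vcf.samples)}
    for trio in trios:
        for member in trio[1:]:
            if member not in sample_idx:
                raise KeyError(f"PED sample {member!r} absent from VCF header")
            if member not in coverage or coverage[member] <= 0:
                raise ValueError(f"no positive mean coverage for sample {member!r}")
    trio_cols = np.array(
        [[sample_idx[t.child], sample_idx[t.mother], sample_idx[t.father]] for t in trios]
    )
    counters = stats if stats is not None else {}
    for key in ("sites", "non_autosome", "multiallelic", "symbolic", "evaluated", "mic"):
        counters.setdefault(key, 0)

    n_samples = len(sample_idx)
    for v in vcf:
        counters["sites"] += 1
        if not is_autosome(v.CHROM):
            counters["non_autosome"] += 1
            continue
        if len(v.ALT) != 1:
            counters["multiallelic"] += 1
            continue
        try:
            var_class, indel_len = classify_variant(v.REF, v.ALT[0])
        except ValueError:
            counters["symbolic"] += 1
            continue
        counters["evaluated"] += 1
        gts = np.asarray(v.gt_types)  # gts012: 0,1,2 codes, 3 = missing
        child_g = gts[trio_cols[:, 0]]
        mother_g = gts[trio_cols[:, 1]]
        father_g = gts[trio_cols[:, 2]]
        callable_ = (child_g < 3) & (mother_g < 3) & (father_g < 3)
        if not callable_.any():
            continue
        ordinals = np.zeros(len(trios), dtype=np.int8)
        ordinals[callable_] = _SIG_LUT[
            child_g[callable_], mother_g[callable_], father_g[callable_]
        ]
        hit = np.nonzero(ordinals)[0]
        if hit.size == 0:
            continue
        dp = v.format("DP")
        gq = v.format("GQ")
        ad = v.format("AD")
        dp = dp.reshape(n_samples) if dp is not None else np.zeros(n_samples, int)
        gq = gq.reshape(n_samples) if gq is not None else np.zeros(n_samples, int)
        if ad is None:
            ad = np.zeros((n_samples, 2), int)
        site = VariantSite(
            chrom=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alt=v.ALT[0],
            var_class=var_class,
            indel_len=indel_len,
        )
        for ti in hit:
            trio = trios[ti]
            sig = SIGNATURES_BY_ORDINAL[int(ordinals[ti])]
            members = {}
            all_reasons: list[str] = []
            for label, col, gcode in (
                ("child", trio_cols[ti, 0], child_g[ti]),
                ("mother", trio_cols[ti, 1], mother_g[ti]),
                ("father", trio_cols[ti, 2], father_g[ti]),
            ):
                m = _metrics_from_arrays(col, dp, gq, ad)
                members[label] = m
                ok, reasons = apply_quality_filters(
                    m, int(gcode), coverage[vcf.samples[col]], cfg
                )
                if not ok:
                    all_reasons.extend(f"{label}:{r}" for r in reasons)
            counters["mic"] += 1
            yield MicRecord(
                trio_id=trio.trio_id,
                site=site,
                signature=sig,
                child=members["child"],
                mother=members["mother"],
                father=members["father"],
                passed_filters=not all_reasons,
                fail_reasons=all_reasons,
            )
    vcf.close()


MIC_TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "trio_id",
    "signature_ordinal",
    "signature",
    "deletion_category",
    "var_class",
    "indel_len",
    "child_dp",
    "child_gq",
    "child_ab",
    "mother_dp",
    "mother_gq",
    "mother_ab",
    "father_dp",
    "father_gq",
    "father_ab",
    "pass",
    "fail_reasons",
]


def _fmt_ab(ab: float | None) -> str:
    return "" if ab is None else f"{ab:.6g}"


def write_mic_tsv(records: Iterable[MicRecord], path: str | Path) -> int:
    """Write MicRecords as TSV; returns the number of rows written."""
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(MIC_TSV_COLUMNS) + "\n")
        for r in records:
            row = [
                r.site.chrom,
                str(r.site.pos),
                r.site.ref,
                r.site.alt,
                r.trio_id,
                str(r.signature.ordinal),
                str(r.signature.triple),
                r.signature.deletion_category.value,
                r.site.var_class.value,
                str(r.site.indel_len),
                str(r.child.dp),
                str(r.child.gq),
                _fmt_ab(r.child.ab),
                str(r.mother.dp),
                str(r.mother.gq),
                _fmt_ab(r.mother.ab),
                str(r.father.dp),
                str(r.father.gq),
                _fmt_ab(r.father.ab),
                "1" if r.passed_filters else "0",
                ";".join(r.fail_reasons),
            ]
            fh.write("\t".join(row) + "\n")
            n += 1
    return n


def read_mic_tsv(path: str | Path):
    """Read a MIC TSV (as written by :func:`write_mic_tsv`) into a DataFrame."""
    import pandas as pd

    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "signature": str, "fail_reasons": str},
        keep_default_na=False,
        na_values=[""],
    )
    df["pass"] = df["pass"].astype(int).astype(bool)
    return df
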