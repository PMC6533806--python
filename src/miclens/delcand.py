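"""Selection and clustering of inherited-deletion candidate MIC.

High-confidence candidates are deletion-signature SNV MIC in uniquely
alignable sequence whose normalized maternal/paternal depth ratio points
the right way (below 0.5 for a maternal deletion, above 2 for a paternal
one); candidates from the same trio are then clustered into candidate
deletion regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from miclens.mic_core import DeletionCategory

MATERNAL_RATIO_BOUND = 0.5
PATERNAL_RATIO_BOUND = 2.0


@dataclass
class DeletionCandidateCriteria:
    required_category: DeletionCategory = DeletionCategory.MATERNAL_DEL
    repeat_class_filter: str | None = None
    min_alignability: float = 1.0
    ratio_bound: float | None = None  # default depends on category
    snv_only: bool = True
    require_pass: bool = True

    def __post_init__(self) -> None:
        if self.required_category is DeletionCategory.NONE:
            raise ValueError("candidate category must be maternal or paternal")
        if self.ratio_bound is None:
            self.ratio_bound = (
                MATERNAL_RATIO_BOUND
                if self.required_category is DeletionCategory.MATERNAL_DEL
                else PATERNAL_RATIO_BOUND
            )


def select_candidates(df: pd.DataFrame, criteria: DeletionCandidateCriteria) -> pd.DataFrame:
    """Filter annotated MIC rows down to deletion candidates.

    The depth-ratio bound is strict (< for maternal, > for paternal); the
    alignability bound is inclusive.  Rows with missing alignability or
    depth ratio never qualify.
    """
    mask = df["deletion_category"] == criteria.required_category.value
    if criteria.snv_only:
        mask &= df["var_class"] == "SNV"
    if criteria.require_pass and "pass" in df.columns:
        mask &= df["pass"]
    if criteria.repeat_class_filter is not None:
        mask &= df["repeat_class"] == criteria.repeat_class_filter
    mask &= df["alignability"].notna() & (df["alignability"] >= criteria.min_alignability)
    ratio = df["depth_ratio"]
    if criteria.required_category is DeletionCategory.MATERNAL_DEL:
        mask &= ratio.notna() & (ratio < criteria.ratio_bound)
    else:
        mask &= ratio.notna() & (ratio > criteria.ratio_bound)
    return df[mask].copy()


@dataclass
class DeletionRegion:
    chrom: str
    start: int  # 0-based, spanning member MIC
    end: int  # exclusive
    trio_id: str
    parent_of_origin: str  # "maternal" | "paternal"
    n_mic: int
    positions: list[int] = field(default_factory=list)  # 1-based member sites


_PARENT_LABEL = {
    DeletionCategory.MATERNAL_DEL.value: "maternal",
    DeletionCategory.PATERNAL_DEL.value: "paternal",
}


def cluster_candidates(
    df: pd.DataFrame, max_gap: int = 10_000, min_cluster_size: int = 2
) -> list[DeletionRegion]:
    """Cluster selected candidates into per-trio candidate deletion regions.

    Within each (trio, chromosome, deletion category), maximal runs of
    candidates with inter-site gap <= ``max_gap`` and at least
    ``min_cluster_size`` members become regions spanning their member MIC.
    """
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    regions: list[DeletionRegion] = []
    if df.empty:
        return regions
    for (trio_id, chrom, category), grp in df.groupby(
        ["trio_id", "chrom", "deletion_category"], sort=True
    ):
        positions = sorted(grp["pos"].astype(int))
        run: list[int] = [positions[0]]
        for pos in positions[1:]:
            if pos - run[-1] <= max_gap:
                run.append(pos)
            else:
                if len(run) >= min_cluster_size:
                    regions.append(_make_region(chrom, trio_id, category, run))
                run = [pos]
        if len(run) >= min_cluster_size:
            regions.append(_make_region(chrom, trio_id, category, run))
    regions.sort(key=lambda r: (r.chrom, r.start, r.trio_id))
    return regions


def _make_region(chrom: str, trio_id: str, category: str, run: list[int]) -> DeletionRegion:
    return DeletionRegion(
        chrom=chrom,
        start=run[0] - 1,
        end=run[-1],
        trio_id=trio_id,
        parent_of_origin=_PARENT_LABEL[category],
        n_mic=len(run),
        positions=list(run),
    )


def write_regions_bed(regions: list[DeletionRegion], path: str | Path) -> None:
    """BED6: name = trio_id:parent, score = number of member MIC."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.trio_id}:{r.parent_of_origin}"
                f"\t{r.n_mic}\t.\n"
            )


def read_regions_bed(path: str | Path) -> list[DeletionRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            trio_id, _, parent = parts[3].rpartition(":")
            regions.append(
                DeletionRegion(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    trio_id=trio_id,
                    parent_of_origin=parent,
                    n_mic=int(parts[4]),
                )
            )
    return regions
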