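"""Genomic-context and trio-level annotation of Mendelian-inconsistent calls.

Adds, per MIC row: overlapping repeat class (most specific interval wins),
offset from the start of an overlapping SINE, alignability score at the
site, the normalized maternal/paternal depth ratio, and a single-bp-indel
flag; plus per-signature summary tables.

Coordinate conventions: VCF positions are 1-based; BED and bedGraph
intervals are 0-based half-open.  :func:`pos_to_zero_based` is the single
conversion point.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REPEAT_CLASSES = (
    "SINE",
    "LINE",
    "LTR",
    "Simple_repeat",
    "Satellite",
    "Low_complexity",
    "DNA",
    "Other",
)

NO_REPEAT = "NONE"


def pos_to_zero_based(pos: int) -> int:
    """Convert a 1-based VCF position to a 0-based interval coordinate."""
    return pos - 1


def _normalize_repeat_class(raw: str) -> str:
    # RepeatMasker repClass values carry subfamily suffixes ("SINE/Alu")
    # and uncertainty marks ("LINE?").
    base = raw.split("/")[0].rstrip("?")
    return base if base in REPEAT_CLASSES else "Other"


@dataclass(frozen=True)
class RepeatInterval:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    repeat_class: str
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty repeat interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


class RepeatIndex:
    """Point-overlap queries against a (possibly nested) repeat interval set."""

    def __init__(self, intervals: Iterable[RepeatInterval]):
        by_chrom: dict[str, list[RepeatInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._starts: dict[str, list[int]] = {}
        self._ivs: dict[str, list[RepeatInterval]] = {}
        self._max_len: dict[str, int] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            self._ivs[chrom] = ivs
            self._starts[chrom] = [iv.start for iv in ivs]
            self._max_len[chrom] = max(iv.length for iv in ivs)

    def overlapping(self, chrom: str, pos0: int) -> list[RepeatInterval]:
        ivs = self._ivs.get(chrom)
        if not ivs:
            return []
        starts = self._starts[chrom]
        hi = bisect_right(starts, pos0)
        lo_bound = pos0 - self._max_len[chrom]
        out = []
        i = hi - 1
        while i >= 0 and starts[i] > lo_bound:
            if ivs[i].end > pos0:
                out.append(ivs[i])
            i -= 1
        out.reverse()
        return out

    def best(self, chrom: str, pos0: int) -> RepeatInterval | None:
        """Most specific overlap: shortest interval, ties by leftmost start."""
        hits = self.overlapping(chrom, pos0)
        if not hits:
            return None
        return min(hits, key=lambda iv: (iv.length, iv.start))


def read_repeat_bed(path: str | Path) -> RepeatIndex:
    """Read repeats from BED6+class (column 7) or a RepeatMasker-track TSV.

    The RepeatMasker dialect is recognized by a header line containing
    ``repClass``; columns genoName/genoStart/genoEnd/strand/repName/repClass
    are used.
    """
    intervals: list[RepeatInterval] = []
    with open(path) as fh:
        first = fh.readline()
        if "repClass" in first:
            cols = first.lstrip("#").split()
            idx = {c: i for i, c in enumerate(cols)}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < len(cols):
                    continue
                intervals.append(
                    RepeatInterval(
                        chrom=parts[idx["genoName"]],
                        start=int(parts[idx["genoStart"]]),
                        end=int(parts[idx["genoEnd"]]),
                        repeat_class=_normalize_repeat_class(parts[idx["repClass"]]),
                        name=parts[idx.get("repName", idx["repClass"])],
                        strand=parts[idx["strand"]] if "strand" in idx else ".",
                    )
                )
        else:
            lines = [] if not first.strip() or first.startswith(("#", "track")) else [first]
            lines.extend(fh)
            for line in lines:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t")
                if len(parts) < 7:
                    raise ValueError(
                        f"repeat BED needs >=7 columns (class in column 7): {line!r}"
                    )
                intervals.append(
                    RepeatInterval(
                        chrom=parts[0],
                        start=int(parts[1]),
                        end=int(parts[2]),
                        repeat_class=_normalize_repeat_class(parts[6]),
                        name=parts[3],
                        strand=parts[5],
                    )
                )
    if not intervals:
        raise ValueError(f"no repeat intervals parsed from {path}")
    return RepeatIndex(intervals)


class AlignabilityTrack:
    """Sorted, non-overlapping scored intervals with point lookup in [0, 1]."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, float]]):
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, score in intervals:
            by_chrom.setdefault(chrom, []).append((start, end, min(max(score, 0.0), 1.0)))
        self._starts: dict[str, list[int]] = {}
        self._rows: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            for (s1, e1, _), (s2, _, _) in zip(rows, rows[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping alignability intervals on {chrom}")
            self._rows[chrom] = rows
            self._starts[chrom] = [r[0] for r in rows]

    def score_at(self, chrom: str, pos0: int) -> float | None:
        rows = self._rows.get(chrom)
        if not rows:
            return None
        i = bisect_right(self._starts[chrom], pos0) - 1
        if i < 0:
            return None
        start, end, score = rows[i]
        return score if start <= pos0 < end else None


def read_alignability(path: str | Path) -> AlignabilityTrack:
    """Read a 4-column bedGraph or a fixedStep wiggle into a track."""
    intervals: list[tuple[str, int, int, float]] = []
    chrom = None
    step_pos = start = step = span = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                chrom = kv["chrom"]
                step_pos = int(kv["start"]) - 1  # wig fixedStep is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                continue
            if step_pos is not None and "\t" not in line and " " not in line:
                intervals.append((chrom, step_pos, step_pos + span, float(line)))
                step_pos += step
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"bad bedGraph line: {line!r}")
            intervals.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    if not intervals:
        raise ValueError(f"no alignability intervals parsed from {path}")
    return AlignabilityTrack(intervals)


def sine_offset(pos: int, sine: RepeatInterval) -> int:
    """Nucleotide offset of a 1-based position from the BED start of a SINE."""
    pos0 = pos_to_zero_based(pos)
    if not (sine.start <= pos0 < sine.end):
        raise ValueError(
            f"position {pos} (0-based {pos0}) outside SINE "
            f"{sine.chrom}:{sine.start}-{sine.end}"
        )
    return pos0 - sine.start


def depth_ratio(
    mother_dp: float, father_dp: float, maternal_mean_cov: float, paternal_mean_cov: float
) -> float | None:
    """Normalized maternal/paternal depth ratio; None when father DP is 0."""
    if maternal_mean_cov <= 0 or paternal_mean_cov <= 0:
        raise ValueError("parental mean coverage must be positive")
    if father_dp == 0:
        return None
    return (mother_dp / maternal_mean_cov) / (father_dp / paternal_mean_cov)


def annotate_records(
    df: pd.DataFrame,
    repeats: RepeatIndex | None = None,
    alignability: AlignabilityTrack | None = None,
    coverage: Mapping[str, float] | None = None,
    trios: Sequence | None = None,
) -> pd.DataFrame:
    """Attach annotation columns to a MIC DataFrame (as from ``read_mic_tsv``).

    Adds: ``repeat_class``, ``sine_offset``, ``alignability``,
    ``depth_ratio`` and ``single_bp_indel``.  ``coverage`` plus ``trios``
    (mapping trio_id to mother/father sample ids) are required for the
    depth ratio; missing inputs leave the corresponding column NaN/NONE.
    """
    df = df.copy()
    pos0 = df["pos"].astype(int) - 1

    if repeats is not None:
        classes: list[str] = []
        offsets: list[float] = []
        for chrom, p0 in zip(df["chrom"], pos0):
            iv = repeats.best(chrom, int(p0))
            if iv is None:
                classes.append(NO_REPEAT)
                offsets.append(np.nan)
            else:
                classes.append(iv.repeat_class)
                offsets.append(int(p0) - iv.start if iv.repeat_class == "SINE" else np.nan)
        df["repeat_class"] = classes
        df["sine_offset"] = offsets
    else:
        df["repeat_class"] = NO_REPEAT
        df["sine_offset"] = np.nan

    if alignability is not None:
        df["alignability"] = [
            alignability.score_at(chrom, int(p0))
            for chrom, p0 in zip(df["chrom"], pos0)
        ]
        df["alignability"] = df["alignability"].astype(float)
    else:
        df["alignability"] = np.nan

    if coverage is not None and trios is not None:
        parent_ids = {t.trio_id: (t.mother, t.father) for t in trios}
        ratios = []
        for trio_id, mdp, fdp in zip(df["trio_id"], df["mother_dp"], df["father_dp"]):
            mother, father = parent_ids[trio_id]
            r = depth_ratio(float(mdp), float(fdp), coverage[mother], coverage[father])
            ratios.append(np.nan if r is None else r)
        df["depth_ratio"] = ratios
    else:
        df["depth_ratio"] = np.nan

    df["single_bp_indel"] = (df["var_class"] != "SNV") & (df["indel_len"] == 1)
    return df


def summarize_by_signature(df: pd.DataFrame) -> pd.DataFrame:
    """Per (signature, var_class) descriptive statistics.

    Expects an annotated DataFrame; returns one row per present
    (signature_ordinal, var_class) with counts, repeat-class proportions,
    alignability and depth-ratio medians, median child AB over het-child
    records, and the single-bp-indel proportion.
    """
    if df.empty:
        return pd.DataFrame(
            columns=["signature_ordinal", "var_class", "count"]
        )
    rows = []
    for (ordinal, var_class), grp in df.groupby(
        ["signature_ordinal", "var_class"], sort=True
    ):
        row: dict = {
            "signature_ordinal": ordinal,
            "signature": grp["signature"].iloc[0],
            "deletion_category": grp["deletion_category"].iloc[0],
            "var_class": var_class,
            "count": len(grp),
        }
        props = grp["repeat_class"].value_counts(normalize=True)
        for cls in list(REPEAT_CLASSES) + [NO_REPEAT]:
            row[f"prop_{cls}"] = float(props.get(cls, 0.0))
        align = grp["alignability"].dropna()
        row["median_alignability"] = float(align.median()) if len(align) else np.nan
        row["mean_alignability"] = float(align.mean()) if len(align) else np.nan
        ratio = grp["depth_ratio"].dropna()
        row["median_depth_ratio"] = float(ratio.median()) if len(ratio) else np.nan
        # child AB restricted to het child calls (signature child code 1)
        het = grp[grp["signature"].str.startswith("1")]["child_ab"].dropna()
        row["median_child_ab"] = float(het.median()) if len(het) else np.nan
        row["prop_single_bp_indel"] = float(grp["single_bp_indel"].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_totals(df: pd.DataFrame, filtered: bool = True) -> dict:
    """Cohort-level totals: MIC count, distinct sites, singleton sites,
    mean inconsistent trios per site."""
    if filtered and "pass" in df.columns:
        df = df[df["pass"]]
    if df.empty:
        return {
            "total_mic": 0,
            "total_sites": 0,
            "sites_one_trio": 0,
            "mean_trios_per_site": 0.0,
        }
    per_site = df.groupby(["chrom", "pos"])["trio_id"].nunique()
    return {
        "total_mic": int(len(df)),
        "total_sites": int(len(per_site)),
        "sites_one_trio": int((per_site == 1).sum()),
        "mean_trios_per_site": float(per_site.mean()),
    }
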