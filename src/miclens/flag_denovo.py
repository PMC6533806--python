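"""Flag candidate de novo mutations against cohort MIC evidence.

A candidate recurring as an MIC position across multiple trios is most
plausibly a systematic calling error; a candidate inside a candidate
deletion region, or whose own trio triple is deletion-compatible, may be
an inherited-deletion artifact; repeat overlap warrants review.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from miclens.annotate import NO_REPEAT, RepeatIndex
from miclens.delcand import DeletionRegion
from miclens.mic_core import (
    DeletionCategory,
    TrioGenotypeTriple,
    classify_signature,
)

FLAG_RECURRENT = "RECURRENT_MIC"
FLAG_DELETION = "DELETION_SIGNATURE_REGION"
FLAG_REPEAT = "REPEAT_OVERLAP"

VERDICT_KEEP = "KEEP"
VERDICT_REVIEW = "REVIEW"
VERDICT_LIKELY_ERROR = "LIKELY_ERROR"


@dataclass(frozen=True)
class DenovoCandidate:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_id: str
    trio_triple: TrioGenotypeTriple | None = None


@dataclass
class FlagThresholds:
    recurrence_min: int = 2  # total MIC trios at the position => LIKELY_ERROR


@dataclass
class DenovoFlagReport:
    candidate: DenovoCandidate
    population_counts: dict[str, int]
    total_count: int
    flags: list[str] = field(default_factory=list)
    verdict: str = VERDICT_KEEP


def read_candidates(path: str | Path) -> list[DenovoCandidate]:
    """Read a candidate TSV with columns chrom, pos, ref, alt, sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cols = {c.lower(): c for c in df.columns}
    needed = ["chrom", "pos", "ref", "alt", "sample"]
    missing = [c for c in needed if c not in cols]
    if missing:
        raise ValueError(f"candidate table missing columns: {missing}")
    return [
        DenovoCandidate(
            chrom=str(row[cols["chrom"]]),
            pos=int(row[cols["pos"]]),
            ref=str(row[cols["ref"]]),
            alt=str(row[cols["alt"]]),
            sample_id=str(row[cols["sample"]]),
        )
        for _, row in df.iterrows()
    ]


class PositionTracks:
    """Per-population exact-position MIC trio counts loaded from bedGraphs."""

    def __init__(self, per_pop: Mapping[str, Mapping[tuple[str, int], int]]):
        self._per_pop = {p: dict(m) for p, m in per_pop.items()}

    @classmethod
    def from_bedgraphs(cls, paths: Mapping[str, str | Path]) -> "PositionTracks":
        per_pop = {}
        for pop, path in paths.items():
            counts: dict[tuple[str, int], int] = {}
            with open(path) as fh:
                for line in fh:
                    line = line.strip()
                    if not line or line.startswith(("#", "track", "browser")):
                        continue
                    chrom, start, end, value = line.split("\t")
                    for pos0 in range(int(start), int(end)):
                        counts[(chrom, pos0 + 1)] = counts.get((chrom, pos0 + 1), 0) + int(value)
            per_pop[pop] = counts
        return cls(per_pop)

    @property
    def populations(self) -> list[str]:
        return sorted(self._per_pop)

    def counts_at(self, chrom: str, pos: int) -> dict[str, int]:
        return {p: m.get((chrom, pos), 0) for p, m in self._per_pop.items()}


def intersect_candidates(
    candidates: Sequence[DenovoCandidate], tracks: PositionTracks
) -> list[dict[str, int]]:
    """Exact-position per-population counts (plus 'total') per candidate."""
    out = []
    for c in candidates:
        counts = tracks.counts_at(c.chrom, c.pos)
        counts["total"] = sum(counts.values())
        out.append(counts)
    return out


def _in_region(c: DenovoCandidate, regions: Sequence[DeletionRegion]) -> bool:
    pos0 = c.pos - 1
    return any(r.chrom == c.chrom and r.start <= pos0 < r.end for r in regions)


def flag(
    candidate: DenovoCandidate,
    counts: Mapping[str, int],
    regions: Sequence[DeletionRegion] = (),
    repeats: RepeatIndex | None = None,
    thresholds: FlagThresholds | None = None,
) -> DenovoFlagReport:
    """Produce flags and a deterministic verdict for one candidate.

    LIKELY_ERROR when the total MIC trio count reaches the recurrence
    threshold; REVIEW when any other flag fires; KEEP otherwise.
    """
    thresholds = thresholds or FlagThresholds()
    flags: list[str] = []
    total = int(counts.get("total", sum(v for k, v in counts.items() if k != "total")))
    if total >= thresholds.recurrence_min:
        flags.append(FLAG_RECURRENT)
    deletion_hit = _in_region(candidate, regions)
    if not deletion_hit and candidate.trio_triple is not None:
        sig = classify_signature(candidate.trio_triple)
        deletion_hit = sig is not None and sig.deletion_category is not DeletionCategory.NONE
    if deletion_hit:
        flags.append(FLAG_DELETION)
    if repeats is not None:
        best = repeats.best(candidate.chrom, candidate.pos - 1)
        if best is not None and best.repeat_class != NO_REPEAT:
            flags.append(FLAG_REPEAT)
    if FLAG_RECURRENT in flags:
        verdict = VERDICT_LIKELY_ERROR
    elif flags:
        verdict = VERDICT_REVIEW
    else:
        verdict = VERDICT_KEEP
    return DenovoFlagReport(
        candidate=candidate,
        population_counts={k: int(v) for k, v in counts.items() if k != "total"},
        total_count=total,
        flags=flags,
        verdict=verdict,
    )


def flag_candidates(
    candidates: Sequence[DenovoCandidate],
    tracks: PositionTracks,
    regions: Sequence[DeletionRegion] = (),
    repeats: RepeatIndex | None = None,
    thresholds: FlagThresholds | None = None,
) -> list[DenovoFlagReport]:
    reports = []
    for cand, counts in zip(candidates, intersect_candidates(candidates, tracks)):
        reports.append(flag(cand, counts, regions, repeats, thresholds))
    return reports


def write_report_tsv(reports: Sequence[DenovoFlagReport], path: str | Path) -> None:
    pops = sorted({p for r in reports for p in r.population_counts})
    cols = ["chrom", "pos", "ref", "alt", "sample"] + [f"n_{p}" for p in pops] + [
        "n_total",
        "flags",
        "verdict",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reports:
            c = r.candidate
            row = [c.chrom, str(c.pos), c.ref, c.alt, c.sample_id]
            row += [str(r.population_counts.get(p, 0)) for p in pops]
            row += [str(r.total_count), ";".join(r.flags), r.verdict]
            fh.write("\t".join(row) + "\n")
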