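"""Population grouping, windowed MIC count matrices, PCA and bedGraph tracks.

Trios are grouped by parental ancestry (k-means on PC coordinates with a
silhouette acceptance rule), filtered SNV MIC counts are aggregated per
trio over tiling genomic windows, and PCA over the resulting matrix
exposes windows whose deletion-signature MIC load stratifies populations.
Per-population bedGraph tracks record, at every MIC position, the number
of trios from the population carrying an MIC there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from miclens.mic_core import Trio

logger = logging.getLogger(__name__)

POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")
OTHERS = "OTHERS"

SILHOUETTE_MIN = 0.6  # strict >; below or equal means OTHERS


@dataclass(frozen=True)
class AncestryAssignment:
    sample_id: str
    cluster_label: int
    silhouette: float
    ancestry: str


def assign_ancestry(
    pc_coords: pd.DataFrame,
    reference_labels: Mapping[str, str],
    k: int = 5,
    random_state: int = 0,
) -> list[AncestryAssignment]:
    """Cluster samples on PCs 1-3 and assign ancestry by silhouette rule.

    ``pc_coords`` is indexed by sample id with (at least) three leading PC
    columns.  ``reference_labels`` gives known population labels for a
    subset of samples; each cluster takes the majority label among its
    labelled members (clusters with no labelled member become OTHERS).  A
    sample keeps its cluster's population only when its silhouette score
    is strictly greater than 0.6, otherwise it is assigned OTHERS.
    """
    if k > len(pc_coords):
        raise ValueError(f"k={k} exceeds the number of samples ({len(pc_coords)})")
    X = pc_coords.iloc[:, :3].to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
    clusters = km.fit_predict(X)
    if k == 1:
        sil = np.ones(len(X))
    else:
        sil = silhouette_samples(X, clusters)
    cluster_pop: dict[int, str] = {}
    samples = list(pc_coords.index)
    for c in range(k):
        labels = [
            reference_labels[s]
            for s, cl in zip(samples, clusters)
            if cl == c and s in reference_labels
        ]
        cluster_pop[c] = (
            pd.Series(labels).mode().iloc[0] if labels else OTHERS
        )
    out = []
    for s, c, sc in zip(samples, clusters, sil):
        ancestry = cluster_pop[int(c)] if sc > SILHOUETTE_MIN else OTHERS
        out.append(
            AncestryAssignment(
                sample_id=s, cluster_label=int(c), silhouette=float(sc), ancestry=ancestry
            )
        )
    return out


def group_trios(
    trios: Sequence[Trio], assignments: Sequence[AncestryAssignment]
) -> dict[str, str]:
    """trio_id -> population for trios whose parents share an ancestry.

    Trios with discordant (or OTHERS-vs-population) parents are excluded;
    both-OTHERS parents yield an OTHERS trio, matching the grouping that
    reports an OTHERS trio count.
    """
    by_sample = {a.sample_id: a.ancestry for a in assignments}
    grouped: dict[str, str] = {}
    n_excluded = 0
    for t in trios:
        try:
            mother, father = by_sample[t.mother], by_sample[t.father]
        except KeyError as e:
            raise KeyError(f"no ancestry assignment for parent {e.args[0]!r}") from e
        if mother == father:
            grouped[t.trio_id] = mother
        else:
            n_excluded += 1
    if n_excluded:
        logger.info("excluded %d trios with discordant parental ancestry", n_excluded)
    return grouped


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    index: int


def make_windows(
    chrom_sizes: Mapping[str, int] | Sequence[tuple[str, int]],
    window_size: int = 1_000_000,
) -> list[GenomicWindow]:
    """Tile each chromosome with fixed windows; the last one is truncated."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    items = chrom_sizes.items() if isinstance(chrom_sizes, Mapping) else chrom_sizes
    windows: list[GenomicWindow] = []
    idx = 0
    for chrom, length in items:
        if length <= 0:
            raise ValueError(f"nonpositive length for {chrom}")
        for start in range(0, length, window_size):
            windows.append(
                GenomicWindow(chrom=chrom, start=start, end=min(start + window_size, length), index=idx)
            )
            idx += 1
    return windows


def read_chrom_sizes(path: str | Path) -> list[tuple[str, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 2:
                out.append((parts[0], int(parts[1])))
    if not out:
        raise ValueError(f"no chromosome sizes parsed from {path}")
    return out


@dataclass
class WindowCountMatrix:
    """trios x windows MIC counts for one signature category."""

    counts: pd.DataFrame  # index = trio_id, columns = window index
    windows: list[GenomicWindow]
    category: str  # "deletion" | "nondeletion"


def aggregate_counts(
    df: pd.DataFrame,
    windows: list[GenomicWindow],
    category: str,
    trio_ids: Sequence[str] | None = None,
) -> WindowCountMatrix:
    """Aggregate filtered-pass SNV MIC into per-trio window counts.

    ``category`` selects deletion-signature rows ("deletion") or the
    complement ("nondeletion").  Rows on chromosomes absent from the
    window set raise.  ``trio_ids`` fixes the row universe so trios with
    zero counts keep a (zero) row.
    """
    if category not in ("deletion", "nondeletion"):
        raise ValueError("category must be 'deletion' or 'nondeletion'")
    sel = df[(df["pass"]) & (df["var_class"] == "SNV")]
    if category == "deletion":
        sel = sel[sel["deletion_category"] != "NONE"]
    else:
        sel = sel[sel["deletion_category"] == "NONE"]

    window_chroms = {w.chrom for w in windows}
    bad = set(sel["chrom"]) - window_chroms
    if bad:
        raise ValueError(f"records on chromosomes without windows: {sorted(bad)}")
    # per-chrom lookup: windows are tiling and sorted, so index by division
    by_chrom: dict[str, list[GenomicWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    wsize = {c: ws[0].end - ws[0].start for c, ws in by_chrom.items()}

    rows = list(trio_ids) if trio_ids is not None else sorted(sel["trio_id"].unique())
    mat = pd.DataFrame(
        0, index=pd.Index(rows, name="trio_id"), columns=[w.index for w in windows]
    )
    for trio_id, chrom, pos in zip(sel["trio_id"], sel["chrom"], sel["pos"]):
        ws = by_chrom[chrom]
        wi = (int(pos) - 1) // wsize[chrom]
        if wi >= len(ws):
            raise ValueError(f"position {chrom}:{pos} beyond chromosome windows")
        mat.loc[trio_id, ws[wi].index] += 1
    return WindowCountMatrix(counts=mat, windows=windows, category=category)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # index = trio_id, columns PC1..PCk
    loadings: pd.DataFrame  # index = window index, columns PC1..PCk
    explained_variance_ratio: np.ndarray


def run_pca(matrix: WindowCountMatrix, n_components: int | None = None) -> PcaResult:
    """Column-mean-centered, unscaled PCA of the window count matrix.

    Component signs are fixed deterministically: PC1 so its scores
    correlate positively with per-trio totals, the rest so each loading
    vector's largest-magnitude entry is positive.
    """
    X = matrix.counts.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 trios and 2 windows")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValueError("no variance in count matrix")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components or min(Xc.shape)
    k = min(k, len(S))
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    row_totals = X.sum(axis=1)
    for j in range(k):
        if j == 0 and np.std(row_totals) > 0:
            flip = np.corrcoef(scores[:, 0], row_totals)[0, 1] < 0
        else:
            flip = loadings[np.argmax(np.abs(loadings[:, j])), j] < 0
        if flip:
            scores[:, j] *= -1
            loadings[:, j] *= -1
    var = S**2
    cols = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.counts.index, columns=cols),
        loadings=pd.DataFrame(loadings, index=matrix.counts.columns, columns=cols),
        explained_variance_ratio=var[:k] / var.sum(),
    )


def top_windows(
    result: PcaResult, windows: list[GenomicWindow], component: int = 2, k: int = 10
) -> list[GenomicWindow]:
    """Windows ranked by |loading| on the given component (1-based)."""
    col = f"PC{component}"
    if col not in result.loadings.columns:
        raise ValueError(f"component {component} not computed")
    by_index = {w.index: w for w in windows}
    load = result.loadings[col]
    order = sorted(load.index, key=lambda wi: (-abs(load[wi]), wi))
    return [by_index[wi] for wi in order[: min(k, len(order))]]


def position_counts(df: pd.DataFrame, trio_pop: Mapping[str, str]) -> pd.DataFrame:
    """Distinct-trio MIC counts per (population, chrom, pos) for grouped trios."""
    sel = df[df["pass"]] if "pass" in df.columns else df
    sel = sel[sel["trio_id"].isin(trio_pop.keys())].copy()
    if sel.empty:
        return pd.DataFrame(columns=["population", "chrom", "pos", "n_trios"])
    sel["population"] = sel["trio_id"].map(trio_pop)
    out = (
        sel.groupby(["population", "chrom", "pos"])["trio_id"]
        .nunique()
        .reset_index(name="n_trios")
    )
    return out.sort_values(["population", "chrom", "pos"], kind="stable").reset_index(drop=True)


def write_population_tracks(
    df: pd.DataFrame,
    trio_pop: Mapping[str, str],
    out_prefix: str | Path,
    track_line: bool = False,
) -> dict[str, Path]:
    """One bedGraph per population: (chrom, pos-1, pos, trios with an MIC).

    Positions with zero count are omitted; counts are bounded by the
    population's trio count.  Returns population -> written path.
    """
    counts = position_counts(df, trio_pop)
    paths: dict[str, Path] = {}
    for pop in sorted(set(trio_pop.values())):
        sub = counts[counts["population"] == pop]
        path = Path(f"{out_prefix}{pop}.bedGraph")
        with open(path, "w") as fh:
            if track_line:
                fh.write(f'track type=bedGraph name="MIC_{pop}"\n')
            for chrom, pos, n in zip(sub["chrom"], sub["pos"], sub["n_trios"]):
                fh.write(f"{chrom}\t{int(pos) - 1}\t{int(pos)}\t{int(n)}\n")
        paths[pop] = path
    return paths
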