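"""Synthetic trio-cohort simulator with ground truth.

Generates a small pseudo-genome (repeat annotation + alignability track +
polymorphic site catalog) and a multi-population trio cohort over it with
three MIC-generating mechanisms, each recorded in a truth set:

* inherited hemizygous deletions with population-specific carrier
  frequencies — hemizygous loci are "called" homozygous for the remaining
  allele and read depth scales with copy number (Poisson at coverage x
  copies / 2),
* genotype-caller errors whose probability scales with repeat class and
  with (1 - alignability), plus 1-bp indel slippage restricted to the
  poly-T head / poly-A tail homopolymer runs of SINEs,
* true de novo SNVs as child-only heterozygotes at a configurable
  per-bp-per-generation rate.

All randomness flows from one mandatory seed; identical seeds give
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from miclens.annotate import RepeatIndex, RepeatInterval
from miclens.mic_core import Trio

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class RepeatModel:
    sine_per_mb: float = 30.0
    line_per_mb: float = 5.0
    simple_per_mb: float = 20.0
    sine_len: tuple[int, int] = (270, 330)
    line_len: tuple[int, int] = (500, 8000)
    simple_len: tuple[int, int] = (20, 200)
    homopolymer_margin: int = 20  # nt of poly-T head / poly-A tail per SINE
    sine_alignability: tuple[float, float] = (0.1, 0.5)
    simple_alignability: tuple[float, float] = (0.05, 0.4)
    line_alignability: float = 1.0


@dataclass
class ErrorModel:
    base_rate: float = 0.0  # per genotype call in unique sequence
    repeat_multipliers: dict = field(
        default_factory=lambda: {
            "SINE": 6.0,
            "Simple_repeat": 8.0,
            "LINE": 1.5,
            "NONE": 1.0,
        }
    )
    alignability_weight: float = 3.0
    homopolymer_indel_rate: float = 0.0  # per call at a slippage-prone indel site
    error_het_ab: float = 0.3  # alt-read fraction of erroneous het calls
    trio_scale_sd: float = 0.0  # lognormal sd of the per-trio error-load multiplier


@dataclass
class DeletionRegionSpec:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    frequency: dict  # population label -> parent carrier probability
    extra_site_density: float = 0.0  # additional polymorphic sites per bp inside
    parent: str = "either"  # restrict carriers: "either" | "maternal" | "paternal"


@dataclass
class SimulationConfig:
    populations: list  # [(label, n_trios), ...]
    genome: list  # [(chrom, length), ...]
    seed: int
    mean_coverage: float = 40.0
    site_density: float = 5e-4  # polymorphic SNVs per bp
    af_range: tuple[float, float] = (0.1, 0.9)
    repeats: RepeatModel = field(default_factory=RepeatModel)
    deletions: list = field(default_factory=list)  # [DeletionRegionSpec, ...]
    errors: ErrorModel = field(default_factory=ErrorModel)
    de_novo_rate: float = 1.2e-8  # per bp per generation

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not self.populations or not self.genome:
            raise ValueError("populations and genome must be non-empty")
        lengths = dict(self.genome)
        for rate in (self.de_novo_rate, self.errors.base_rate, self.errors.homopolymer_indel_rate):
            if not 0 <= rate <= 1:
                raise ValueError(f"rate {rate} outside [0, 1]")
        spans: dict[str, list[tuple[int, int]]] = {}
        for d in self.deletions:
            if d.chrom not in lengths:
                raise ValueError(f"deletion region on unknown chromosome {d.chrom!r}")
            if not (0 <= d.start < d.end <= lengths[d.chrom]):
                raise ValueError(
                    f"deletion region {d.chrom}:{d.start}-{d.end} outside the genome"
                )
            for s, e in spans.setdefault(d.chrom, []):
                if d.start < e and s < d.end:
                    raise ValueError("deletion regions must not overlap")
            spans[d.chrom].append((d.start, d.end))
            for pop, f in d.frequency.items():
                if not 0 <= f <= 1:
                    raise ValueError(f"carrier frequency {f} for {pop} outside [0, 1]")
            if d.parent not in ("either", "maternal", "paternal"):
                raise ValueError(f"invalid deletion parent restriction {d.parent!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "repeats" in d and isinstance(d["repeats"], Mapping):
            rep = dict(d["repeats"])
            for key in ("sine_len", "line_len", "simple_len", "sine_alignability", "simple_alignability"):
                if key in rep:
                    rep[key] = tuple(rep[key])
            d["repeats"] = RepeatModel(**rep)
        if "errors" in d and isinstance(d["errors"], Mapping):
            d["errors"] = ErrorModel(**dict(d["errors"]))
        if "deletions" in d:
            d["deletions"] = [
                DeletionRegionSpec(**dict(x)) if isinstance(x, Mapping) else x
                for x in d["deletions"]
            ]
        d["populations"] = [tuple(p) for p in d["populations"]]
        d["genome"] = [tuple(g) for g in d["genome"]]
        if "af_range" in d:
            d["af_range"] = tuple(d["af_range"])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GenomeTracks:
    repeats: list  # [RepeatInterval, ...]
    homopolymers: list  # [(chrom, start, end), ...] slippage-prone runs
    alignability: list  # tiling [(chrom, start, end, score), ...]
    sites: pd.DataFrame  # chrom,pos,ref,alt,af,is_indel,repeat_class,alignability,in_homopolymer


@dataclass
class TruthSet:
    deletions: list = field(default_factory=list)
    de_novos: list = field(default_factory=list)
    errors: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"deletions": self.deletions, "de_novos": self.de_novos, "errors": self.errors},
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(deletions=d["deletions"], de_novos=d["de_novos"], errors=d["errors"])


@dataclass
class CohortData:
    config: SimulationConfig
    tracks: GenomeTracks
    trios: list  # [Trio, ...]
    samples: list  # VCF column order: child, mother, father per trio
    sites: pd.DataFrame  # catalog + de novo sites, genome order
    gt: np.ndarray  # (n_samples, n_sites) int8 codes, -1 missing
    dp: np.ndarray
    gq: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    truth: TruthSet
    ancestry: pd.DataFrame  # parent sample_id, PC1-3, ref_pop


def _place_repeats(
    rng: np.random.Generator, length: int, count: int, len_range: tuple[int, int],
    occupied: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Non-overlapping placement by rejection sampling."""
    placed: list[tuple[int, int]] = []
    attempts = 0
    while len(placed) < count and attempts < count * 200:
        attempts += 1
        size = int(rng.integers(len_range[0], len_range[1] + 1))
        if size >= length:
            continue
        start = int(rng.integers(0, length - size))
        end = start + size
        if any(start < e and s < end for s, e in occupied):
            continue
        occupied.append((start, end))
        placed.append((start, end))
    return placed


def simulate_genome_tracks(config: SimulationConfig, rng: np.random.Generator) -> GenomeTracks:
    config.validate()
    rep = config.repeats
    repeats: list[RepeatInterval] = []
    homopolymers: list[tuple[str, int, int]] = []
    alignability: list[tuple[str, int, int, float]] = []
    site_rows: list[tuple] = []

    for chrom, length in config.genome:
        mb = length / 1e6
        occupied: list[tuple[int, int]] = []
        lines = _place_repeats(rng, length, round(rep.line_per_mb * mb), rep.line_len, occupied)
        sines = _place_repeats(rng, length, round(rep.sine_per_mb * mb), rep.sine_len, occupied)
        simples = _place_repeats(rng, length, round(rep.simple_per_mb * mb), rep.simple_len, occupied)

        scored: list[tuple[int, int, float]] = []
        for i, (s, e) in enumerate(sorted(lines)):
            repeats.append(RepeatInterval(chrom, s, e, "LINE", f"L1_{chrom}_{i}", "+"))
            scored.append((s, e, rep.line_alignability))
        for i, (s, e) in enumerate(sorted(sines)):
            repeats.append(RepeatInterval(chrom, s, e, "SINE", f"Alu_{chrom}_{i}", "+"))
            margin = min(rep.homopolymer_margin, (e - s) // 2)
            homopolymers.append((chrom, s, s + margin))  # poly-T head
            homopolymers.append((chrom, e - margin, e))  # poly-A tail
            scored.append((s, e, float(rng.uniform(*rep.sine_alignability))))
        for i, (s, e) in enumerate(sorted(simples)):
            repeats.append(
                RepeatInterval(chrom, s, e, "Simple_repeat", f"(A)n_{chrom}_{i}", "+")
            )
            scored.append((s, e, float(rng.uniform(*rep.simple_alignability))))

        # tiling alignability: background 1.0 outside scored repeats
        prev = 0
        for s, e, score in sorted(scored):
            if s > prev:
                alignability.append((chrom, prev, s, 1.0))
            alignability.append((chrom, s, e, score))
            prev = e
        if prev < length:
            alignability.append((chrom, prev, length, 1.0))

        # polymorphic SNV catalog; deletion regions may add extra sites
        n_sites = round(config.site_density * length)
        extra: list[int] = []
        for d in config.deletions:
            if d.chrom == chrom and d.extra_site_density > 0:
                n_extra = round(d.extra_site_density * (d.end - d.start))
                extra.extend(
                    int(p) + d.start
                    for p in rng.choice(d.end - d.start, size=min(n_extra, d.end - d.start), replace=False)
                )
        base_positions = rng.choice(length, size=min(n_sites, length), replace=False)
        positions = sorted({int(p) for p in base_positions} | set(extra))
        for p in positions:
            ref_i = int(rng.integers(0, 4))
            alt_i = (ref_i + 1 + int(rng.integers(0, 3))) % 4
            af = float(rng.uniform(*config.af_range))
            site_rows.append((chrom, p + 1, _BASES[ref_i], _BASES[alt_i], af, False))

        # slippage-prone 1-bp insertion sites inside each SINE homopolymer run
        for s, e in sorted(sines):
            margin = min(rep.homopolymer_margin, (e - s) // 2)
            head = s + int(rng.integers(0, margin))
            tail = e - margin + int(rng.integers(0, margin))
            for p, base in ((head, "T"), (tail, "A")):
                site_rows.append((chrom, p + 1, base, base * 2, 0.0, True))

    sites = pd.DataFrame(
        site_rows, columns=["chrom", "pos", "ref", "alt", "af", "is_indel"]
    )
    chrom_order = {c: i for i, (c, _) in enumerate(config.genome)}
    sites["chrom_idx"] = sites["chrom"].map(chrom_order)
    sites = (
        sites.drop_duplicates(subset=["chrom", "pos"], keep="first")
        .sort_values(["chrom_idx", "pos"], kind="stable")
        .reset_index(drop=True)
    )

    # annotate catalog with repeat class / alignability / homopolymer flags
    rindex = RepeatIndex(repeats) if repeats else None
    from miclens.annotate import NO_REPEAT, AlignabilityTrack

    atrack = AlignabilityTrack(alignability)
    hp_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in homopolymers:
        hp_by_chrom.setdefault(chrom, []).append((s, e))
    classes, scores, in_hp = [], [], []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        p0 = int(pos) - 1
        best = rindex.best(chrom, p0) if rindex else None
        classes.append(best.repeat_class if best else NO_REPEAT)
        scores.append(atrack.score_at(chrom, p0))
        in_hp.append(any(s <= p0 < e for s, e in hp_by_chrom.get(chrom, ())))
    sites["repeat_class"] = classes
    sites["alignability"] = scores
    sites["in_homopolymer"] = in_hp
    return GenomeTracks(
        repeats=repeats, homopolymers=homopolymers, alignability=alignability, sites=sites
    )


def _error_probability(config: SimulationConfig, sites: pd.DataFrame) -> np.ndarray:
    """Per-call flip probability per site under the error model."""
    em = config.errors
    mult = sites["repeat_class"].map(
        lambda c: em.repeat_multipliers.get(c, 1.0)
    ).to_numpy(dtype=float)
    align = sites["alignability"].to_numpy(dtype=float)
    p = em.base_rate * mult * (1.0 + em.alignability_weight * (1.0 - align))
    p = np.where(sites["is_indel"].to_numpy(), 0.0, p)
    slip = np.where(
        sites["is_indel"].to_numpy() & sites["in_homopolymer"].to_numpy(),
        em.homopolymer_indel_rate,
        0.0,
    )
    return np.clip(p + slip, 0.0, 0.5)


def simulate_trios(
    config: SimulationConfig, tracks: GenomeTracks, rng: np.random.Generator
) -> CohortData:
    config.validate()
    catalog = tracks.sites
    chrom_order = {c: i for i, (c, _) in enumerate(config.genome)}
    genome_len = sum(length for _, length in config.genome)
    chrom_offsets = np.cumsum([0] + [length for _, length in config.genome])

    trio_pops: list[str] = []
    trios: list[Trio] = []
    for pop, n in config.populations:
        for i in range(n):
            base = f"{pop}{i:04d}"
            trios.append(Trio(trio_id=base, child=f"{base}C", mother=f"{base}M", father=f"{base}F"))
            trio_pops.append(pop)
    samples = [s for t in trios for s in (t.child, t.mother, t.father)]
    n_trios = len(trios)

    # draw all de novo events up front so the global site list is fixed
    existing = {(c, int(p)) for c, p in zip(catalog["chrom"], catalog["pos"])}
    denovo_rows: list[tuple] = []
    truth = TruthSet()
    for ti, trio in enumerate(trios):
        n_dn = int(rng.poisson(config.de_novo_rate * genome_len))
        for _ in range(n_dn):
            while True:
                g = int(rng.integers(0, genome_len))
                ci = int(np.searchsorted(chrom_offsets, g, side="right") - 1)
                chrom = config.genome[ci][0]
                pos = g - int(chrom_offsets[ci]) + 1
                if (chrom, pos) not in existing:
                    existing.add((chrom, pos))
                    break
            ref_i = int(rng.integers(0, 4))
            alt_i = (ref_i + 1 + int(rng.integers(0, 3))) % 4
            denovo_rows.append(
                (chrom, pos, _BASES[ref_i], _BASES[alt_i], 0.0, False, ti)
            )
            truth.de_novos.append(
                {
                    "trio_id": trio.trio_id,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": str(_BASES[ref_i]),
                    "alt": str(_BASES[alt_i]),
                }
            )

    sites = catalog.copy()
    sites["denovo_owner"] = -1
    if denovo_rows:
        dn = pd.DataFrame(
            denovo_rows,
            columns=["chrom", "pos", "ref", "alt", "af", "is_indel", "denovo_owner"],
        )
        dn["chrom_idx"] = dn["chrom"].map(chrom_order)
        dn["repeat_class"] = "NONE"
        dn["alignability"] = 1.0
        dn["in_homopolymer"] = False
        sites = pd.concat([sites, dn], ignore_index=True)
    sites = sites.sort_values(["chrom_idx", "pos"], kind="stable").reset_index(drop=True)

    n_sites = len(sites)
    af = sites["af"].to_numpy(dtype=float)
    site_chrom_idx = sites["chrom_idx"].to_numpy(dtype=int)
    pos0 = sites["pos"].to_numpy(dtype=int) - 1
    p_err = _error_probability(config, sites)
    denovo_owner = sites["denovo_owner"].to_numpy(dtype=int)

    # per-site deletion-region id per config spec (-1 = none)
    region_id = np.full(n_sites, -1, dtype=int)
    for ri, d in enumerate(config.deletions):
        mask = (
            (site_chrom_idx == chrom_order[d.chrom]) & (pos0 >= d.start) & (pos0 < d.end)
        )
        region_id[mask] = ri

    gt = np.full((len(samples), n_sites), -1, dtype=np.int8)
    dp = np.zeros((len(samples), n_sites), dtype=np.int32)
    gq = np.zeros((len(samples), n_sites), dtype=np.int16)
    ad_ref = np.zeros((len(samples), n_sites), dtype=np.int32)
    ad_alt = np.zeros((len(samples), n_sites), dtype=np.int32)

    n_chroms = len(config.genome)
    cov = config.mean_coverage
    em = config.errors

    for ti, trio in enumerate(trios):
        pop = trio_pops[ti]
        # deletion carrier status per parent per region
        m_del_hap = np.full(len(config.deletions), -1, dtype=int)
        f_del_hap = np.full(len(config.deletions), -1, dtype=int)
        for ri, d in enumerate(config.deletions):
            freq = float(d.frequency.get(pop, 0.0))
            if d.parent in ("either", "maternal") and rng.random() < freq:
                m_del_hap[ri] = int(rng.integers(0, 2))
            if d.parent in ("either", "paternal") and rng.random() < freq:
                f_del_hap[ri] = int(rng.integers(0, 2))

        # heterogeneous per-trio error load (library/run quality variation)
        trio_scale = float(np.exp(rng.normal(0.0, em.trio_scale_sd))) if em.trio_scale_sd > 0 else 1.0
        p_err_trio = np.clip(p_err * trio_scale, 0.0, 0.5)

        tm = rng.integers(0, 2, size=n_chroms)  # transmitted maternal hap per chrom
        tf = rng.integers(0, 2, size=n_chroms)

        M = rng.random((2, n_sites)) < af  # maternal haplotype alleles
        F = rng.random((2, n_sites)) < af

        # per-site deleted-haplotype index for each parent (-1 = diploid)
        if config.deletions:
            m_hap_site = np.where(region_id >= 0, m_del_hap[np.clip(region_id, 0, None)], -1)
            f_hap_site = np.where(region_id >= 0, f_del_hap[np.clip(region_id, 0, None)], -1)
        else:
            m_hap_site = np.full(n_sites, -1, dtype=int)
            f_hap_site = np.full(n_sites, -1, dtype=int)

        tm_site = tm[site_chrom_idx]
        tf_site = tf[site_chrom_idx]
        child_m_del = (m_hap_site >= 0) & (tm_site == m_hap_site)
        child_f_del = (f_hap_site >= 0) & (tf_site == f_hap_site)

        a_m = np.where(tm_site == 0, M[0], M[1]).astype(np.int8)
        a_f = np.where(tf_site == 0, F[0], F[1]).astype(np.int8)

        def _parent_call(haps: np.ndarray, hap_site: np.ndarray):
            copies = np.where(hap_site >= 0, 1, 2).astype(np.int8)
            diploid = haps[0].astype(np.int8) + haps[1].astype(np.int8)
            remaining = np.where(hap_site == 0, haps[1], haps[0]).astype(np.int8)
            g = np.where(hap_site >= 0, 2 * remaining, diploid)
            return g.astype(np.int8), copies

        g_m, copies_m = _parent_call(M, m_hap_site)
        g_f, copies_f = _parent_call(F, f_hap_site)

        copies_c = (2 - child_m_del.astype(np.int8) - child_f_del.astype(np.int8))
        g_c = np.where(
            copies_c == 2,
            a_m + a_f,
            np.where(copies_c == 1, 2 * np.where(child_m_del, a_f, a_m), -1),
        ).astype(np.int8)

        # true de novo: child-only het at owned diploid sites
        own = (denovo_owner == ti) & (copies_c == 2)
        g_c[own] = 1

        # record deletion truth (carrier + transmission) for this trio
        for ri, d in enumerate(config.deletions):
            for parent, hap in (("maternal", m_del_hap[ri]), ("paternal", f_del_hap[ri])):
                if hap < 0:
                    continue
                t_site = tm if parent == "maternal" else tf
                truth.deletions.append(
                    {
                        "trio_id": trio.trio_id,
                        "chrom": d.chrom,
                        "start": d.start,
                        "end": d.end,
                        "parent": parent,
                        "haplotype": int(hap),
                        "transmitted": bool(t_site[chrom_order[d.chrom]] == hap),
                    }
                )

        for member, sample, g, copies in (
            ("child", trio.child, g_c, copies_c),
            ("mother", trio.mother, g_m, copies_m),
            ("father", trio.father, g_f, copies_f),
        ):
            row = ti * 3 + ("child", "mother", "father").index(member)
            called = g >= 0
            err = (rng.random(n_sites) < p_err_trio) & called
            g_called = g.copy()
            if err.any():
                k = int(err.sum())
                shift = 1 + rng.integers(0, 2, size=k).astype(np.int8)
                g_called[err] = (g[err] + shift) % 3
                for idx in np.nonzero(err)[0]:
                    truth.errors.append(
                        {
                            "sample": sample,
                            "chrom": sites["chrom"].iat[int(idx)],
                            "pos": int(sites["pos"].iat[int(idx)]),
                            "true_code": int(g[idx]),
                            "called_code": int(g_called[idx]),
                            "kind": "homopolymer_indel"
                            if bool(sites["is_indel"].iat[int(idx)])
                            else "genotype_flip",
                        }
                    )

            lam = cov * copies.astype(float) / 2.0
            lam[~called] = 0.0
            dpv = rng.poisson(lam).astype(np.int32)
            altv = np.where(g_called == 2, dpv, 0).astype(np.int32)
            het = called & (g_called == 1) & (dpv > 0)
            if het.any():
                p_alt = np.where(err[het], em.error_het_ab, 0.5)
                altv[het] = rng.binomial(dpv[het], p_alt)
            gqv = np.where(called, 99, 0).astype(np.int16)
            if err.any():
                gqv[err] = rng.integers(10, 51, size=int(err.sum())).astype(np.int16)

            gt[row] = np.where(called, g_called, -1)
            dp[row] = dpv
            gq[row] = gqv
            ad_alt[row] = altv
            ad_ref[row] = dpv - altv

    ancestry = _simulate_ancestry_pcs(config, trios, trio_pops, rng)
    return CohortData(
        config=config,
        tracks=tracks,
        trios=trios,
        samples=samples,
        sites=sites,
        gt=gt,
        dp=dp,
        gq=gq,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        truth=truth,
        ancestry=ancestry,
    )


def _simulate_ancestry_pcs(
    config: SimulationConfig, trios: Sequence[Trio], trio_pops: Sequence[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Well-separated Gaussian blobs per population on PCs 1-3 (parents only)."""
    pops = [p for p, _ in config.populations]
    centers = {
        pop: np.array([12.0 * i, 6.0 * ((i % 2) * 2 - 1), 4.0 * i]) for i, pop in enumerate(pops)
    }
    rows = []
    for trio, pop in zip(trios, trio_pops):
        for parent in (trio.mother, trio.father):
            coords = centers[pop] + rng.normal(0.0, 0.6, size=3)
            rows.append((parent, coords[0], coords[1], coords[2], pop))
    return pd.DataFrame(rows, columns=["sample_id", "PC1", "PC2", "PC3", "ref_pop"])


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Run both simulation stages with seed-derived, stage-local streams."""
    config.validate()
    rng_tracks = np.random.default_rng([config.seed, 0])
    rng_trios = np.random.default_rng([config.seed, 1])
    tracks = simulate_genome_tracks(config, rng_tracks)
    return simulate_trios(config, tracks, rng_trios)


_GT_STR = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(cohort: CohortData, path: str | Path) -> None:
    """Plain-text VCF v4.2 with GT:DP:GQ:AD, samples child,mother,father per trio."""
    sites = cohort.sites
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=miclens-simulate\n")
        for chrom, length in cohort.config.genome:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        chroms = sites["chrom"].to_numpy()
        poss = sites["pos"].to_numpy()
        refs = sites["ref"].to_numpy()
        alts = sites["alt"].to_numpy()
        gt, dp, gq = cohort.gt, cohort.dp, cohort.gq
        adr, ada = cohort.ad_ref, cohort.ad_alt
        n_samples = len(cohort.samples)
        for j in range(len(sites)):
            fields = [
                f"{_GT_STR[int(gt[i, j])]}:{dp[i, j]}:{gq[i, j]}:{adr[i, j]},{ada[i, j]}"
                for i in range(n_samples)
            ]
            fh.write(
                f"{chroms[j]}\t{poss[j]}\t.\t{refs[j]}\t{alts[j]}\t.\tPASS\t.\tGT:DP:GQ:AD\t"
                + "\t".join(fields)
                + "\n"
            )


def write_ped(cohort: CohortData, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in cohort.trios:
            fh.write(f"{t.trio_id}\t{t.father}\t0\t0\t1\t0\n")
            fh.write(f"{t.trio_id}\t{t.mother}\t0\t0\t2\t0\n")
            fh.write(f"{t.trio_id}\t{t.child}\t{t.father}\t{t.mother}\t0\t0\n")


def write_coverage_table(cohort: CohortData, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tmean_coverage\n")
        for s in cohort.samples:
            fh.write(f"{s}\t{cohort.config.mean_coverage:g}\n")


def write_repeat_bed(tracks: GenomeTracks, path: str | Path) -> None:
    ivs = sorted(tracks.repeats, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in ivs:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\t{iv.repeat_class}\n"
            )


def write_alignability_bedgraph(tracks: GenomeTracks, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, score in tracks.alignability:
            fh.write(f"{chrom}\t{start}\t{end}\t{score:g}\n")


def write_ancestry_tsv(cohort: CohortData, path: str | Path) -> None:
    cohort.ancestry.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_chrom_sizes(cohort: CohortData, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in cohort.config.genome:
            fh.write(f"{chrom}\t{length}\n")


def write_outputs(cohort: CohortData, out_dir: str | Path) -> dict[str, Path]:
    """Write all cohort artifacts; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "ped": out / "cohort.ped",
        "coverage": out / "coverage.tsv",
        "repeats": out / "repeats.bed",
        "alignability": out / "alignability.bedGraph",
        "ancestry": out / "ancestry_pcs.tsv",
        "chrom_sizes": out / "chrom.sizes",
        "truth": out / "truth.json",
    }
    write_vcf(cohort, paths["vcf"])
    write_ped(cohort, paths["ped"])
    write_coverage_table(cohort, paths["coverage"])
    write_repeat_bed(cohort.tracks, paths["repeats"])
    write_alignability_bedgraph(cohort.tracks, paths["alignability"])
    write_ancestry_tsv(cohort, paths["ancestry"])
    write_chrom_sizes(cohort, paths["chrom_sizes"])
    cohort.truth.to_json(paths["truth"])
    return paths


def draw_het_calls(
    rng: np.random.Generator, mean_coverage: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Depths and alt-read counts of n clean heterozygous calls.

    DP ~ Poisson(mean coverage), alt reads ~ Binomial(DP, 1/2) — the
    simulator's diploid het model, exposed for calibration checks.
    """
    dp = rng.poisson(mean_coverage, size=n)
    alt = rng.binomial(dp, 0.5)
    return dp, alt
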