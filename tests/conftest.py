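from __future__ import annotations

from pathlib import Path

import pytest

from miclens import synthetic_data as sim
from miclens.mic_core import (
    FilterConfig,
    detect_mic,
    read_coverage_table,
    write_mic_tsv,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##contig=<ID=chrX,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""


def write_toy_vcf(path: Path, samples: list[str], rows: list[str]) -> Path:
    """rows are pre-formatted body lines (tab-joined, no trailing newline)."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for row in rows:
            fh.write(row + "\n")
    return path


def gt_field(gt: str, dp: int = 40, gq: int = 99, ad: tuple[int, int] | None = None) -> str:
    if ad is None:
        ad = {"0/0": (dp, 0), "0/1": (dp // 2, dp - dp // 2), "1/1": (0, dp)}.get(gt, (0, 0))
    return f"{gt}:{dp}:{gq}:{ad[0]},{ad[1]}"


@pytest.fixture(scope="session")
def basic_cohort(tmp_path_factory):
    """Small mixed cohort: deletions, errors, slippage and de novos.

    Returns (cohort, paths, mic_tsv_path, coverage dict).
    """
    cfg = sim.SimulationConfig(
        populations=[("EUR", 20), ("AMR", 20)],
        genome=[("chr1", 800_000), ("chr2", 500_000)],
        seed=123,
        site_density=5e-4,
        de_novo_rate=2e-6,
        deletions=[
            sim.DeletionRegionSpec(
                "chr1", 300_000, 360_000, {"AMR": 0.5, "EUR": 0.1}, extra_site_density=3e-4
            )
        ],
        errors=sim.ErrorModel(base_rate=2e-3, homopolymer_indel_rate=1e-2, trio_scale_sd=0.4),
    )
    cohort = sim.simulate_cohort(cfg)
    out = tmp_path_factory.mktemp("basic_cohort")
    paths = sim.write_outputs(cohort, out)
    coverage = read_coverage_table(paths["coverage"])
    mic_path = out / "mic.tsv"
    write_mic_tsv(
        detect_mic(paths["vcf"], cohort.trios, FilterConfig(), coverage), mic_path
    )
    return cohort, paths, mic_path, coverage
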