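"""Configuration objects for simulation and pipeline runs."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: conditions used throughout; infected carries Wolbachia, cured does not
CONDITIONS = ("infected", "cured")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one global seed.

    Stages can be regenerated independently: the stream depends only on
    (seed, name), never on call order.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode()) & 0x7FFFFFFF])
    )


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic data generator.

    Defaults emulate the introgression study design: three infected and
    three cured clonal replicate lines, a bimodal gene-body methylation
    landscape, a small hyper-biased fraction of infection-responsive CpGs,
    negative-binomial expression counts with higher dispersion in cured
    lines, a few retained maternal blocks, and a lambda spike-in with
    bisulfite conversion error below 0.2%.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 1_000_000
    n_genes: int = 300
    exons_per_gene: tuple[int, int] = (3, 8)
    n_parental_snps: int = 2_000
    n_cpgs: int = 6_000
    n_lambda_sites: int = 2_000
    n_replicates_per_condition: int = 3
    # truth intervals of retained maternal (non-introgressed) ancestry,
    # 1-based inclusive; ~5% of the genome by default (95-99% replaced)
    maternal_block_spec: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("chr1", 100_001, 160_000), ("chr2", 500_001, 540_000)]
    )
    origin_misclassification_rate: float = 0.0
    conversion_error: float = 0.002
    depth_mean: float = 60.0
    depth_dispersion: float = 0.15  # NB alpha for per-site read depth
    # gene-body methylation landscape: fraction of genes methylated, and
    # beta parameters for CpG fractions in the low/high modes
    frac_genes_methylated: float = 0.30
    meth_low_beta: tuple[float, float] = (0.2, 150.0)
    meth_high_beta: tuple[float, float] = (8.0, 2.0)
    frac_dmp: float = 0.01
    frac_hyper: float = 0.7
    delta_logit: float = 2.0
    frac_de: float = 0.05
    frac_up_de: float = 0.76
    lfc_mean: float = 1.5
    lfc_sd: float = 0.5
    base_expression_log_mean: float = 5.0
    base_expression_log_sd: float = 1.5
    dispersion_asymptote: float = 0.05
    dispersion_scale: float = 2.0  # per-gene NB dispersion law: a0/mu + a1
    noise_inflation_cured: float = 1.5
    frac_deu: float = 0.05
    deu_fold: float = 2.0
    library_size_log_sd: float = 0.15

    def validate(self) -> None:
        for name in ("frac_genes_methylated", "frac_dmp", "frac_hyper",
                     "frac_de", "frac_up_de", "frac_deu",
                     "origin_misclassification_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if not 0.0 < self.conversion_error < 0.05:
            raise ValueError(f"conversion_error={self.conversion_error} must lie in (0, 0.05)")
        if self.n_replicates_per_condition < 2:
            raise ValueError("need at least 2 replicates per condition")
        if self.noise_inflation_cured < 1.0:
            raise ValueError("noise_inflation_cured must be >= 1")
        chroms = self.chrom_names()
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.maternal_block_spec:
            if chrom not in chroms:
                raise ValueError(f"maternal block ({chrom}, {start}, {end}): unknown chromosome")
            if not (1 <= start <= end <= self.chrom_len):
                raise ValueError(
                    f"maternal block ({chrom}, {start}, {end}) outside chromosome bounds "
                    f"[1, {self.chrom_len}]"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"maternal blocks ({chrom}, {s1}, {e1}) and ({chrom}, {s2}, {e2}) overlap"
                    )

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def sample_sheet(self):
        """Sample -> condition table: <line letter><i|c> naming (Ai..Cc)."""
        import pandas as pd

        rows = []
        for i in range(self.n_replicates_per_condition):
            line = chr(ord("A") + i)
            rows.append((f"{line}i", "infected", line))
            rows.append((f"{line}c", "cured", line))
        return pd.DataFrame(rows, columns=["sample", "condition", "line"])


@dataclass
class PipelineConfig:
    """End-to-end run configuration: input paths, thresholds, seed, outputs."""

    input_dir: Path
    output_dir: Path
    seed: int = 0
    introgression_threshold_bp: int = 10_000
    min_depth: int = 10
    min_quality: float = 30.0
    alpha: float = 0.05
    gene_methylation_threshold: float = 0.004
    mask_maternal: bool = True

    def validate(self) -> None:
        if self.introgression_threshold_bp <= 0:
            raise ValueError("introgression threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
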