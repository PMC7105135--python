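"""Strand-combined CpG counts, methylation status calls, gene-body summaries.

A CpG unit pairs the plus-strand C at position p with the minus-strand C
at p+1; read counts from both strands are summed onto the plus-strand
coordinate. Sites are called methylated/unmethylated by a one-sided
binomial test against the bisulfite conversion-error rate estimated from
the unmethylated lambda spike-in, with BH correction per sample.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

STATUS_METHYLATED = "methylated"
STATUS_UNMETHYLATED = "unmethylated"


def combine_strand_counts(per_strand: pd.DataFrame) -> pd.DataFrame:
    """Sum plus- and minus-strand C/T counts onto the plus-strand C position.

    The minus-strand C of a CpG sits one base downstream of the plus-strand
    C, so a minus-strand row at p is credited to the unit at p-1. A
    minus-strand C with no plus-strand partner is kept as its own unit at
    p-1 and logged. Total read counts are conserved exactly.
    """
    df = per_strand.copy()
    is_minus = df["strand"] == "-"
    df["unit_pos"] = np.where(is_minus, df["pos"] - 1, df["pos"])
    minus_only = set(map(tuple, df.loc[is_minus, ["chrom", "unit_pos"]].itertuples(index=False))) \
        - set(map(tuple, df.loc[~is_minus, ["chrom", "unit_pos"]].itertuples(index=False)))
    if minus_only:
        logger.info("%d minus-strand Cs had no plus-strand partner; kept as own units",
                    len(minus_only))
    out = (
        df.groupby(["chrom", "unit_pos"], as_index=False)[["count_methylated", "count_unmethylated"]]
        .sum()
        .rename(columns={"unit_pos": "pos"})
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    out["count_total"] = out["count_methylated"] + out["count_unmethylated"]
    return out.drop(columns=["count_unmethylated"])


def estimate_conversion_error(lambda_counts: pd.DataFrame) -> float:
    """Conversion-error rate from the unmethylated lambda spike-in.

    error = total methylated lambda calls / total lambda calls; conversion
    efficiency is 1 - error. Warns if efficiency falls below 99.8%.
    """
    total = int(lambda_counts["count_total"].sum())
    if total == 0:
        raise ValueError("lambda spike-in has zero total counts")
    error = float(lambda_counts["count_methylated"].sum()) / total
    if 1.0 - error < 0.998:
        warnings.warn(f"bisulfite conversion efficiency {100 * (1 - error):.2f}% < 99.8%",
                      stacklevel=2)
    return error


def classify_site_methylation(sites: pd.DataFrame, sample: str, error: float,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Call each covered CpG methylated or unmethylated for one sample.

    Per site, the one-sided binomial tail probability of observing at least
    count_methylated successes in count_total trials at the conversion-error
    rate; BH adjustment across the sample's covered sites; methylated iff
    q < alpha. Sites with zero coverage are left uncalled (dropped).
    """
    if not 0.0 < error < 1.0:
        raise ValueError(f"error rate must lie in (0, 1), got {error}")
    covered = sites[sites["count_total"] > 0].copy()
    m = covered["count_methylated"].to_numpy()
    n = covered["count_total"].to_numpy()
    p = stats.binom.sf(m - 1, n, error)
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    covered["sample"] = sample
    covered["fractional_methylation"] = m / n
    covered["p_value"] = p
    covered["q_value"] = q
    covered["status"] = np.where(q < alpha, STATUS_METHYLATED, STATUS_UNMETHYLATED)
    return covered.reset_index(drop=True)


def compute_gene_body_methylation(sites: pd.DataFrame, genes: pd.DataFrame,
                                  fraction_col: str = "fractional_methylation") -> pd.DataFrame:
    """Unweighted mean fractional methylation over the CpGs in each gene span.

    The gene span is the full annotated interval including introns; gene
    strand is ignored. Genes with zero covered CpGs are flagged
    (n_cpgs == 0, NaN mean) for downstream exclusion.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for _, g in genes.iterrows():
        trees.setdefault(g["chrom"], IntervalTree()).addi(g["start"], g["end"] + 1, g["gene_id"])
    sums: dict[str, float] = {g: 0.0 for g in genes["gene_id"]}
    counts: dict[str, int] = {g: 0 for g in genes["gene_id"]}
    for chrom, sub in sites.groupby("chrom"):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for pos, frac in zip(sub["pos"].to_numpy(), sub[fraction_col].to_numpy()):
            for iv in tree.at(pos):
                sums[iv.data] += frac
                counts[iv.data] += 1
    n = np.array([counts[g] for g in genes["gene_id"]])
    with np.errstate(invalid="ignore"):
        mean = np.array([sums[g] for g in genes["gene_id"]]) / np.where(n > 0, n, np.nan)
    return pd.DataFrame({
        "gene_id": genes["gene_id"].to_numpy(),
        "mean_fractional_methylation": mean,
        "n_cpgs": n,
    })


def classify_gene_methylation(gene_meth: pd.DataFrame,
                              threshold: float = 0.004) -> pd.DataFrame:
    """Label a gene methylated iff its gene-body mean exceeds the threshold
    (strictly); genes with no CpGs stay unlabeled."""
    out = gene_meth.copy()
    mean = out["mean_fractional_methylation"]
    out["class"] = np.where(mean > threshold, STATUS_METHYLATED, STATUS_UNMETHYLATED)
    out.loc[mean.isna(), "class"] = ""
    return out
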