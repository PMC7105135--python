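"""Maternal ancestry-block detection and masking from diagnostic SNPs.

Introgressed lines should carry the paternal nuclear genome except for a
few retained maternal blocks. High-confidence homozygous SNP calls are
classified by allelic origin against the parental diagnostic panel; runs
of maternal SNPs are chained into blocks (a chain extends to the next
maternal SNP within a threshold distance and stops at any intervening
paternal SNP); blocks are masked from all downstream statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ORIGIN_MATERNAL = "maternal"
ORIGIN_PATERNAL = "paternal"
ORIGIN_UNCLASSIFIED = "unclassified"


def filter_snp_calls(calls: pd.DataFrame, min_depth: int = 10,
                     min_quality: float = 30.0) -> pd.DataFrame:
    """Keep homozygous calls with depth >= min_depth and quality >= min_quality.

    Row order is preserved; an empty result is allowed.
    """
    keep = (
        (calls["zygosity"] == "hom")
        & (calls["depth"] >= min_depth)
        & (calls["quality"] >= min_quality)
    )
    return calls.loc[keep].reset_index(drop=True)


def classify_origin(calls: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Assign each call maternal/paternal/unclassified origin against the panel.

    A call at a panel position matching the maternal allele is maternal,
    matching the paternal allele is paternal; anything else (including
    positions absent from the panel) is unclassified.
    """
    dup = panel.duplicated(subset=["chrom", "pos"])
    if dup.any():
        bad = panel.loc[dup, ["chrom", "pos"]].head(5).to_records(index=False)
        raise ValueError(f"duplicate parental panel positions: {list(bad)}")
    merged = calls.merge(panel, on=["chrom", "pos"], how="left")
    origin = np.where(
        merged["allele"] == merged["maternal_allele"], ORIGIN_MATERNAL,
        np.where(merged["allele"] == merged["paternal_allele"], ORIGIN_PATERNAL,
                 ORIGIN_UNCLASSIFIED),
    )
    origin = np.where(merged["maternal_allele"].isna(), ORIGIN_UNCLASSIFIED, origin)
    return pd.DataFrame({"chrom": calls["chrom"], "pos": calls["pos"], "origin": origin})


def call_maternal_blocks(origins: pd.DataFrame, threshold: int = 10_000) -> pd.DataFrame:
    """Chain maternal SNPs into ancestry blocks.

    A block starts at a maternal SNP and extends to each next maternal SNP
    within ``threshold`` bp of the previous one, until a paternal SNP is
    reached; an intervening paternal SNP always terminates the chain, and
    unclassified positions neither extend nor break it. Block span runs
    from the first to the last maternal SNP of the chain (1-based
    inclusive); a singleton chain yields a 1-bp block.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    rows = []
    informative = origins[origins["origin"] != ORIGIN_UNCLASSIFIED]
    for chrom, sub in informative.groupby("chrom", sort=True):
        sub = sub.sort_values("pos", kind="stable")
        start = prev = None
        count = 0
        for pos, origin in zip(sub["pos"].to_numpy(), sub["origin"].to_numpy()):
            if origin == ORIGIN_MATERNAL:
                if start is not None and pos - prev <= threshold:
                    prev = pos
                    count += 1
                else:
                    if start is not None:
                        rows.append((chrom, start, prev, count))
                    start = prev = pos
                    count = 1
            else:  # paternal: always break the chain
                if start is not None:
                    rows.append((chrom, start, prev, count))
                    start = prev = None
                    count = 0
        if start is not None:
            rows.append((chrom, start, prev, count))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_maternal_snps"])


def mask_intervals(blocks: pd.DataFrame, sites: pd.DataFrame):
    """Drop sites falling inside any maternal block (inclusive ends).

    Returns (retained sites, summary dict with masked site/bp totals).
    ``sites`` needs chrom and pos columns; other columns pass through.
    """
    if blocks.empty:
        return sites.reset_index(drop=True), {"n_masked_sites": 0, "masked_bp": 0}
    keep = np.ones(len(sites), dtype=bool)
    for chrom, sub in blocks.groupby("chrom"):
        sel = (sites["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = sub.sort_values("start")["end"].to_numpy()
        pos = sites.loc[sel, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])
        keep[np.flatnonzero(sel)[inside]] = False
    masked_bp = int((blocks["end"] - blocks["start"] + 1).sum())
    summary = {"n_masked_sites": int((~keep).sum()), "masked_bp": masked_bp}
    return sites.loc[keep].reset_index(drop=True), summary


def blocks_to_bed(blocks: pd.DataFrame) -> pd.DataFrame:
    """Internal 1-based inclusive blocks as 0-based half-open BED records."""
    return pd.DataFrame({
        "chrom": blocks["chrom"],
        "start": blocks["start"] - 1,
        "end": blocks["end"],
    })


def block_base_overlap(called: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Base-level recall and precision of called blocks against truth blocks.

    Both tables use 1-based inclusive (chrom, start, end). Recall = truth
    bases covered by calls / truth bases; precision = called bases inside
    truth / called bases.
    """
    def to_sets(df):
        bases: dict[str, set] = {}
        for _, r in df.iterrows():
            bases.setdefault(r["chrom"], set()).update(range(int(r["start"]), int(r["end"]) + 1))
        return bases

    called_b = to_sets(called)
    truth_b = to_sets(truth)
    n_called = sum(len(v) for v in called_b.values())
    n_truth = sum(len(v) for v in truth_b.values())
    n_hit = sum(len(called_b.get(c, set()) & v) for c, v in truth_b.items())
    return {
        "recall": n_hit / n_truth if n_truth else float("nan"),
        "precision": n_hit / n_called if n_called else float("nan"),
        "called_bp": n_called,
        "truth_bp": n_truth,
    }


def summarize_introgression(origins: pd.DataFrame, blocks: pd.DataFrame,
                            genome_size: int) -> dict:
    """Genome fraction in maternal blocks, per-chromosome block stats, and
    the distribution of distances between adjacent maternal SNPs."""
    if genome_size <= 0:
        raise ValueError(f"genome_size must be positive, got {genome_size}")
    maternal = origins[origins["origin"] == ORIGIN_MATERNAL]
    distances = []
    for _, sub in maternal.groupby("chrom"):
        pos = np.sort(sub["pos"].to_numpy())
        distances.extend(np.diff(pos).tolist())
    distances = np.asarray(distances, dtype=float)
    maternal_bp = int((blocks["end"] - blocks["start"] + 1).sum()) if len(blocks) else 0
    per_chrom = {}
    for chrom, sub in blocks.groupby("chrom"):
        per_chrom[chrom] = {
            "n_blocks": int(len(sub)),
            "total_bp": int((sub["end"] - sub["start"] + 1).sum()),
            "mean_bp": float((sub["end"] - sub["start"] + 1).mean()),
        }
    return {
        "n_maternal_snps": int(len(maternal)),
        "n_paternal_snps": int((origins["origin"] == ORIGIN_PATERNAL).sum()),
        "n_unclassified": int((origins["origin"] == ORIGIN_UNCLASSIFIED).sum()),
        "n_blocks": int(len(blocks)),
        "maternal_bp": maternal_bp,
        "maternal_fraction": maternal_bp / genome_size,
        "per_chromosome": per_chrom,
        "n_adjacent_distances": int(distances.size),
        "frac_adjacent_within_2kb": float((distances <= 2_000).mean()) if distances.size else float("nan"),
        "frac_adjacent_within_10kb": float((distances <= 10_000).mean()) if distances.size else float("nan"),
    }
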