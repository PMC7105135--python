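"""Overlap and enrichment statistics: Fisher's exact test, chi-squared
equal-proportion tests, and hypergeometric term enrichment with BH."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> dict:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Cells are (in-both, in-A-only, in-B-only, in-neither). The reported
    odds ratio is the sample odds ratio a*d / (b*c); when a zero cell
    occurs, the Haldane correction (0.5 added to every cell) is applied to
    the odds ratio only, and flagged. The p-value sums hypergeometric
    probabilities of all margin-fixed tables as or less probable than the
    observed one (probability ordering).
    """
    cells = np.array([a, b, c, d])
    if np.any(cells < 0):
        raise ValueError(f"negative cell count in table {cells.tolist()}")
    haldane = bool(np.any(cells == 0))
    if haldane:
        a2, b2, c2, d2 = cells + 0.5
    else:
        a2, b2, c2, d2 = cells
    odds_ratio = (a2 * d2) / (b2 * c2)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {"odds_ratio": float(odds_ratio), "p_value": float(p),
            "haldane_corrected": haldane,
            "odds_ratio_convention": "sample (Haldane 0.5 on zero cells)"}


def chi_square_equal_proportions(k1: int, k2: int) -> tuple[float, float]:
    """1-df goodness-of-fit of the split (k1, k2) against 50:50.

    No continuity correction. Returns (statistic, p).
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("counts must be non-negative")
    if k1 + k2 == 0:
        raise ValueError("both counts are zero")
    stat, p = stats.chisquare([k1, k2])
    return float(stat), float(p)


def hypergeometric_term_enrichment(query: set, terms: dict, universe: set,
                                   alpha: float = 0.05,
                                   skip_zero_overlap: bool = True) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in a query gene set.

    ``terms`` maps term id -> gene set; all genes are tested against the
    declared universe as background. BH correction across tested terms;
    terms with zero overlap are skipped (flagged in the returned frame's
    attrs) unless ``skip_zero_overlap`` is False.
    """
    if not query:
        raise ValueError("empty query gene set")
    stray = set(query) - set(universe)
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:10]}")
    N = len(universe)
    n_query = len(query)
    rows = []
    n_skipped = 0
    for term, genes in terms.items():
        genes = set(genes) & set(universe)
        k = len(set(query) & genes)
        if k == 0 and skip_zero_overlap:
            n_skipped += 1
            continue
        p = stats.hypergeom.sf(k - 1, N, len(genes), n_query)
        rows.append((term, k, len(genes), float(p)))
    out = pd.DataFrame(rows, columns=["term", "n_overlap", "term_size", "p_value"])
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["q_value"] < alpha
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        out["q_value"] = []
        out["significant"] = []
    out.attrs["n_terms_skipped_zero_overlap"] = n_skipped
    return out
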