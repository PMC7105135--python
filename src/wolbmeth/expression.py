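"""Negative-binomial differential expression and differential exon usage.

Libraries are normalized by median-of-ratios size factors. Genes are fit
by an NB generalized linear model (log link, log size factors as offsets);
because the single predictor is a two-level condition, the mean structure
is saturated per condition and fit by Newton ascent. Per-gene dispersions
are estimated by Cox-Reid adjusted profile maximum likelihood and pooled
across genes through the mean-dispersion law alpha(mu) = a0/mu + a1; the
1-df likelihood-ratio test of the infection effect is computed at the
trended dispersion, which keeps the chi-squared reference honest with
three replicates per condition. No outlier machinery.

Exon usage conditions on per-sample gene totals: the exon's count is
modeled against an offset of log(gene total), so a condition effect on
the exon's proportional share is a 1-df LRT per exon.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .diffmeth import adjust_bh
from .enrichment import chi_square_equal_proportions

LOG2 = np.log(2.0)
MIN_DISPERSION = 1e-8
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0
_T_GRID = np.linspace(-3.0, 20.0, 10)  # t = log r = -log(alpha)


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    The reference is the per-gene geometric mean across samples, computed
    over genes with no zero count; each sample's factor is the median of
    its count/reference ratios.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; consider a pseudo-reference"
        )
    log_ref = np.log(mat[all_nonzero]).mean(axis=1)
    factors = np.exp(np.median(np.log(mat[all_nonzero]) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _nb_ll(y, mu, r):
    """NB log-likelihood summed over the sample axis (y! term omitted:
    constant in the parameters, cancels in every likelihood ratio)."""
    return (special.gammaln(y + r) - special.gammaln(r)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu) + 1e-300)).sum(axis=-1)


def _fit_group_means(y, off, groups, r, n_iter: int = 40):
    """Per-group ML log-mean via Fisher-scoring Newton, vectorized over genes.

    y, off: (G, k) arrays; groups: list of sample-index arrays; r: (G,)
    NB size (1/dispersion). Returns one (G,) log-mean array per group.
    """
    out = []
    for g in groups:
        yy = y[:, g]
        oo = off[:, g]
        bg = np.log(np.maximum((yy / np.exp(oo)).mean(axis=1), 1e-10))
        r_e = r[:, None]
        for _ in range(n_iter):
            mu = np.exp(np.clip(bg[:, None] + oo, -40, 40))
            grad = (r_e * (yy - mu) / (r_e + mu)).sum(axis=1)
            info = (r_e * mu / (r_e + mu)).sum(axis=1)  # expected information
            step = np.clip(grad / np.maximum(info, 1e-12), -3.0, 3.0)
            bg = np.clip(bg + step, -30.0, 30.0)
            if np.max(np.abs(step)) < 1e-11:
                break
        out.append(bg)
    return out


def _group_ll(y, off, groups, betas, r):
    ll = 0.0
    for g, bg in zip(groups, betas):
        mu = np.exp(np.clip(bg[:, None] + off[:, g], -40, 40))
        ll = ll + _nb_ll(y[:, g], mu, r[:, None])
    return ll


def _cr_apl(y, off, groups, t):
    """Cox-Reid adjusted profile log-likelihood at t = log r (vector)."""
    r = np.exp(t)
    betas = _fit_group_means(y, off, groups, r)
    ll = _group_ll(y, off, groups, betas, r)
    adj = 0.0
    for g, bg in zip(groups, betas):
        mu = np.exp(np.clip(bg[:, None] + off[:, g], -40, 40))
        w = (r[:, None] * mu / (r[:, None] + mu)).sum(axis=1)
        adj = adj + 0.5 * np.log(np.maximum(w, 1e-300))
    return ll - adj


def estimate_dispersions(y, off, groups):
    """Per-gene CR-adjusted ML dispersion via grid + golden section on log r."""
    G = y.shape[0]
    vals = np.stack([_cr_apl(y, off, groups, np.full(G, t)) for t in _T_GRID], axis=1)
    best = _T_GRID[np.argmax(vals, axis=1)]
    lo, hi = best - 2.6, best + 2.6
    x1 = hi - _GOLDEN * (hi - lo)
    x2 = lo + _GOLDEN * (hi - lo)
    f1 = _cr_apl(y, off, groups, x1)
    f2 = _cr_apl(y, off, groups, x2)
    for _ in range(22):
        right = f1 < f2
        lo = np.where(right, x1, lo)
        hi = np.where(right, hi, x2)
        x1n = np.where(right, x2, hi - _GOLDEN * (hi - lo))
        x2n = np.where(right, lo + _GOLDEN * (hi - lo), x1)
        f1_old, f2_old = f1, f2
        fe = _cr_apl(y, off, groups, np.where(right, x2n, x1n))
        f1 = np.where(right, f2_old, fe)
        f2 = np.where(right, fe, f1_old)
        x1, x2 = x1n, x2n
    t_hat = np.where(f1 > f2, x1, x2)
    return np.maximum(1.0 / np.exp(t_hat), MIN_DISPERSION)


def fit_dispersion_trend(alpha_hat, base_mean, n_iter: int = 8):
    """Fit of the dispersion law alpha = a0/mu + a1 over informative genes.

    Per-gene dispersion estimates from few replicates have a heavy right
    tail, so the least-squares fit is re-run with iterative exclusion of
    genes whose estimate deviates from the current trend by more than
    15-fold (or below 1e-4 of it); without the trimming a handful of
    outliers can crush the asymptote and destroy test calibration.
    Returns (a0, a1), both floored at 0; falls back to the per-gene median
    when fewer than 10 genes are available.
    """
    keep = base_mean > 1
    if keep.sum() < 10:
        return 0.0, float(np.median(alpha_hat))
    x = 1.0 / base_mean[keep]
    a = np.maximum(alpha_hat[keep], 1e-8)
    # robust start: asymptote from high-expression genes, slope from the rest
    hi = base_mean[keep] > np.median(base_mean[keep])
    a1 = float(np.median(a[hi]))
    a0 = float(np.median(np.maximum(a[~hi] - a1, 0.0) / x[~hi])) if (~hi).any() else 0.0
    use = np.ones(len(a), dtype=bool)
    for _ in range(n_iter):
        trend = np.maximum(a0 * x + a1, 1e-8)
        use = (a / trend > 1e-4) & (a / trend < 15.0)
        if use.sum() < 10:
            break
        w = 1.0 / trend[use] ** 2  # gamma-family style: relative errors
        X = np.column_stack([x[use], np.ones(int(use.sum()))])
        Xw = X * w[:, None]
        coef = np.linalg.solve(X.T @ Xw, Xw.T @ a[use])
        new = np.maximum(coef, 0.0)
        if np.allclose(new, [a0, a1], rtol=1e-6, atol=1e-12):
            a0, a1 = new
            break
        a0, a1 = new
    return float(a0), float(a1)


def batch_nb_lrt(y, off, infected):
    """Vectorized per-row NB LRT of a condition effect.

    y, off: (G, k) count and offset arrays; infected: boolean (k,).
    Dispersion: per-row CR-adjusted ML, pooled through the alpha(mu)
    trend, LRT evaluated at the trended value. Returns a DataFrame with
    log2_fold_change, lrt_statistic, p_value and dispersion columns.
    """
    y = np.asarray(y, dtype=float)
    off = np.broadcast_to(np.asarray(off, dtype=float), y.shape)
    infected = np.asarray(infected, dtype=bool)
    groups_full = [np.flatnonzero(infected), np.flatnonzero(~infected)]
    groups_null = [np.arange(y.shape[1])]

    alpha_hat = estimate_dispersions(y, off, groups_full)
    base_mean = (y / np.exp(off)).mean(axis=1)
    a0, a1 = fit_dispersion_trend(alpha_hat, base_mean)
    alpha_tr = np.maximum(a0 / np.maximum(base_mean, 1e-8) + a1, MIN_DISPERSION)
    r = 1.0 / alpha_tr

    betas_full = _fit_group_means(y, off, groups_full, r)
    betas_null = _fit_group_means(y, off, groups_null, r)
    ll_full = _group_ll(y, off, groups_full, betas_full, r)
    ll_null = _group_ll(y, off, groups_null, betas_null, r)
    lrt = np.maximum(0.0, 2.0 * (ll_full - ll_null))
    out = pd.DataFrame({
        "log2_fold_change": (betas_full[0] - betas_full[1]) / LOG2,
        "lrt_statistic": lrt,
        "p_value": stats.chi2.sf(lrt, df=1),
        "dispersion_gene": alpha_hat,
        "dispersion_trend": alpha_tr,
    })
    out.attrs["dispersion_law"] = {"a0": a0, "a1": a1}
    return out


def fit_nb_de(counts: pd.DataFrame, size_factors: pd.Series,
              conditions: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene NB LRT of an infection effect on expression.

    Returns a frame with log2_fold_change (infected vs cured), p, q and
    is_deg; genes with all-zero counts are excluded from testing and from
    the BH denominator.
    """
    samples = list(counts.columns)
    per_cond = pd.Series([conditions[s] for s in samples]).value_counts()
    if per_cond.get("infected", 0) < 2 or per_cond.get("cured", 0) < 2:
        raise ValueError("need >= 2 replicates per condition")
    infected = np.array([conditions[s] == "infected" for s in samples])
    offsets = np.log(size_factors.loc[samples].to_numpy())

    y = counts.to_numpy(dtype=float)
    tested = y.sum(axis=1) > 0
    res = batch_nb_lrt(y[tested], np.broadcast_to(offsets, y[tested].shape), infected)
    out = pd.DataFrame(index=counts.index,
                       columns=["log2_fold_change", "lrt_statistic", "p_value"],
                       dtype=float)
    out.loc[tested, ["log2_fold_change", "lrt_statistic", "p_value"]] = \
        res[["log2_fold_change", "lrt_statistic", "p_value"]].to_numpy()
    out["tested"] = tested
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested] = adjust_bh(out.loc[tested, "p_value"].to_numpy())
    out["q_value"] = q
    out["is_deg"] = (out["q_value"] < alpha) & tested
    out.index.name = "gene_id"
    return out


def summarize_fold_changes(de: pd.DataFrame) -> dict:
    """Direction split and mean linear fold changes of the DEG set.

    Up-regulated means higher in infected. Mean fold changes are averaged
    on the linear scale; the down set is reported as mean fold *lower* in
    infected. Empty DEG set yields an empty summary, not an error.
    """
    degs = de[de["is_deg"]]
    if degs.empty:
        return {"n_degs": 0, "n_up": 0, "n_down": 0}
    lfc = degs["log2_fold_change"]
    n_up = int((lfc > 0).sum())
    n_down = int((lfc <= 0).sum())
    summary = {
        "n_degs": int(len(degs)),
        "n_up": n_up,
        "n_down": n_down,
        "up_percent": 100.0 * n_up / len(degs),
    }
    chi2, p = chi_square_equal_proportions(n_up, n_down)
    summary["direction_chi2"] = chi2
    summary["direction_p"] = p
    if n_up:
        summary["mean_fold_up"] = float((2.0 ** lfc[lfc > 0]).mean())
    if n_down:
        summary["mean_fold_down"] = float((2.0 ** (-lfc[lfc <= 0])).mean())
    return summary


def fit_deu(exon_counts: pd.DataFrame, exon_to_gene: pd.Series,
            conditions: pd.Series, size_factors: pd.Series | None = None,
            alpha: float = 0.05) -> pd.DataFrame:
    """Per-exon NB LRT of a condition effect on the exon's share of its gene.

    The model offsets each sample by log(per-sample gene total), so library
    size cancels; ``size_factors`` is accepted for interface symmetry but
    unused. Exons of single-exon genes, all-zero exons, and exons whose
    gene total is positive in fewer than 2 samples of either condition are
    untestable and excluded from the BH denominator.
    """
    samples = list(exon_counts.columns)
    infected = np.array([conditions[s] == "infected" for s in samples])
    gene_of = exon_to_gene.loc[exon_counts.index]
    gene_totals = exon_counts.groupby(gene_of.to_numpy()).sum()
    n_exons = gene_of.value_counts()

    y = exon_counts.to_numpy(dtype=float)
    tot = gene_totals.loc[gene_of.to_numpy()].to_numpy(dtype=float)
    covered = tot > 0
    testable = ((gene_of.map(n_exons) >= 2).to_numpy()
                & (y.sum(axis=1) > 0)
                & ((covered & infected).sum(axis=1) >= 2)
                & ((covered & ~infected).sum(axis=1) >= 2))
    out = pd.DataFrame(index=exon_counts.index,
                       columns=["usage_log2_change", "lrt_statistic", "p_value"],
                       dtype=float)
    out.insert(0, "gene_id", gene_of.to_numpy())
    if testable.any():
        # a sample with zero gene total has y = 0 and mu -> 0: zero contribution
        off = np.where(covered[testable], np.log(np.maximum(tot[testable], 1e-12)), -30.0)
        res = batch_nb_lrt(y[testable], off, infected)
        out.loc[testable, ["usage_log2_change", "lrt_statistic", "p_value"]] = \
            res[["log2_fold_change", "lrt_statistic", "p_value"]].to_numpy()
    out["testable"] = testable
    q = np.full(len(out), np.nan)
    if testable.any():
        q[testable] = adjust_bh(out.loc[testable, "p_value"].to_numpy())
    out["q_value"] = q
    out["is_deu"] = (out["q_value"] < alpha) & testable
    out.index.name = "exon_id"
    return out


def normalize_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Counts divided by their sample's size factor."""
    return counts / size_factors.loc[counts.columns]
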