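"""Beta-binomial differential methylation: per-CpG infection-effect tests.

Testable sites are CpGs called methylated in at least one sample. Each is
fit by maximum likelihood under a beta-binomial regression with a logit
link — logit(mean) = intercept + beta * infected — and one overdispersion
parameter shared across samples; the infection effect is judged by a 1-df
likelihood-ratio test against the intercept-only model, with BH control of
the FDR across testable sites. Significant sites (DMPs) are aggregated
into differentially methylated genes (DMGs), intergenic DMPs being
assigned to the nearest annotated gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .enrichment import chi_square_equal_proportions
from .methylation import STATUS_METHYLATED

# logit-mean bound guarding against quasi-separation (all-0 vs all-n sites)
ETA_BOUND = 15.0
# overdispersion (correlation parameterization) kept inside (1e-8, 1 - 1e-8)
S_BOUND = 18.4  # logit(1e-8) ~= -18.42


def select_testable_sites(calls: pd.DataFrame) -> pd.DataFrame:
    """Sites called methylated in >= 1 sample (long call table in, site list out)."""
    meth = calls[calls["status"] == STATUS_METHYLATED]
    return meth[["chrom", "pos"]].drop_duplicates().sort_values(
        ["chrom", "pos"], kind="stable").reset_index(drop=True)


def _bb_loglik(y, n, eta, phi):
    """Beta-binomial log-likelihood summed over the sample axis.

    eta is the logit mean (already clipped), phi the precision; the
    binomial coefficient term is constant in the parameters and omitted
    (it cancels in every likelihood ratio). Rows with n = 0 (and y = 0)
    contribute exactly zero.
    """
    p = special.expit(eta)
    a = p * phi
    b = (1.0 - p) * phi
    return (special.betaln(y + a, n - y + b) - special.betaln(a, b)).sum(axis=-1)


def _newton_eta(y, n, phi, eta0, n_iter: int = 25, tol: float = 1e-9):
    """Vectorized safeguarded Newton ascent of the likelihood in eta.

    y, n: (..., k) count arrays; phi, eta0: (...) arrays. Maximizes the
    beta-binomial log-likelihood over the logit mean with the precision
    held fixed, clamping to +-ETA_BOUND. Warm starts make this converge in
    a handful of iterations. Returns (eta_hat, ll_hat).
    """
    eta = np.clip(np.asarray(eta0, dtype=float).copy(), -ETA_BOUND, ETA_BOUND)
    phi_e = phi[..., None]
    ll = _bb_loglik(y, n, eta[..., None], phi_e)
    for _ in range(n_iter):
        p = special.expit(eta)[..., None]
        a = p * phi_e
        b = (1.0 - p) * phi_e
        g_obs = (special.digamma(y + a) - special.digamma(a)
                 - special.digamma(n - y + b) + special.digamma(b))
        dp = p * (1.0 - p)
        grad = (phi_e * dp * g_obs).sum(axis=-1)
        curv_obs = (special.polygamma(1, y + a) - special.polygamma(1, a)
                    + special.polygamma(1, n - y + b) - special.polygamma(1, b))
        hess = (phi_e * dp * (1.0 - 2.0 * p) * g_obs
                + (phi_e * dp) ** 2 * curv_obs).sum(axis=-1)
        step = np.where(hess < -1e-12, -grad / np.where(hess < -1e-12, hess, -1.0),
                        np.sign(grad))  # fall back to unit ascent when not concave
        step = np.clip(step, -4.0, 4.0)
        new = np.clip(eta + step, -ETA_BOUND, ETA_BOUND)
        ll_new = _bb_loglik(y, n, new[..., None], phi_e)
        worse = ll_new < ll
        if np.any(worse):  # one half-step backtrack, else stay put
            half = np.clip(eta + 0.5 * step, -ETA_BOUND, ETA_BOUND)
            ll_half = _bb_loglik(y, n, half[..., None], phi_e)
            take_half = worse & (ll_half >= ll)
            new = np.where(take_half, half, np.where(worse, eta, new))
            ll_new = np.where(take_half, ll_half, np.where(worse, ll, ll_new))
        moved = np.max(np.abs(new - eta))
        eta, ll = new, ll_new
        if moved < tol:
            break
    return eta, ll


class _ProfileState:
    """Carries warm-start logit means across profile evaluations."""

    def __init__(self, y_groups, n_groups):
        self.y_groups = y_groups
        self.n_groups = n_groups
        self.etas = []
        for y, n in zip(y_groups, n_groups):
            pbar = (y.sum(axis=-1) + 0.5) / (n.sum(axis=-1) + 1.0)
            self.etas.append(special.logit(np.clip(pbar, 1e-8, 1 - 1e-8)))

    def __call__(self, s):
        """Profile log-likelihood at overdispersion s = logit(rho);
        phi = (1 - rho)/rho = exp(-s)."""
        phi = np.exp(-np.clip(s, -S_BOUND, S_BOUND))
        ll = 0.0
        for i, (y, n) in enumerate(zip(self.y_groups, self.n_groups)):
            eta_hat, ll_g = _newton_eta(y, n, phi, self.etas[i])
            self.etas[i] = eta_hat
            ll = ll + ll_g
        return ll


_S_GRID = np.array([-14.0, -9.0, -6.0, -4.0, -2.0, 0.0, 2.5, 6.0, 16.0])
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _maximize_profile(y_groups, n_groups, n_golden: int = 22):
    """Maximize the beta-binomial likelihood over (group means, overdispersion).

    Coarse grid over s = logit(rho) to bracket the optimum, then
    golden-section refinement (one new profile evaluation per iteration,
    vectorized across sites); the group logit means are profiled out by
    warm-started Newton at every s. Returns (ll, s_hat, eta_hats).
    """
    profile = _ProfileState(y_groups, n_groups)
    shape = y_groups[0].shape[:-1]
    grid_ll = np.empty(shape + (_S_GRID.size,))
    for j, s in enumerate(_S_GRID):
        grid_ll[..., j] = profile(np.full(shape, s))
    best = np.argmax(grid_ll, axis=-1)
    lo = _S_GRID[np.maximum(best - 1, 0)]
    hi = _S_GRID[np.minimum(best + 1, _S_GRID.size - 1)]

    x1 = hi - _GOLDEN * (hi - lo)
    x2 = lo + _GOLDEN * (hi - lo)
    f1 = profile(x1)
    f2 = profile(x2)
    for _ in range(n_golden):
        move_right = f1 < f2  # maximum lies in [x1, hi]
        lo = np.where(move_right, x1, lo)
        hi = np.where(move_right, hi, x2)
        # one interior point is inherited, only the other needs evaluating
        x1_new = np.where(move_right, x2, hi - _GOLDEN * (hi - lo))
        x2_new = np.where(move_right, lo + _GOLDEN * (hi - lo), x1)
        f1_old, f2_old = f1, f2
        x_eval = np.where(move_right, x2_new, x1_new)
        f_eval = profile(x_eval)
        f1 = np.where(move_right, f2_old, f_eval)
        f2 = np.where(move_right, f_eval, f1_old)
        x1, x2 = x1_new, x2_new
    s_hat = np.where(f1 > f2, x1, x2)
    ll = profile(s_hat)
    return ll, s_hat, profile.etas


def batch_beta_binomial_lrt(m_matrix, n_matrix, infected) -> pd.DataFrame:
    """Vectorized per-site beta-binomial LRT of an infection effect.

    m_matrix/n_matrix: (sites x samples) arrays of methylated and total
    counts; infected: boolean per sample. The full model gives each
    condition its own logit mean with a shared per-site overdispersion;
    the null model shares one mean. Sites with fewer than two covered
    samples in either condition are untestable (NaN statistics).
    """
    y = np.asarray(m_matrix, dtype=float)
    n = np.asarray(n_matrix, dtype=float)
    infected = np.asarray(infected, dtype=bool)
    y = np.where(n > 0, y, 0.0)
    covered = n > 0
    testable = ((covered[:, infected].sum(axis=1) >= 2)
                & (covered[:, ~infected].sum(axis=1) >= 2))

    ll_null, _, _ = _maximize_profile([y], [n])
    ll_full, _, (eta_inf, eta_cur) = _maximize_profile(
        [y[:, infected], y[:, ~infected]], [n[:, infected], n[:, ~infected]])
    lrt = np.maximum(0.0, 2.0 * (ll_full - ll_null))
    beta = eta_inf - eta_cur
    p = stats.chi2.sf(lrt, df=1)
    out = pd.DataFrame({
        "beta_infection": np.where(testable, beta, np.nan),
        "lrt_statistic": np.where(testable, lrt, np.nan),
        "p_value": np.where(testable, p, np.nan),
        "direction": np.where(testable,
                              np.where(beta > 0, "hyper_in_infected", "hypo_in_infected"),
                              ""),
        "testable": testable,
    })
    return out


def fit_beta_binomial_site(m_counts, totals, infected) -> dict:
    """Likelihood-ratio test of an infection effect at one CpG.

    Single-site convenience wrapper around the batched fitter. Returns a
    dict with beta_infection (logit scale), lrt_statistic, p_value,
    direction, and a testable flag; a site with fewer than two covered
    samples in either condition is marked untestable rather than raising.
    """
    out = batch_beta_binomial_lrt(np.asarray(m_counts)[None, :],
                                  np.asarray(totals)[None, :],
                                  np.asarray(infected, dtype=bool))
    return out.iloc[0].to_dict()


def test_differential_methylation(m_matrix: pd.DataFrame, n_matrix: pd.DataFrame,
                                  conditions: pd.Series) -> pd.DataFrame:
    """Run the per-site beta-binomial LRT over a site x sample count matrix.

    ``m_matrix``/``n_matrix`` share an index of sites and one column per
    sample; ``conditions`` maps sample -> {infected, cured}. Untestable
    sites are excluded from the BH denominator.
    """
    samples = list(m_matrix.columns)
    infected = np.array([conditions[s] == "infected" for s in samples])
    out = batch_beta_binomial_lrt(m_matrix.to_numpy(), n_matrix.to_numpy(), infected)
    out.index = m_matrix.index
    testable = out["testable"].to_numpy()
    q = np.full(len(out), np.nan)
    if testable.any():
        q[testable] = adjust_bh(out.loc[testable, "p_value"].to_numpy())
    out["q_value"] = q
    return out


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dmps(results: pd.DataFrame, alpha: float = 0.05):
    """DMPs are testable sites with q strictly below alpha.

    Returns (dmp table, summary) where the summary tallies the hyper/hypo
    direction split with a chi-squared test of equal proportions.
    """
    dmps = results[(results["testable"]) & (results["q_value"] < alpha)].copy()
    dmps["is_dmp"] = True
    n_hyper = int((dmps["direction"] == "hyper_in_infected").sum())
    n_hypo = int(len(dmps) - n_hyper)
    summary = {"n_dmps": int(len(dmps)), "n_hyper": n_hyper, "n_hypo": n_hypo}
    if len(dmps):
        summary["hyper_percent"] = 100.0 * n_hyper / len(dmps)
        chi2, p = chi_square_equal_proportions(n_hyper, n_hypo)
        summary["direction_chi2"] = chi2
        summary["direction_p"] = p
    return dmps, summary


def assign_dmps_to_genes(dmps: pd.DataFrame, genes: pd.DataFrame):
    """Aggregate DMPs into differentially methylated genes.

    A DMP inside any gene span is genic and attributed to every overlapping
    gene; an intergenic DMP is attributed to the gene whose nearest span
    boundary is closest (ties go to the lower-coordinate gene). Returns
    (per-DMP assignment table, per-gene DMG table, summary).
    """
    import warnings as _warnings

    if genes.empty:
        _warnings.warn("empty annotation: all DMPs intergenic and unassigned", stacklevel=2)
        assign = dmps.assign(gene_id="", assignment="unassigned", distance=np.nan)
        return assign, pd.DataFrame(columns=["gene_id", "n_dmps", "assignment"]), {
            "n_genic": 0, "n_intergenic": int(len(dmps)), "n_dmgs": 0}

    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for _, g in genes.iterrows():
        trees.setdefault(g["chrom"], IntervalTree()).addi(g["start"], g["end"] + 1, g["gene_id"])
    rows = []
    n_genic_dmps = 0
    for _, d in dmps.iterrows():
        chrom, pos = d["chrom"], d["pos"]
        hits = sorted(iv.data for iv in trees.get(chrom, IntervalTree()).at(pos))
        if hits:
            n_genic_dmps += 1
            for gid in hits:
                rows.append((chrom, pos, gid, "genic", 0))
        else:
            cand = genes[genes["chrom"] == chrom]
            if cand.empty:
                cand = genes
            dist = np.minimum(np.abs(cand["start"] - pos), np.abs(cand["end"] - pos))
            best = dist.min()
            tied = cand.loc[dist == best].sort_values(["start", "gene_id"], kind="stable")
            rows.append((chrom, pos, tied.iloc[0]["gene_id"], "nearest_gene", int(best)))
    assign = pd.DataFrame(rows, columns=["chrom", "pos", "gene_id", "assignment", "distance"])
    dmgs = (assign.groupby("gene_id")
            .agg(n_dmps=("pos", "size"),
                 assignment=("assignment", lambda a: "genic" if (a == "genic").any() else "nearest_gene"))
            .reset_index())
    summary = {
        "n_genic": n_genic_dmps,
        "n_intergenic": int(len(dmps) - n_genic_dmps),
        "n_dmgs": int(len(dmgs)),
        "mean_dmps_per_dmg": float(dmgs["n_dmps"].mean()) if len(dmgs) else float("nan"),
    }
    return assign, dmgs, summary
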