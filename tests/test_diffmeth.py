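"""Beta-binomial differential methylation: fitter vs independent ML oracle,
BH adjustment, DMP calling and gene aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from wolbmeth import diffmeth

INFECTED = np.array([True, True, True, False, False, False])


# ---------------------------------------------------------------- site choice

def test_select_testable_union(small_config, small_truth):
    rng = np.random.default_rng(0)
    sites = [("chr1", int(p)) for p in rng.choice(10_000, 100, replace=False)]
    frames = []
    for s in range(6):
        status = rng.choice(["methylated", "unmethylated"], 100, p=[0.2, 0.8])
        frames.append(pd.DataFrame({
            "chrom": [c for c, _ in sites], "pos": [p for _, p in sites],
            "sample": f"s{s}", "status": status,
        }))
    calls = pd.concat(frames, ignore_index=True)
    out = diffmeth.select_testable_sites(calls)
    brute = {site for site in sites
             if any(f.loc[[c == site[0] and p == site[1]
                           for c, p in zip(f["chrom"], f["pos"])], "status"].eq("methylated").any()
                    for f in frames)}
    assert set(map(tuple, out.to_records(index=False))) == brute


def test_site_methylated_in_one_sample_is_retained():
    calls = pd.DataFrame({
        "chrom": ["chr1"] * 6, "pos": [10] * 6, "sample": list("abcdef"),
        "status": ["methylated"] + ["unmethylated"] * 5,
    })
    assert len(diffmeth.select_testable_sites(calls)) == 1
    calls["status"] = "unmethylated"
    assert len(diffmeth.select_testable_sites(calls)) == 0


# --------------------------------------------------------------------- fitter

def _oracle_lrt(y, n, x):
    """Independent ML oracle: scipy.stats.betabinom likelihood maximized by
    Nelder-Mead from a grid of starts."""
    def negll(theta, slope):
        b0, b1, s = (theta[0], theta[1], theta[2]) if slope else (theta[0], 0.0, theta[1])
        p = special.expit(np.clip(b0 + b1 * x, -15, 15))
        rho = special.expit(np.clip(s, -18.4, 18.4))
        phi = (1 - rho) / rho
        return -stats.betabinom.logpmf(y, n, p * phi, (1 - p) * phi).sum()

    pbar = np.clip(y.sum() / n.sum(), 1e-4, 1 - 1e-4)
    best_full, best_null = np.inf, np.inf
    for s0 in (-8, -4, -1, 2, 8):
        for d0 in (-2, 0, 2):
            r = optimize.minimize(negll, [special.logit(pbar), d0, s0], args=(True,),
                                  method="Nelder-Mead",
                                  options=dict(maxiter=3000, xatol=1e-10, fatol=1e-12))
            best_full = min(best_full, r.fun)
        r0 = optimize.minimize(negll, [special.logit(pbar), s0], args=(False,),
                               method="Nelder-Mead",
                               options=dict(maxiter=3000, xatol=1e-10, fatol=1e-12))
        best_null = min(best_null, r0.fun)
    return max(0.0, 2.0 * (best_null - best_full))


def test_lrt_matches_grid_search_oracle():
    rng = np.random.default_rng(3)
    n = rng.negative_binomial(10, 10 / 40.0, size=(12, 6)) + 5
    y = rng.binomial(n, rng.uniform(0.05, 0.9, 12)[:, None])
    res = diffmeth.batch_beta_binomial_lrt(y, n, INFECTED)
    for i in range(12):
        oracle = _oracle_lrt(y[i], n[i], INFECTED.astype(float))
        assert res["lrt_statistic"][i] == pytest.approx(oracle, abs=2e-3)


def test_identical_counts_give_null_result():
    out = diffmeth.fit_beta_binomial_site([5] * 6, [10] * 6, INFECTED)
    assert abs(out["beta_infection"]) < 1e-4
    assert out["p_value"] > 0.99


def test_complete_separation_is_significant_and_matches_oracle():
    """All-methylated infected vs all-unmethylated cured. The bounded-
    overdispersion null can absorb a two-point split (rho -> 1 puts all
    mass on 0 and n), so the exact ML answer is LRT = -2*6*log(0.5) =
    8.318 rather than an arbitrarily extreme statistic; the grid-search
    oracle confirms it."""
    out = diffmeth.fit_beta_binomial_site([30, 30, 30, 0, 0, 0], [30] * 6, INFECTED)
    oracle = _oracle_lrt(np.array([30, 30, 30, 0, 0, 0]), np.full(6, 30),
                         INFECTED.astype(float))
    assert out["lrt_statistic"] == pytest.approx(oracle, abs=1e-3)
    assert out["lrt_statistic"] == pytest.approx(-2 * 6 * np.log(0.5), abs=1e-3)
    assert out["p_value"] < 0.01
    assert out["direction"] == "hyper_in_infected"


def test_binomial_limit_agrees_with_logistic_lrt():
    """With the overdispersion pinned at its lower bound the model is a
    binomial logistic regression; the profiled group means must reproduce
    that LRT."""
    import statsmodels.api as sm

    rng = np.random.default_rng(8)
    y = rng.binomial(40, [0.5, 0.55, 0.48, 0.3, 0.33, 0.35])
    n = np.full(6, 40)
    state = diffmeth._ProfileState([y[None, :].astype(float)], [n[None, :].astype(float)])
    ll_null = state(np.full(1, -diffmeth.S_BOUND))
    state_full = diffmeth._ProfileState(
        [y[None, :3].astype(float), y[None, 3:].astype(float)],
        [n[None, :3].astype(float), n[None, 3:].astype(float)])
    ll_full = state_full(np.full(1, -diffmeth.S_BOUND))
    lrt = 2.0 * float((ll_full - ll_null)[0])

    X = sm.add_constant(INFECTED.astype(float))
    full = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial()).fit()
    null = sm.GLM(np.column_stack([y, n - y]), np.ones((6, 1)),
                  family=sm.families.Binomial()).fit()
    lrt_sm = 2.0 * (full.llf - null.llf)
    assert lrt == pytest.approx(lrt_sm, abs=1e-3)


def test_untestable_when_condition_uncovered():
    out = diffmeth.fit_beta_binomial_site([3, 0, 0, 2, 3, 1], [10, 0, 0, 10, 10, 10],
                                          np.array([1, 1, 1, 0, 0, 0], bool))
    assert not out["testable"]
    assert np.isnan(out["p_value"])
    out2 = diffmeth.fit_beta_binomial_site([3, 4, 1, 2, 3, 1], [10, 10, 5, 10, 10, 0],
                                           np.array([1, 1, 1, 0, 0, 0], bool))
    assert out2["testable"]


def test_lrt_nonnegative_on_random_fixtures():
    rng = np.random.default_rng(13)
    n = rng.integers(1, 60, size=(200, 6))
    y = rng.binomial(n, rng.random(200)[:, None])
    res = diffmeth.batch_beta_binomial_lrt(y, n, INFECTED)
    ok = res["testable"]
    assert (res.loc[ok, "lrt_statistic"] >= 0).all()
    assert res.loc[ok, "p_value"].between(0, 1).all()


# ------------------------------------------------------------------------- BH

def test_bh_hand_example():
    q = diffmeth.adjust_bh([0.001, 0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.005, 0.025, 1 / 30, 0.0375, 0.04])


def test_bh_degenerate_inputs():
    assert np.allclose(diffmeth.adjust_bh([1.0, 1.0, 1.0]), 1.0)
    assert diffmeth.adjust_bh([0.07])[0] == pytest.approx(0.07)
    with pytest.raises(ValueError):
        diffmeth.adjust_bh([1.5])


def test_bh_monotone_in_p():
    rng = np.random.default_rng(1)
    p = rng.random(500)
    q = diffmeth.adjust_bh(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


# ----------------------------------------------------------------- DMP calls

def _results_frame(n_hyper, n_hypo, q_sig=0.01, n_null=0):
    rows = []
    for i in range(n_hyper):
        rows.append(("chr1", i + 1, 1.0, q_sig, "hyper_in_infected", True))
    for i in range(n_hypo):
        rows.append(("chr1", 10_000 + i, -1.0, q_sig, "hypo_in_infected", True))
    for i in range(n_null):
        rows.append(("chr1", 20_000 + i, 0.0, 0.9, "hyper_in_infected", True))
    return pd.DataFrame(rows, columns=["chrom", "pos", "beta_infection",
                                       "q_value", "direction", "testable"])


def test_direction_split_reported_as_percent():
    """A 238 / 102 split is 70% hypermethylated with a decisive bias test."""
    dmps, summary = diffmeth.call_dmps(_results_frame(238, 102))
    assert summary["n_dmps"] == 340
    assert summary["hyper_percent"] == pytest.approx(70.0)
    assert summary["direction_chi2"] == pytest.approx(2 * 68 ** 2 / 170)
    assert summary["direction_p"] < 1e-12


def test_q_exactly_alpha_is_not_a_dmp():
    res = _results_frame(1, 0, q_sig=0.05)
    dmps, summary = diffmeth.call_dmps(res, alpha=0.05)
    assert summary["n_dmps"] == 0


def test_dmp_gene_assignment_rules():
    genes = pd.DataFrame({"gene_id": ["A", "B"], "chrom": ["chr1", "chr1"],
                          "start": [1_000, 5_000], "end": [2_000, 6_000]})
    dmps = pd.DataFrame({"chrom": ["chr1"] * 4, "pos": [1_100, 1_200, 1_300, 2_500]})
    assign, dmgs, summary = diffmeth.assign_dmps_to_genes(dmps, genes)
    assert summary["n_genic"] == 3 and summary["n_intergenic"] == 1
    rec = dmgs.set_index("gene_id")
    assert rec.loc["A", "n_dmps"] == 4      # 3 genic + the nearest intergenic (500 < 2500)
    # equidistant DMP between gene A (end 2000) and gene B (start 5000): pos 3500
    tie = diffmeth.assign_dmps_to_genes(
        pd.DataFrame({"chrom": ["chr1"], "pos": [3_500]}), genes)[0]
    assert tie["gene_id"].iloc[0] == "A"    # lower-coordinate gene wins ties
    assert (tie["assignment"] == "nearest_gene").all()


def test_dmp_assignment_matches_bruteforce_join():
    rng = np.random.default_rng(9)
    genes = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(30)], "chrom": "chr1",
        "start": np.arange(30) * 1_000 + 1, "end": np.arange(30) * 1_000 + 600,
    })
    dmps = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(1, 30_000, 300)})
    assign, _, summary = diffmeth.assign_dmps_to_genes(dmps, genes)
    genic = assign[assign["assignment"] == "genic"]
    for _, row in genic.iterrows():
        g = genes.set_index("gene_id").loc[row["gene_id"]]
        assert g["start"] <= row["pos"] <= g["end"]
    n_genic_brute = sum(
        any(s <= p <= e for s, e in zip(genes["start"], genes["end"]))
        for p in dmps["pos"])
    assert summary["n_genic"] == n_genic_brute
    assert summary["n_genic"] + summary["n_intergenic"] == len(dmps)


def test_empty_annotation_warns():
    dmps = pd.DataFrame({"chrom": ["chr1"], "pos": [100]})
    with pytest.warns(UserWarning, match="empty annotation"):
        _, _, summary = diffmeth.assign_dmps_to_genes(dmps, pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end"]))
    assert summary["n_intergenic"] == 1
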