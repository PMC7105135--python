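"""Simulation experiments measuring the pipeline's statistical behavior.

These are the study-condition benchmarks the package ships with: masking
accuracy of the introgression mapper on genomes with known maternal
blocks, type-I error / FDR / power of the differential-methylation test,
calibration and effect recovery of the NB expression test, and coverage
and directionality of the transcriptional-noise regression. Every
experiment regenerates its data from a seed at run time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import diffmeth, expression, introgression, methylation, noise
from .config import SimConfig, substream
from .simulate import _nb_counts

INFECTED6 = np.array([True, True, True, False, False, False])
CONDITIONS6 = pd.Series(["infected"] * 3 + ["cured"] * 3, index=list("abcdef"))


# ------------------------------------------------- printed-tally arithmetic

def dmp_direction_split(n_hyper: int, n_hypo: int) -> dict:
    """Run the DMP summary op on a direction tally (counts as inputs)."""
    rows = [("chr1", i + 1, 1.0 if i < n_hyper else -1.0, 0.01,
             "hyper_in_infected" if i < n_hyper else "hypo_in_infected", True)
            for i in range(n_hyper + n_hypo)]
    results = pd.DataFrame(rows, columns=["chrom", "pos", "beta_infection",
                                          "q_value", "direction", "testable"])
    _, summary = diffmeth.call_dmps(results, alpha=0.05)
    return summary


def deg_direction_split(n_up: int, n_down: int, mean_lfc_up: float = 1.0,
                        mean_lfc_down: float = -1.0) -> dict:
    """Run the fold-change summary op on a DEG direction tally."""
    lfc = np.concatenate([np.full(n_up, mean_lfc_up), np.full(n_down, mean_lfc_down)])
    de = pd.DataFrame({"log2_fold_change": lfc, "is_deg": True})
    return expression.summarize_fold_changes(de)


# --------------------------------------------------- introgression benchmark

def random_block_genome(rng: np.random.Generator, chrom_len: int = 1_000_000,
                        n_blocks: int = 3, block_len: tuple = (80_000, 150_000),
                        snp_spacing: float = 1_000.0):
    """One synthetic genome: known maternal blocks and diagnostic SNPs at a
    mean in-block spacing below 2 kb. Returns (origins, truth_blocks)."""
    starts = np.sort(rng.choice(chrom_len - block_len[1], n_blocks, replace=False))
    blocks = []
    prev_end = 0
    for s in starts:
        s = max(s, prev_end + 20_000)
        e = min(s + int(rng.integers(*block_len)), chrom_len)
        if e > s:
            blocks.append(("chr1", int(s), int(e)))
            prev_end = e
    n_snps = int(chrom_len / snp_spacing)
    pos = np.sort(rng.choice(np.arange(1, chrom_len + 1), n_snps, replace=False))
    maternal = np.zeros(n_snps, dtype=bool)
    for _, s, e in blocks:
        maternal |= (pos >= s) & (pos <= e)
    origins = pd.DataFrame({
        "chrom": "chr1", "pos": pos,
        "origin": np.where(maternal, "maternal", "paternal"),
    })
    truth = pd.DataFrame(blocks, columns=["chrom", "start", "end"])
    return origins, truth


def introgression_masking_accuracy(seed: int, n_genomes: int = 50,
                                   threshold: int = 10_000) -> dict:
    """Base-level recall/precision of maternal-block masking on random
    genomes with known blocks."""
    rng = substream(seed, "mask_benchmark")
    recalls, precisions = [], []
    for _ in range(n_genomes):
        origins, truth = random_block_genome(rng)
        called = introgression.call_maternal_blocks(origins, threshold)
        stats = introgression.block_base_overlap(called, truth)
        recalls.append(stats["recall"])
        precisions.append(stats["precision"])
    return {"recall": float(np.mean(recalls)), "precision": float(np.mean(precisions)),
            "n_genomes": n_genomes}


# ------------------------------------------- differential-methylation suite

def _null_site_counts(rng, n_sites, depth_mean, config: SimConfig):
    """Null WGBS counts for a-priori methylated-mode CpGs (no effect)."""
    a_hi, b_hi = config.meth_high_beta
    p = np.clip(rng.beta(a_hi, b_hi, n_sites), 1e-4, 1 - 1e-4)
    e = config.conversion_error
    p_obs = p + (1 - p) * e
    n = _nb_counts(rng, depth_mean, config.depth_dispersion, (n_sites, 6)) + 1
    y = rng.binomial(n, p_obs[:, None])
    return y, n


def dm_null_type1(seed: int, n_sites: int = 10_000, depth_mean: float = 60.0) -> dict:
    """Per-site type-I error of the beta-binomial LRT at p < 0.05 on null
    methylated-mode sites (3 vs 3, no infection effect)."""
    cfg = SimConfig()
    rng = substream(seed, "dm_type1")
    y, n = _null_site_counts(rng, n_sites, depth_mean, cfg)
    res = diffmeth.batch_beta_binomial_lrt(y, n, INFECTED6)
    pv = res.loc[res["testable"], "p_value"].to_numpy()
    rate = float((pv < 0.05).mean())
    return {"type1_at_05": rate, "n": int(len(pv)),
            "mc_sd": float(np.sqrt(0.05 * 0.95 / len(pv)))}


def dm_null_fdr(seed: int, n_reps: int = 12, n_sites: int = 2_000,
                depth_mean: float = 60.0, alpha: float = 0.05) -> dict:
    """Mean false-discovery proportion of Q < alpha calls across pure-null
    replicates run through classification + testable-site selection."""
    cfg = SimConfig()
    fdps = []
    for rep in range(n_reps):
        rng = substream(seed, f"dm_fdr:{rep}")
        y, n = _null_site_counts(rng, n_sites, depth_mean, cfg)
        # emulate the pipeline: classify each sample, keep sites methylated
        # somewhere (here effectively all of them), then test + BH
        sel = np.zeros(n_sites, dtype=bool)
        for j in range(6):
            sites = pd.DataFrame({"chrom": "c", "pos": np.arange(n_sites) + 1,
                                  "count_methylated": y[:, j], "count_total": n[:, j]})
            calls = methylation.classify_site_methylation(sites, f"s{j}",
                                                          cfg.conversion_error)
            meth_pos = calls.loc[calls["status"] == "methylated", "pos"].to_numpy()
            sel[meth_pos - 1] = True
        res = diffmeth.batch_beta_binomial_lrt(y[sel], n[sel], INFECTED6)
        ok = res["testable"].to_numpy()
        q = diffmeth.adjust_bh(res.loc[ok, "p_value"].to_numpy())
        n_disc = int((q < alpha).sum())
        fdps.append(1.0 if n_disc > 0 else 0.0)  # all discoveries are false
    fdps = np.asarray(fdps)
    return {"mean_fdp": float(fdps.mean()), "n_reps": n_reps,
            "mc_se": float(fdps.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0}


def dm_power(seed: int, n_sites: int = 2_000, frac_effect: float = 0.25,
             delta_logit: float = 2.0, depth_mean: float = 30.0,
             alpha: float = 0.05) -> dict:
    """Power at Q < alpha for a delta_logit shift at moderate base
    methylation (sites where a logit shift is observable)."""
    rng = substream(seed, "dm_power")
    p0 = np.clip(rng.beta(2, 2, n_sites), 0.02, 0.98)
    is_effect = rng.random(n_sites) < frac_effect
    hyper = rng.random(n_sites) < SimConfig().frac_hyper
    shift = np.where(hyper, delta_logit, -delta_logit) * is_effect
    p1 = expit(logit(p0) + shift)
    n = _nb_counts(rng, depth_mean, SimConfig().depth_dispersion, (n_sites, 6)) + 5
    y = np.column_stack([rng.binomial(n[:, :3], p1[:, None]),
                         rng.binomial(n[:, 3:], p0[:, None])])
    res = diffmeth.batch_beta_binomial_lrt(y, n, INFECTED6)
    q = diffmeth.adjust_bh(res["p_value"].to_numpy())
    power = float((q[is_effect] < alpha).mean())
    return {"power": power, "n_effect_sites": int(is_effect.sum())}


# --------------------------------------------- differential-expression suite

def de_null_type1(seed: int, n_genes: int = 2_000) -> dict:
    """Type-I error of the NB LRT on null genes drawn from the simulator's
    expression law (equal dispersion in both conditions)."""
    cfg = SimConfig(noise_inflation_cured=1.0, frac_de=0.0)
    rng = substream(seed, "de_type1")
    mu = np.exp(rng.normal(cfg.base_expression_log_mean, cfg.base_expression_log_sd,
                           n_genes))
    alpha = cfg.dispersion_scale / mu + cfg.dispersion_asymptote
    y = _nb_counts(rng, np.broadcast_to(mu[:, None], (n_genes, 6)),
                   np.broadcast_to(alpha[:, None], (n_genes, 6)))
    counts = pd.DataFrame(y, columns=list("abcdef"))
    sf = expression.estimate_size_factors(counts)
    de = expression.fit_nb_de(counts, sf, CONDITIONS6)
    pv = de.loc[de["tested"], "p_value"].to_numpy()
    rate = float((pv < 0.05).mean())
    return {"type1_at_05": rate, "n": int(len(pv)),
            "mc_sd": float(np.sqrt(0.05 * 0.95 / len(pv)))}


def de_lfc_recovery(seed: int, n_genes: int = 200, true_lfc: float = 2.0,
                    base_mean: float = 500.0) -> dict:
    """Bias of the estimated log2 fold change at a known effect size."""
    cfg = SimConfig()
    rng = substream(seed, "de_recovery")
    mu0 = np.full(n_genes, base_mean)
    alpha = cfg.dispersion_scale / mu0 + cfg.dispersion_asymptote
    mu = np.column_stack([np.tile(mu0 * 2.0 ** true_lfc, (3, 1)).T,
                          np.tile(mu0, (3, 1)).T])
    y = _nb_counts(rng, mu, np.broadcast_to(alpha[:, None], mu.shape))
    counts = pd.DataFrame(y, columns=list("abcdef"))
    de = expression.fit_nb_de(counts, pd.Series(1.0, index=list("abcdef")), CONDITIONS6)
    est = de["log2_fold_change"].to_numpy()
    return {"mean_lfc": float(est.mean()), "bias": float(est.mean() - true_lfc),
            "n_genes": n_genes,
            "frac_within_half": float((np.abs(est - true_lfc) <= 0.5).mean())}


# ------------------------------------------------------- noise-model suite

def noise_coefficient_coverage(seed: int, n_sims: int = 100, n: int = 5_000) -> dict:
    """Fraction of simulations whose 95% CIs cover the true coefficients of
    the noise regression (truth: -0.85 on log2 expression, -0.1 infection)."""
    truth = {"gene_body_methylation": -0.5, "log2_expression": -0.85,
             "log10_length": -0.2, "infected": -0.1}
    rng = substream(seed, "noise_coverage")
    covered = {k: 0 for k in truth}
    for _ in range(n_sims):
        gbm = rng.random(n)
        l2e = rng.uniform(2, 12, n)
        l10l = rng.uniform(2.5, 4.5, n)
        inf = rng.integers(0, 2, n).astype(float)
        y = (1.8 + truth["gene_body_methylation"] * gbm
             + truth["log2_expression"] * l2e + truth["log10_length"] * l10l
             + truth["infected"] * inf + rng.normal(0, 0.4, n))
        records = pd.DataFrame({
            "gene_id": np.arange(n), "condition": np.where(inf == 1, "infected", "cured"),
            "mean_expression": 2.0 ** l2e, "percent_cv": 10.0 ** y,
            "gene_body_methylation": gbm, "gene_length": 10.0 ** l10l,
            "excluded": False,
        })
        fit, _ = noise.fit_noise_regression(records)
        ci = fit.conf_int(alpha=0.05)
        for k, v in truth.items():
            lo, hi = ci.loc[k]
            covered[k] += int(lo <= v <= hi)
    return {"coverage": {k: c / n_sims for k, c in covered.items()},
            "min_coverage": min(c / n_sims for c in covered.values()),
            "n_sims": n_sims}


def noise_infection_direction(seed: int, n_sims: int = 60) -> dict:
    """With cured-condition dispersion inflated, the fitted infection
    coefficient should be negative (infected lines are less noisy)."""
    from .simulate import simulate_expression_counts, simulate_genome_and_annotation

    negative = 0
    for k in range(n_sims):
        cfg = SimConfig(seed=int(substream(seed, f"noise_dir:{k}").integers(2**31)),
                        n_genes=300, n_cpgs=400, n_parental_snps=60,
                        noise_inflation_cured=1.5, frac_de=0.0)
        _, _, _, _, truth = simulate_genome_and_annotation(cfg)
        gene_counts, _ = simulate_expression_counts(cfg, truth)
        sf = expression.estimate_size_factors(gene_counts)
        norm = expression.normalize_counts(gene_counts, sf)
        conditions = truth.samples.set_index("sample")["condition"]
        cv = noise.compute_percent_cv(norm, conditions)
        gbm = truth.cpgs.groupby("gene_id")["base_fraction"].mean()
        records = cv.assign(
            gene_body_methylation=cv["gene_id"].map(gbm).fillna(0.0),
            gene_length=cv["gene_id"].map(
                truth.genes.set_index("gene_id").eval("end - start + 1")),
        )
        _, summary = noise.fit_noise_regression(records)
        negative += int(summary["coefficients"]["infected"] < 0)
    return {"frac_negative": negative / n_sims, "n_sims": n_sims}
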