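"""Transcriptional noise: per-gene, per-condition percent CV and its model.

Noise is the percent coefficient of variation (100 * SD / mean, n-1 SD)
of normalized expression across a condition's replicates. The noise model
is an ordinary least-squares regression:

    log10(percent CV) ~ gene-body methylation + log2(expression)
                        + log10(gene length) + infected

with one observation per gene x condition.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

NOISE_COVARIATES = ["gene_body_methylation", "log2_expression", "log10_length", "infected"]


def compute_percent_cv(norm_counts: pd.DataFrame, conditions: pd.Series) -> pd.DataFrame:
    """Percent CV of normalized counts per gene and condition.

    Genes with zero mean or zero SD in a condition are flagged
    (excluded=True) and dropped from log-scale modeling; their counts are
    reported by the caller. Raises if any condition has < 2 replicates.
    """
    rows = []
    for cond in ("infected", "cured"):
        cols = [s for s in norm_counts.columns if conditions[s] == cond]
        if len(cols) < 2:
            raise ValueError(f"condition {cond!r} has {len(cols)} replicate(s); need >= 2")
        sub = norm_counts[cols].to_numpy(dtype=float)
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = 100.0 * sd / mean
        rows.append(pd.DataFrame({
            "gene_id": norm_counts.index,
            "condition": cond,
            "mean_expression": mean,
            "percent_cv": cv,
            "excluded": (mean <= 0) | (sd <= 0),
        }))
    return pd.concat(rows, ignore_index=True)


def build_noise_records(cv_table: pd.DataFrame, gene_meth: pd.DataFrame,
                        genes: pd.DataFrame) -> pd.DataFrame:
    """Join CV records with condition-matched gene-body methylation and length.

    ``gene_meth`` carries gene_id, condition, mean_fractional_methylation.
    """
    lengths = genes.assign(gene_length=genes["end"] - genes["start"] + 1)[
        ["gene_id", "gene_length"]]
    out = (cv_table.merge(gene_meth, on=["gene_id", "condition"], how="left")
           .merge(lengths, on="gene_id", how="left"))
    return out.rename(columns={"mean_fractional_methylation": "gene_body_methylation"})


def fit_noise_regression(records: pd.DataFrame):
    """OLS of log10(percent CV) on methylation, expression, length, infection.

    Records with zero CV or mean, or missing covariates, are excluded
    (counts reported in the returned summary). Also fits per-condition
    simple regressions of log10(CV) on log2(expression). Returns
    (statsmodels results, summary dict).
    """
    usable = records[
        (~records.get("excluded", False))
        & (records["percent_cv"] > 0)
        & (records["mean_expression"] > 0)
        & records["gene_body_methylation"].notna()
        & (records["gene_length"] > 0)
    ].copy()
    design = pd.DataFrame({
        "gene_body_methylation": usable["gene_body_methylation"],
        "log2_expression": np.log2(usable["mean_expression"]),
        "log10_length": np.log10(usable["gene_length"]),
        "infected": (usable["condition"] == "infected").astype(float),
    })
    X = sm.add_constant(design)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        corr = design.corr().abs()
        np.fill_diagonal(corr.to_numpy(), 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"design matrix rank deficient; check columns {worst}")
    fit = sm.OLS(np.log10(usable["percent_cv"].to_numpy()), X).fit()

    per_condition_slopes = {}
    for cond, sub in usable.groupby("condition"):
        Xc = sm.add_constant(np.log2(sub["mean_expression"].to_numpy()))
        fc = sm.OLS(np.log10(sub["percent_cv"].to_numpy()), Xc).fit()
        per_condition_slopes[cond] = {"slope": float(fc.params[1]),
                                      "p_value": float(fc.pvalues[1])}
    summary = {
        "n_obs": int(fit.nobs),
        "n_excluded": int(len(records) - len(usable)),
        "r_squared": float(fit.rsquared),
        "coefficients": {k: float(v) for k, v in fit.params.items()},
        "std_errors": {k: float(v) for k, v in fit.bse.items()},
        "p_values": {k: float(v) for k, v in fit.pvalues.items()},
        "expression_slope_by_condition": per_condition_slopes,
    }
    return fit, summary


def compare_noise_between_conditions(records: pd.DataFrame) -> dict:
    """Two-sample t-test on log10(percent CV) between infected and cured."""
    groups = {}
    for cond in ("infected", "cured"):
        vals = records.loc[(records["condition"] == cond) & (records["percent_cv"] > 0),
                           "percent_cv"].to_numpy()
        if vals.size == 0:
            raise ValueError(f"no usable noise records for condition {cond!r}")
        groups[cond] = np.log10(vals)
    stat, p = stats.ttest_ind(groups["infected"], groups["cured"])
    return {
        "t_statistic": float(stat),
        "p_value": float(p),
        "mean_log10_cv_infected": float(groups["infected"].mean()),
        "mean_log10_cv_cured": float(groups["cured"].mean()),
        "infected_lower": bool(groups["infected"].mean() < groups["cured"].mean()),
    }


def compare_expression_by_class(expression: pd.Series, classes: pd.Series) -> dict:
    """One-way ANOVA on log-transformed expression across gene classes,
    with Tukey HSD post hoc comparisons.

    Classes with fewer than 2 members are dropped with a warning.
    """
    df = pd.DataFrame({"expression": expression, "cls": classes}).dropna()
    df = df[df["expression"] > 0]
    sizes = df["cls"].value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"dropping classes with < 2 members: {small}", stacklevel=2)
        df = df[~df["cls"].isin(small)]
    if df["cls"].nunique() < 2:
        raise ValueError("need >= 2 non-empty classes")
    logged = np.log2(df["expression"].to_numpy())
    groups = [logged[df["cls"].to_numpy() == c] for c in sorted(df["cls"].unique())]
    f_stat, p = stats.f_oneway(*groups)
    tukey = pairwise_tukeyhsd(logged, df["cls"].to_numpy())
    pairwise = [
        {"group1": str(r[0]), "group2": str(r[1]), "meandiff": float(r[2]),
         "p_adj": float(r[3]), "reject": bool(r[6])}
        for r in tukey.summary().data[1:]
    ]
    return {"f_statistic": float(f_stat), "p_value": float(p), "pairwise": pairwise}
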