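"""Size factors, NB differential expression, fold-change summaries, exon usage."""

import numpy as np
import pandas as pd
import pytest

from wolbmeth import expression as expr

SAMPLES = list("abcdef")
COND = pd.Series(["infected"] * 3 + ["cured"] * 3, index=SAMPLES)


def _counts(mat):
    return pd.DataFrame(np.asarray(mat), columns=SAMPLES,
                        index=[f"g{i}" for i in range(len(mat))])


# --------------------------------------------------------------- size factors

def test_identical_libraries_unit_factors():
    counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
    sf = expr.estimate_size_factors(counts)
    assert np.allclose(sf, 1.0)


def test_doubled_library_median_of_ratios():
    # B = 2 x A exactly: geometric reference is sqrt(2)*A, so factors are
    # (1/sqrt(2), sqrt(2))
    counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
    sf = expr.estimate_size_factors(counts)
    assert sf["a"] == pytest.approx(1 / np.sqrt(2))
    assert sf["b"] == pytest.approx(np.sqrt(2))


def test_size_factor_scale_equivariance():
    """Scaling one library by c scales its factor *relative to the others*
    by c (the geometric-mean reference absorbs a c^(1/m) of the change)."""
    rng = np.random.default_rng(0)
    counts = _counts(rng.integers(1, 500, (50, 6)))
    sf = expr.estimate_size_factors(counts)
    scaled = counts.copy()
    scaled["c"] = scaled["c"] * 3
    sf2 = expr.estimate_size_factors(scaled)
    assert sf2["c"] / sf2["a"] == pytest.approx(3 * sf["c"] / sf["a"])
    assert sf2["c"] == pytest.approx(3 ** (5 / 6) * sf["c"])


def test_size_factors_need_a_common_nonzero_gene():
    counts = pd.DataFrame({"a": [5, 0], "b": [0, 7]})
    with pytest.raises(ValueError, match="pseudo-reference"):
        expr.estimate_size_factors(counts)


def test_normalization_invariant_to_global_rescaling():
    rng = np.random.default_rng(4)
    counts = _counts(rng.integers(1, 300, (40, 6)))
    sf = expr.estimate_size_factors(counts)
    norm = expr.normalize_counts(counts, sf)
    counts2 = counts * 5
    norm2 = expr.normalize_counts(counts2, expr.estimate_size_factors(counts2))
    ratio = (norm2 / norm).to_numpy()
    assert np.allclose(ratio, ratio[0, 0])


# -------------------------------------------------------------------------- DE

def test_constant_gene_has_no_fold_change():
    rng = np.random.default_rng(1)
    mat = rng.integers(20, 200, (40, 6))
    mat[0] = 50
    counts = _counts(mat)
    de = expr.fit_nb_de(counts, pd.Series(1.0, index=SAMPLES), COND)
    assert de.iloc[0]["log2_fold_change"] == pytest.approx(0.0, abs=1e-6)
    assert de.iloc[0]["p_value"] > 0.99


def test_all_zero_gene_excluded_from_testing():
    rng = np.random.default_rng(2)
    mat = rng.integers(20, 200, (30, 6))
    mat[3] = 0
    de = expr.fit_nb_de(_counts(mat), pd.Series(1.0, index=SAMPLES), COND)
    assert not de.iloc[3]["tested"]
    assert np.isnan(de.iloc[3]["q_value"])
    assert de["tested"].sum() == 29


def test_de_requires_two_replicates_per_condition():
    counts = _counts(np.ones((5, 6), int))
    bad = pd.Series(["infected"] * 5 + ["cured"], index=SAMPLES)
    with pytest.raises(ValueError, match="replicates"):
        expr.fit_nb_de(counts, pd.Series(1.0, index=SAMPLES), bad)


def test_strong_effect_recovered():
    rng = np.random.default_rng(3)
    mat = rng.poisson(100, (60, 6))
    mat[5, :3] = rng.poisson(400, 3)   # 4-fold up in infected
    de = expr.fit_nb_de(_counts(mat), pd.Series(1.0, index=SAMPLES), COND)
    assert de.iloc[5]["log2_fold_change"] == pytest.approx(2.0, abs=0.5)
    assert de.iloc[5]["q_value"] < 0.05


# ------------------------------------------------------------------ summaries

def test_fold_change_summary_printed_tallies():
    """45 up of 59 DEGs is 76% up-regulated."""
    lfc = np.concatenate([np.full(45, 1.0), np.full(14, -1.0)])
    de = pd.DataFrame({"log2_fold_change": lfc, "is_deg": True})
    s = expr.summarize_fold_changes(de)
    assert (s["n_up"], s["n_down"]) == (45, 14)
    assert round(s["up_percent"]) == 76


def test_fold_change_linear_scale_average():
    de = pd.DataFrame({"log2_fold_change": [1.0, 3.0], "is_deg": [True, True]})
    s = expr.summarize_fold_changes(de)
    assert s["mean_fold_up"] == pytest.approx((2 + 8) / 2)
    assert "mean_fold_down" not in s


def test_fold_change_empty_deg_set():
    de = pd.DataFrame({"log2_fold_change": [1.0], "is_deg": [False]})
    assert expr.summarize_fold_changes(de)["n_degs"] == 0


# ------------------------------------------------------------------------- DEU

def _exon_fixture(rng, n_genes=30, shift_gene=None, fold=3.0, depth=2_000):
    rows, gene_of = [], {}
    for g in range(n_genes):
        shares = rng.dirichlet(np.full(4, 5.0))
        for s in range(6):
            tot = rng.poisson(depth)
            p = shares.copy()
            if g == shift_gene and s < 3:
                p[0] *= fold
                p /= p.sum()
            counts = rng.multinomial(tot, p)
            for e in range(4):
                rows.append((f"g{g}:e{e}", f"g{g}", SAMPLES[s], counts[e]))
    df = pd.DataFrame(rows, columns=["exon_id", "gene_id", "sample", "count"])
    mat = df.pivot(index="exon_id", columns="sample", values="count")[SAMPLES]
    e2g = df.drop_duplicates("exon_id").set_index("exon_id")["gene_id"]
    return mat, e2g


def test_deu_proportional_counts_are_null():
    rng = np.random.default_rng(5)
    mat, e2g = _exon_fixture(rng)
    deu = expr.fit_deu(mat, e2g, COND)
    assert deu["testable"].all()
    assert not deu["is_deu"].any()


def test_deu_share_shift_detected_with_deep_counts():
    rng = np.random.default_rng(6)
    mat, e2g = _exon_fixture(rng, shift_gene=4, fold=3.0)
    deu = expr.fit_deu(mat, e2g, COND)
    assert deu.loc["g4:e0", "is_deu"]
    assert deu.loc["g4:e0", "usage_log2_change"] > 0


def test_deu_single_exon_gene_and_zero_exon_untestable():
    rng = np.random.default_rng(7)
    mat, e2g = _exon_fixture(rng, n_genes=10)
    lone = pd.DataFrame([[50] * 6], index=["solo:e0"], columns=SAMPLES)
    zero = pd.DataFrame([[0] * 6], index=["g0:e99"], columns=SAMPLES)
    mat2 = pd.concat([mat, lone, zero])
    e2g2 = pd.concat([e2g, pd.Series({"solo:e0": "solo", "g0:e99": "g0"})])
    deu = expr.fit_deu(mat2, e2g2, COND)
    assert not deu.loc["solo:e0", "testable"]
    assert not deu.loc["g0:e99", "testable"]
    assert deu["testable"].sum() == len(mat)   # only the original exons enter BH


def test_deu_label_equivariance_under_exon_permutation():
    rng = np.random.default_rng(8)
    mat, e2g = _exon_fixture(rng, n_genes=6, shift_gene=2)
    perm = mat.sample(frac=1.0, random_state=0)
    a = expr.fit_deu(mat, e2g, COND).sort_index()
    b = expr.fit_deu(perm, e2g.loc[perm.index], COND).sort_index()
    pd.testing.assert_frame_equal(a, b)
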