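"""Overlap statistics across result sets: Fisher's exact tests of DMG vs
DEU-gene, DEG vs DEU-gene and DEG vs DMG overlaps; chi-squared direction
splits for DMPs and DEGs; expression comparison of DEG/DMG/other classes
(one-way ANOVA with Tukey post-hoc tests)."""

import pandas as pd

from _common import INPUTS, RESULTS, parse_seed, stage_dir

import wolbmeth.io as io
from wolbmeth import enrichment, noise
from wolbmeth import expression as expr
from wolbmeth.pipeline import _overlap_test

parse_seed(__doc__)
out = stage_dir("overlap")
samples = pd.read_csv(INPUTS / "sample_sheet.tsv", sep="\t")
conditions = samples.set_index("sample")["condition"]
gene_counts = io.read_count_matrix(INPUTS / "gene_counts.tsv")[list(samples["sample"])]

de = pd.read_csv(RESULTS / "expression" / "de_results.tsv", sep="\t", index_col=0)
deu = pd.read_csv(RESULTS / "expression" / "deu_results.tsv", sep="\t", index_col=0)
dmgs = pd.read_csv(RESULTS / "dm" / "dmgs.tsv", sep="\t")
dm_summary = io.read_json(RESULTS / "dm" / "summary.json")

deg_set = set(de.index[de["is_deg"]])
dmg_set = set(dmgs["gene_id"])
deu_genes = set(deu.loc[deu["is_deu"], "gene_id"])
universe = set(de.index)

overlaps = {
    "dmg_vs_deu_genes": _overlap_test(dmg_set, deu_genes, universe),
    "deg_vs_deu_genes": _overlap_test(deg_set, deu_genes, universe),
    "deg_vs_dmg": _overlap_test(deg_set, dmg_set, universe),
}
for name, o in overlaps.items():
    print(f"{name}: {o['n_overlap']} shared genes, OR = {o['odds_ratio']:.2f}, "
          f"Fisher P = {o['p_value']:.3g}")

if dm_summary.get("n_dmps"):
    chi2, p = enrichment.chi_square_equal_proportions(
        dm_summary["n_hyper"], dm_summary["n_hypo"])
    print(f"DMP direction split {dm_summary['n_hyper']}/{dm_summary['n_hypo']}: "
          f"chi2 = {chi2:.2f}, P = {p:.3g}")

sf = expr.estimate_size_factors(gene_counts)
mean_expr = expr.normalize_counts(gene_counts, sf).mean(axis=1)
classes = pd.Series("other", index=sorted(universe))
classes[classes.index.isin(dmg_set)] = "DMG"
classes[classes.index.isin(deg_set)] = "DEG"
try:
    anova = noise.compare_expression_by_class(mean_expr.reindex(classes.index), classes)
    print(f"expression by class: F = {anova['f_statistic']:.2f}, "
          f"P = {anova['p_value']:.3g}")
except ValueError as exc:
    anova = {"error": str(exc)}
    print(f"expression by class: skipped ({exc})")
io.write_json({"overlaps": overlaps, "expression_by_class": anova}, out / "summary.json")
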