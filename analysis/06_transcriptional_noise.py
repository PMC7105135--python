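"""Model transcriptional noise: per-gene, per-condition percent CV of
normalized expression, the multiple regression log10(CV) ~ gene-body
methylation + log2(expression) + log10(length) + infection, per-condition
expression slopes, and the infected-vs-cured t-test on log10(CV)."""

import pandas as pd

from _common import INPUTS, RESULTS, parse_seed, stage_dir

import wolbmeth.io as io
from wolbmeth import expression as expr
from wolbmeth import noise

parse_seed(__doc__)
out = stage_dir("noise")
samples = pd.read_csv(INPUTS / "sample_sheet.tsv", sep="\t")
conditions = samples.set_index("sample")["condition"]
gene_counts = io.read_count_matrix(INPUTS / "gene_counts.tsv")[list(samples["sample"])]
genes, _ = io.read_gff3(INPUTS / "annotation.gff3")
gene_meth = pd.read_csv(RESULTS / "methylation" / "gene_methylation.tsv", sep="\t")

sf = expr.estimate_size_factors(gene_counts)
norm = expr.normalize_counts(gene_counts, sf)
cv = noise.compute_percent_cv(norm, conditions)
records = noise.build_noise_records(cv, gene_meth, genes)
records.to_csv(out / "noise_records.tsv", sep="\t", index=False)

fit, summary = noise.fit_noise_regression(records)
io.write_json(summary, out / "model.json")
print(f"noise regression on {summary['n_obs']} gene x condition records "
      f"(R^2 = {summary['r_squared']:.3f}, {summary['n_excluded']} excluded):")
for term, coef in summary["coefficients"].items():
    print(f"  {term:>24s} {coef:+.4f}  (P = {summary['p_values'][term]:.3g})")
for cond, s in summary["expression_slope_by_condition"].items():
    print(f"  log2-expression slope in {cond}: {s['slope']:+.3f}")

t = noise.compare_noise_between_conditions(records)
print(f"infected vs cured log10(CV): t = {t['t_statistic']:.2f}, "
      f"P = {t['p_value']:.3g}, infected "
      f"{'lower' if t['infected_lower'] else 'higher'}")
io.write_json(t, out / "condition_test.json")
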