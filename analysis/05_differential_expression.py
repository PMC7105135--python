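"""Normalize libraries with median-of-ratios size factors, test each gene
for an infection effect with the trended-dispersion NB likelihood-ratio
model, summarize DEG direction and linear fold changes, and test each exon
for differential usage conditional on its gene's per-sample totals."""

import pandas as pd

from _common import INPUTS, parse_seed, stage_dir

import wolbmeth.io as io
from wolbmeth import expression as expr

parse_seed(__doc__)
out = stage_dir("expression")
samples = pd.read_csv(INPUTS / "sample_sheet.tsv", sep="\t")
conditions = samples.set_index("sample")["condition"]
gene_counts = io.read_count_matrix(INPUTS / "gene_counts.tsv")[list(samples["sample"])]
exon_counts = io.read_count_matrix(INPUTS / "exon_counts.tsv")[list(samples["sample"])]
_, exons = io.read_gff3(INPUTS / "annotation.gff3")

sf = expr.estimate_size_factors(gene_counts)
sf.to_frame().to_csv(out / "size_factors.tsv", sep="\t")
print("size factors:", ", ".join(f"{s}={v:.3f}" for s, v in sf.items()))

de = expr.fit_nb_de(gene_counts, sf, conditions)
de.to_csv(out / "de_results.tsv", sep="\t")
summary = expr.summarize_fold_changes(de)
print(f"DEGs at Q < 0.05: {summary['n_degs']} "
      f"({summary['n_up']} up / {summary['n_down']} down in infected)")
if summary["n_degs"]:
    print(f"  up fraction {summary['up_percent']:.0f}%; mean fold change "
          f"{summary.get('mean_fold_up', float('nan')):.2f}x up, "
          f"{summary.get('mean_fold_down', float('nan')):.2f}x down")

deu = expr.fit_deu(exon_counts, exons.set_index("exon_id")["gene_id"], conditions, sf)
deu.to_csv(out / "deu_results.tsv", sep="\t")
n_deu = int(deu["is_deu"].sum())
print(f"DEU exons at Q < 0.05: {n_deu} in "
      f"{deu.loc[deu['is_deu'], 'gene_id'].nunique()} genes "
      f"({int(deu['testable'].sum())} exons tested)")
io.write_json({**summary, "n_deu_exons": n_deu}, out / "summary.json")
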