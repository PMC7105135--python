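"""Test each testable CpG (methylated in >= 1 sample) for an infection
effect with the beta-binomial likelihood-ratio regression, control the FDR
at 0.05, tally the hyper/hypo direction split, and aggregate DMPs into
DMGs with nearest-gene assignment for intergenic positions."""

import pandas as pd

from _common import INPUTS, RESULTS, parse_seed, stage_dir

import wolbmeth.io as io
from wolbmeth import diffmeth
from wolbmeth.pipeline import _site_matrices

parse_seed(__doc__)
out = stage_dir("dm")
samples = pd.read_csv(INPUTS / "sample_sheet.tsv", sep="\t")
conditions = samples.set_index("sample")["condition"]
genes, _ = io.read_gff3(INPUTS / "annotation.gff3")
meth_dir = RESULTS / "methylation"

calls, site_counts = {}, {}
for s in samples["sample"]:
    calls[s] = pd.read_csv(meth_dir / f"calls.{s}.tsv", sep="\t")
    site_counts[s] = calls[s][["chrom", "pos", "count_methylated", "count_total"]]

testable = diffmeth.select_testable_sites(pd.concat(calls.values(), ignore_index=True))
print(f"testable CpGs (methylated in >= 1 of {len(samples)} samples): {len(testable)}")

m_mat, n_mat = _site_matrices(testable, site_counts, list(samples["sample"]))
res = diffmeth.test_differential_methylation(m_mat, n_mat, conditions)
res = pd.concat([testable.reset_index(drop=True), res.reset_index(drop=True)], axis=1)
res.to_csv(out / "dmp_results.tsv", sep="\t", index=False)

dmps, summary = diffmeth.call_dmps(res, alpha=0.05)
assign, dmgs, agg = diffmeth.assign_dmps_to_genes(dmps, genes)
dmgs.to_csv(out / "dmgs.tsv", sep="\t", index=False)
io.write_json({**summary, **agg}, out / "summary.json")
print(f"DMPs at Q < 0.05: {summary['n_dmps']} "
      f"({summary['n_hyper']} hyper / {summary['n_hypo']} hypo in infected)")
if summary["n_dmps"]:
    print(f"  hyper fraction {summary['hyper_percent']:.0f}%, "
          f"direction chi2 = {summary['direction_chi2']:.2f} "
          f"(P = {summary['direction_p']:.2g})")
print(f"DMGs: {agg['n_dmgs']} ({agg['n_genic']} genic + "
      f"{agg['n_intergenic']} intergenic DMPs)")
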