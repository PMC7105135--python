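"""Build the CpG methylation landscape: combine plus/minus strand counts
onto CpG units, estimate each sample's bisulfite conversion error from the
lambda spike-in, call per-site methylation status (binomial test against
the error rate, BH at 0.05), mask maternal blocks, and summarize gene-body
methylation per condition with the 0.004 methylated/unmethylated split."""

import pandas as pd

from _common import INPUTS, RESULTS, parse_seed, stage_dir

import wolbmeth.io as io
from wolbmeth import introgression as intro
from wolbmeth import methylation as meth

parse_seed(__doc__)
out = stage_dir("methylation")
samples = pd.read_csv(INPUTS / "sample_sheet.tsv", sep="\t")
genes, _ = io.read_gff3(INPUTS / "annotation.gff3")
blocks = io.bed_to_blocks(io.read_bed(RESULTS / "masking" / "masked_regions.bed"))

conversion, calls = {}, {}
for sample in samples["sample"]:
    combined = meth.combine_strand_counts(
        io.read_strand_counts(INPUTS / f"wgbs.{sample}.strand.tsv"))
    combined, masked = intro.mask_intervals(blocks, combined)
    err = meth.estimate_conversion_error(io.read_site_counts(INPUTS / f"lambda.{sample}.tsv"))
    conversion[sample] = err
    calls[sample] = meth.classify_site_methylation(combined, sample, err)
    calls[sample].to_csv(out / f"calls.{sample}.tsv", sep="\t", index=False)
    n_meth = int((calls[sample]["status"] == "methylated").sum())
    print(f"{sample}: conversion efficiency {100 * (1 - err):.2f}%, "
          f"{masked['n_masked_sites']} CpG units masked, "
          f"{n_meth}/{len(calls[sample])} sites methylated")

# condition-level gene-body methylation (mean of replicate fractions)
gm_parts = []
for cond in ("infected", "cured"):
    cols = samples.loc[samples["condition"] == cond, "sample"]
    frac = pd.concat([calls[s].set_index(["chrom", "pos"])["fractional_methylation"]
                      .rename(s) for s in cols], axis=1).mean(axis=1)
    gm = meth.compute_gene_body_methylation(
        frac.rename("fractional_methylation").reset_index(), genes)
    gm["condition"] = cond
    gm_parts.append(gm)
gene_meth = meth.classify_gene_methylation(pd.concat(gm_parts, ignore_index=True))
gene_meth.to_csv(out / "gene_methylation.tsv", sep="\t", index=False)
io.write_json(conversion, out / "conversion.json")
for cond, sub in gene_meth.groupby("condition"):
    covered = sub[sub["n_cpgs"] > 0]
    print(f"{cond}: {len(covered)} genes with CpGs, "
          f"{(covered['class'] == 'methylated').sum()} methylated-class "
          f"(gene-body mean > 0.004)")
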