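"""Map retained maternal ancestry from diagnostic SNPs: filter genotype
calls (homozygous, depth >= 10, Q >= 30), classify allelic origin against
the parental panel, chain maternal SNPs into blocks at the 10 kb threshold,
and write the union of blocks as the mask applied to all later stages."""

import pandas as pd

from _common import INPUTS, parse_seed, stage_dir

import wolbmeth.io as io
from wolbmeth import introgression as intro

parse_seed(__doc__)
out = stage_dir("masking")
panel = io.read_parental_panel(INPUTS / "parental_panel.tsv")
samples = pd.read_csv(INPUTS / "sample_sheet.tsv", sep="\t")
genome = io.read_json(INPUTS / "genome.json")

all_blocks, summaries = [], {}
for sample in samples["sample"]:
    calls = io.read_snp_calls_vcf(INPUTS / f"snp_calls.{sample}.vcf")
    filtered = intro.filter_snp_calls(calls)
    origins = intro.classify_origin(filtered, panel)
    blocks = intro.call_maternal_blocks(origins, threshold=10_000)
    origins.to_csv(out / f"origin.{sample}.tsv", sep="\t", index=False)
    all_blocks.append(blocks)
    s = intro.summarize_introgression(origins, blocks, sum(genome.values()))
    summaries[sample] = s
    print(f"{sample}: {s['n_maternal_snps']} maternal / {s['n_paternal_snps']} "
          f"paternal SNPs, {s['n_blocks']} blocks, "
          f"{100 * s['maternal_fraction']:.2f}% of genome maternal, "
          f"{100 * (s['frac_adjacent_within_2kb'] or 0):.1f}% of adjacent "
          f"maternal SNPs within 2 kb")

union = pd.concat(all_blocks, ignore_index=True)
from wolbmeth.pipeline import _merge_blocks

merged = _merge_blocks(union)
io.write_bed(intro.blocks_to_bed(merged), out / "masked_regions.bed")
io.write_json(summaries, out / "summary.json")
masked_bp = int((merged['end'] - merged['start'] + 1).sum()) if len(merged) else 0
print(f"union mask: {len(merged)} blocks, {masked_bp:,} bp "
      f"-> {out / 'masked_regions.bed'}")
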