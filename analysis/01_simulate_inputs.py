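"""Generate the synthetic introgression study: three Wolbachia-infected and
three cured clonal lines sharing a paternal nuclear genome except for known
maternal blocks, with WGBS-style CpG counts (lambda spike-in included),
diagnostic-SNP genotype calls, a GFF3 annotation, and gene/exon RNA count
matrices. Ground truth is written alongside the inputs."""

from _common import INPUTS, parse_seed

from wolbmeth.config import SimConfig
from wolbmeth.pipeline import simulate_to_dir
from wolbmeth.simulate import TruthTables
import wolbmeth.io as io

seed = parse_seed(__doc__)
config = SimConfig(seed=seed)
simulate_to_dir(config, INPUTS)
truth = TruthTables.from_dict(io.read_json(INPUTS / "truth.json"))

print(f"inputs written to {INPUTS}")
print(f"  chromosomes: {config.n_chrom} x {config.chrom_len:,} bp")
print(f"  genes: {len(truth.genes)} ({int(truth.genes.is_de.sum())} truly DE, "
      f"{(truth.genes.meth_class == 'methylated').mean():.0%} methylated class)")
print(f"  exons: {len(truth.exons)} ({int(truth.exons.is_deu.sum())} truly DEU)")
print(f"  CpGs: {len(truth.cpgs)} ({int(truth.cpgs.is_effect.sum())} with an "
      f"infection effect, {config.frac_hyper:.0%} hyper)")
print(f"  maternal truth blocks: {truth.maternal_blocks}")
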