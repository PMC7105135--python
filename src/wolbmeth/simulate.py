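"""Synthetic data with known ground truth for every pipeline stage.

Generates post-alignment tables — diagnostic-SNP genotype calls, per-strand
CpG counts with a lambda spike-in, and gene/exon count matrices — for an
introgression design: clonal infected and cured replicate lines sharing a
nuclear genome except for a few retained maternal ancestry blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import SimConfig, substream

_BASES = np.array(list("ACGT"))


@dataclass
class TruthTables:
    """Ground truth emitted alongside the simulated inputs."""

    samples: pd.DataFrame          # sample, condition, line
    genes: pd.DataFrame            # gene_id, chrom, start, end, meth_class, is_de, true_log2fc, base_mean
    exons: pd.DataFrame            # exon_id, gene_id, chrom, start, end, is_deu
    cpgs: pd.DataFrame             # chrom, pos, gene_id, base_fraction, is_effect, direction
    maternal_blocks: list[tuple[str, int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "samples": self.samples.to_dict(orient="list"),
            "genes": self.genes.to_dict(orient="list"),
            "exons": self.exons.to_dict(orient="list"),
            "cpgs": self.cpgs.to_dict(orient="list"),
            "maternal_blocks": [list(b) for b in self.maternal_blocks],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthTables":
        return cls(
            samples=pd.DataFrame(d["samples"]),
            genes=pd.DataFrame(d["genes"]),
            exons=pd.DataFrame(d["exons"]),
            cpgs=pd.DataFrame(d["cpgs"]),
            maternal_blocks=[tuple(b) for b in d["maternal_blocks"]],
        )


def _nb_counts(rng: np.random.Generator, mean, alpha, size=None):
    """NB draw parameterized by mean and dispersion (var = mu + alpha*mu^2)."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        return rng.poisson(mean, size=size)
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha, size=size)
    return rng.poisson(lam)


def _in_blocks(chrom: np.ndarray, pos: np.ndarray, blocks) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for bc, bs, be in blocks:
        mask |= (chrom == bc) & (pos >= bs) & (pos <= be)
    return mask


def simulate_genome_and_annotation(config: SimConfig):
    """Simulate annotation, parental diagnostic-SNP panel, and per-line genotypes.

    Returns (genes, exons, panel, genotypes, truth) where genotypes maps
    sample id -> SNP call table. Calls inside a truth maternal block carry
    the maternal allele, outside the paternal allele, up to the configured
    misclassification rate.
    """
    config.validate()
    chroms = config.chrom_names()
    samples = config.sample_sheet()

    # --- genes and exons: non-overlapping genes tiled per chromosome ---
    rng = substream(config.seed, "annotation")
    per_chrom = np.full(config.n_chrom, config.n_genes // config.n_chrom)
    per_chrom[: config.n_genes % config.n_chrom] += 1
    gene_rows, exon_rows = [], []
    gidx = 0
    for chrom, n_here in zip(chroms, per_chrom):
        slot = config.chrom_len // max(n_here, 1)
        for k in range(n_here):
            gidx += 1
            gid = f"G{gidx:05d}"
            slot_start = k * slot + 1
            glen = int(rng.integers(int(slot * 0.2), int(slot * 0.8)))
            gstart = slot_start + int(rng.integers(0, max(slot - glen, 1)))
            gend = min(gstart + glen - 1, config.chrom_len)
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            n_ex = min(n_ex, max(1, (gend - gstart) // 2))  # tiny gene: fewer exons
            # split the gene span into 2*n_ex-1 alternating exon/intron pieces
            cuts = np.sort(rng.choice(np.arange(gstart + 1, gend + 1), size=2 * n_ex - 2,
                                      replace=False)) if n_ex > 1 else np.array([], dtype=int)
            bounds = np.concatenate([[gstart], cuts, [gend + 1]])
            for e in range(n_ex):
                es, ee = int(bounds[2 * e]), int(bounds[2 * e + 1]) - 1
                exon_rows.append((f"{gid}:E{e + 1:03d}", gid, chrom, es, max(ee, es)))
            gene_rows.append((gid, chrom, gstart, gend))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end"])
    exons = pd.DataFrame(exon_rows, columns=["exon_id", "gene_id", "chrom", "start", "end"])

    # --- gene-level truth: methylation class, DE status, expression law ---
    rng = substream(config.seed, "gene_truth")
    n = len(genes)
    meth_class = np.where(rng.random(n) < config.frac_genes_methylated, "methylated", "unmethylated")
    is_de = rng.random(n) < config.frac_de
    lfc = np.abs(rng.normal(config.lfc_mean, config.lfc_sd, n))
    sign = np.where(rng.random(n) < config.frac_up_de, 1.0, -1.0)
    true_log2fc = np.where(is_de, sign * lfc, 0.0)
    base_mean = np.exp(rng.normal(config.base_expression_log_mean, config.base_expression_log_sd, n))
    genes = genes.assign(meth_class=meth_class, is_de=is_de,
                         true_log2fc=true_log2fc, base_mean=base_mean)

    # one altered exon per DEU gene (multi-exon genes only)
    rng = substream(config.seed, "deu_truth")
    exons = exons.assign(is_deu=False)
    n_ex_per_gene = exons.groupby("gene_id")["exon_id"].transform("size")
    eligible = genes.loc[genes.gene_id.isin(exons.loc[n_ex_per_gene >= 2, "gene_id"]), "gene_id"]
    deu_genes = eligible[rng.random(len(eligible)) < config.frac_deu]
    for gid in deu_genes:
        idx = exons.index[exons.gene_id == gid]
        exons.loc[rng.choice(idx), "is_deu"] = True

    # --- parental diagnostic-SNP panel and per-line genotype calls ---
    rng = substream(config.seed, "snps")
    n_per_chrom = np.full(config.n_chrom, config.n_parental_snps // config.n_chrom)
    n_per_chrom[: config.n_parental_snps % config.n_chrom] += 1
    panel_parts = []
    for chrom, n_here in zip(chroms, n_per_chrom):
        pos = np.sort(rng.choice(np.arange(1, config.chrom_len + 1), size=n_here, replace=False))
        mat = rng.integers(0, 4, n_here)
        pat = (mat + rng.integers(1, 4, n_here)) % 4  # always differs from maternal
        panel_parts.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "maternal_allele": _BASES[mat], "paternal_allele": _BASES[pat],
        }))
    panel = pd.concat(panel_parts, ignore_index=True)

    genotypes: dict[str, pd.DataFrame] = {}
    in_block = _in_blocks(panel["chrom"].to_numpy(), panel["pos"].to_numpy(),
                          config.maternal_block_spec)
    for sample in samples["sample"]:
        rng_s = substream(config.seed, f"genotype:{sample}")
        maternal = in_block.copy()
        if config.origin_misclassification_rate > 0:
            flip = rng_s.random(len(panel)) < config.origin_misclassification_rate
            maternal = maternal ^ flip
        allele = np.where(maternal, panel["maternal_allele"], panel["paternal_allele"])
        depth = _nb_counts(rng_s, config.depth_mean, config.depth_dispersion, len(panel))
        qual = np.round(np.clip(rng_s.normal(45, 8, len(panel)), 5, 90), 1)
        genotypes[sample] = pd.DataFrame({
            "chrom": panel["chrom"], "pos": panel["pos"], "allele": allele,
            "zygosity": "hom", "depth": depth, "quality": qual,
        })

    # --- CpG truth: positions (paired-strand Cs), base fractions, effects ---
    rng = substream(config.seed, "cpg_truth")
    n_cpg_per_chrom = np.full(config.n_chrom, config.n_cpgs // config.n_chrom)
    n_cpg_per_chrom[: config.n_cpgs % config.n_chrom] += 1
    cpg_parts = []
    for chrom, n_here in zip(chroms, n_cpg_per_chrom):
        # even positions so the CpG unit (pos, pos+1) never collides with the next
        pos = np.sort(rng.choice(np.arange(2, config.chrom_len - 1, 2), size=n_here, replace=False))
        cpg_parts.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    cpgs = pd.concat(cpg_parts, ignore_index=True)

    # assign CpGs to genes (genes are non-overlapping by construction)
    cpgs["gene_id"] = ""
    for chrom, sub in genes.groupby("chrom"):
        sel = cpgs["chrom"] == chrom
        pos = cpgs.loc[sel, "pos"].to_numpy()
        starts = sub["start"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        hit = (idx >= 0) & (pos <= sub["end"].to_numpy()[np.clip(idx, 0, None)])
        gids = np.where(hit, sub["gene_id"].to_numpy()[np.clip(idx, 0, None)], "")
        cpgs.loc[sel, "gene_id"] = gids

    gene_class = genes.set_index("gene_id")["meth_class"]
    in_meth_gene = cpgs["gene_id"].map(gene_class).eq("methylated").to_numpy()
    a_lo, b_lo = config.meth_low_beta
    a_hi, b_hi = config.meth_high_beta
    base = np.where(in_meth_gene, rng.beta(a_hi, b_hi, len(cpgs)), rng.beta(a_lo, b_lo, len(cpgs)))
    base = np.clip(base, 1e-4, 1 - 1e-4)
    is_effect = rng.random(len(cpgs)) < config.frac_dmp
    direction = np.where(rng.random(len(cpgs)) < config.frac_hyper, "hyper", "hypo")
    direction = np.where(is_effect, direction, "")
    cpgs = cpgs.assign(base_fraction=base, is_effect=is_effect, direction=direction)

    truth = TruthTables(samples=samples, genes=genes, exons=exons, cpgs=cpgs,
                        maternal_blocks=list(config.maternal_block_spec))
    return genes.drop(columns=["meth_class", "is_de", "true_log2fc", "base_mean"]), \
        exons.drop(columns=["is_deu"]), panel, genotypes, truth


def true_cpg_fraction(truth: TruthTables, config: SimConfig, condition: str) -> np.ndarray:
    """Underlying methylation fraction per CpG in one condition.

    Effect CpGs are shifted by delta_logit on the logit scale in infected
    samples, upward for hyper sites and downward for hypo sites.
    """
    base = truth.cpgs["base_fraction"].to_numpy()
    if condition != "infected":
        return base
    shift = np.where(truth.cpgs["direction"].to_numpy() == "hyper",
                     config.delta_logit, -config.delta_logit)
    shift = np.where(truth.cpgs["is_effect"].to_numpy(), shift, 0.0)
    return expit(logit(base) + shift)


def simulate_wgbs_counts(config: SimConfig, truth: TruthTables):
    """Per-sample per-strand CpG count tables plus lambda spike-in counts.

    The plus-strand C sits at the CpG position, the minus-strand C at
    position + 1; each strand receives an independent NB depth. Observed
    methylated counts include conversion-error false positives. Lambda
    sites have true methylation 0.

    Returns (strand_counts, lambda_counts): dicts sample -> DataFrame.
    """
    config.validate()
    frac_by_cond = {c: true_cpg_fraction(truth, config, c)
                    for c in ("infected", "cured")}
    e = config.conversion_error
    strand_counts: dict[str, pd.DataFrame] = {}
    lambda_counts: dict[str, pd.DataFrame] = {}
    n_sites = len(truth.cpgs)
    for _, row in truth.samples.iterrows():
        sample = row["sample"]
        rng = substream(config.seed, f"wgbs:{sample}")
        p_true = frac_by_cond[row["condition"]]
        p_obs = p_true + (1.0 - p_true) * e
        parts = []
        for strand, offset in (("+", 0), ("-", 1)):
            depth = _nb_counts(rng, config.depth_mean / 2.0, config.depth_dispersion, n_sites)
            m = rng.binomial(depth, p_obs)
            parts.append(pd.DataFrame({
                "chrom": truth.cpgs["chrom"],
                "pos": truth.cpgs["pos"] + offset,
                "strand": strand,
                "count_methylated": m,
                "count_unmethylated": depth - m,
            }))
        df = pd.concat(parts, ignore_index=True)
        strand_counts[sample] = df.sort_values(["chrom", "pos"]).reset_index(drop=True)

        lam_depth = _nb_counts(rng, config.depth_mean, config.depth_dispersion,
                               config.n_lambda_sites)
        lam_m = rng.binomial(lam_depth, e)
        lambda_counts[sample] = pd.DataFrame({
            "chrom": "lambda",
            "pos": np.arange(1, config.n_lambda_sites + 1),
            "count_methylated": lam_m,
            "count_total": lam_depth,
        })
    return strand_counts, lambda_counts


def simulate_expression_counts(config: SimConfig, truth: TruthTables):
    """NB gene counts and multinomially split exon counts, with truth effects.

    Cured-condition dispersion is multiplied by ``noise_inflation_cured``;
    DE genes carry their true log2 fold change in infected samples; the
    altered exon of a DEU gene has its proportional share multiplied by
    ``deu_fold`` in infected samples. Exon counts sum to gene counts per
    sample by construction.

    Returns (gene_counts, exon_counts): DataFrames indexed by id with one
    column per sample.
    """
    config.validate()
    genes = truth.genes
    exons = truth.exons.sort_values(["gene_id", "start"], kind="stable")
    n = len(genes)
    rng = substream(config.seed, "expression_setup")
    lib = np.exp(rng.normal(0.0, config.library_size_log_sd, len(truth.samples)))
    alpha0 = config.dispersion_scale / genes["base_mean"].to_numpy() + config.dispersion_asymptote
    # fixed per-gene exon shares (Dirichlet), shared across samples
    shares: dict[str, np.ndarray] = {}
    for gid, sub in exons.groupby("gene_id", sort=False):
        shares[gid] = rng.dirichlet(np.full(len(sub), 5.0))

    gene_cols, exon_cols = {}, {}
    exon_index = exons["exon_id"].to_numpy()
    for j, (_, row) in enumerate(truth.samples.iterrows()):
        sample, cond = row["sample"], row["condition"]
        rng_s = substream(config.seed, f"expression:{sample}")
        mu = genes["base_mean"].to_numpy() * lib[j]
        if cond == "infected":
            mu = mu * 2.0 ** genes["true_log2fc"].to_numpy()
        alpha = alpha0 * (config.noise_inflation_cured if cond == "cured" else 1.0)
        counts = _nb_counts(rng_s, mu, alpha)
        gene_cols[sample] = counts

        ecounts = np.zeros(len(exons), dtype=np.int64)
        off = 0
        counts_by_gene = dict(zip(genes["gene_id"], counts))
        for gid, sub in exons.groupby("gene_id", sort=False):
            k = len(sub)
            p = shares[gid].copy()
            if cond == "infected" and sub["is_deu"].any():
                p[sub["is_deu"].to_numpy()] *= config.deu_fold
                p /= p.sum()
            ecounts[off:off + k] = rng_s.multinomial(counts_by_gene[gid], p)
            off += k
        exon_cols[sample] = ecounts

    gene_counts = pd.DataFrame(gene_cols, index=genes["gene_id"].to_numpy())
    gene_counts.index.name = "gene_id"
    exon_counts = pd.DataFrame(exon_cols, index=exon_index)
    exon_counts.index.name = "exon_id"
    return gene_counts, exon_counts
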