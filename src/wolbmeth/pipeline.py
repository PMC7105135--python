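"""End-to-end orchestration: introgression masking, methylation calls,
differential methylation/expression/exon usage, noise model, overlaps.

All sites and genes overlapping a maternal ancestry block are excluded
before any statistic is computed (the masking rule); ``--no-mask`` style
sensitivity reruns simply disable that exclusion.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffmeth, enrichment, expression, introgression, io, methylation, noise
from .config import PipelineConfig, SimConfig

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


# ------------------------------------------------------------- input writing

def simulate_to_dir(config: SimConfig, input_dir) -> None:
    """Generate every pipeline input file (plus truth) into a directory."""
    from . import simulate

    input_dir = Path(input_dir)
    input_dir.mkdir(parents=True, exist_ok=True)
    genes, exons, panel, genotypes, truth = simulate.simulate_genome_and_annotation(config)
    strand_counts, lambda_counts = simulate.simulate_wgbs_counts(config, truth)
    gene_counts, exon_counts = simulate.simulate_expression_counts(config, truth)

    io.write_gff3(genes, exons, input_dir / "annotation.gff3")
    io.write_parental_panel(panel, input_dir / "parental_panel.tsv")
    truth.samples.to_csv(input_dir / "sample_sheet.tsv", sep="\t", index=False)
    contigs = {c: config.chrom_len for c in config.chrom_names()}
    io.write_json(contigs, input_dir / "genome.json")
    for sample in truth.samples["sample"]:
        io.write_snp_calls_vcf(genotypes[sample], input_dir / f"snp_calls.{sample}.vcf",
                               contig_lengths=contigs, sample=sample)
        io.write_strand_counts(strand_counts[sample], input_dir / f"wgbs.{sample}.strand.tsv")
        io.write_site_counts(lambda_counts[sample], input_dir / f"lambda.{sample}.tsv")
    io.write_count_matrix(gene_counts, input_dir / "gene_counts.tsv")
    io.write_count_matrix(exon_counts, input_dir / "exon_counts.tsv")
    io.write_json(truth.to_dict(), input_dir / "truth.json")


# ------------------------------------------------------------- input reading

def read_inputs(input_dir) -> dict:
    """Load and validate every pipeline input from a directory."""
    input_dir = Path(input_dir)
    samples = pd.read_csv(input_dir / "sample_sheet.tsv", sep="\t")
    bad_cond = set(samples["condition"]) - {"infected", "cured"}
    if bad_cond:
        raise ValueError(f"sample sheet conditions must be infected/cured, got {bad_cond}")
    genes, exons = io.read_gff3(input_dir / "annotation.gff3")
    data = {
        "samples": samples,
        "genes": genes,
        "exons": exons,
        "panel": io.read_parental_panel(input_dir / "parental_panel.tsv"),
        "genome": io.read_json(input_dir / "genome.json"),
        "snp_calls": {}, "strand_counts": {}, "lambda_counts": {},
    }
    for sample in samples["sample"]:
        vcf = input_dir / f"snp_calls.{sample}.vcf"
        tsv = input_dir / f"snp_calls.{sample}.tsv"
        data["snp_calls"][sample] = (io.read_snp_calls_vcf(vcf) if vcf.exists()
                                     else io.read_snp_calls_tsv(tsv))
        data["strand_counts"][sample] = io.read_strand_counts(
            input_dir / f"wgbs.{sample}.strand.tsv")
        data["lambda_counts"][sample] = io.read_site_counts(input_dir / f"lambda.{sample}.tsv")
    gene_counts = io.read_count_matrix(input_dir / "gene_counts.tsv")
    exon_counts = io.read_count_matrix(input_dir / "exon_counts.tsv")
    missing = set(samples["sample"]) - set(gene_counts.columns)
    if missing:
        raise ValueError(f"samples missing from gene count matrix: {sorted(missing)}")
    data["gene_counts"] = gene_counts[list(samples["sample"])]
    data["exon_counts"] = exon_counts[list(samples["sample"])]
    return data


# ---------------------------------------------------------------- the stages

def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write stage tables plus a run report."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = read_inputs(config.input_dir)
    samples = data["samples"]
    conditions = samples.set_index("sample")["condition"]
    report: dict = {"version": __version__, "seed": config.seed,
                    "parameters": {
                        "introgression_threshold_bp": config.introgression_threshold_bp,
                        "min_depth": config.min_depth, "min_quality": config.min_quality,
                        "alpha": config.alpha,
                        "gene_methylation_threshold": config.gene_methylation_threshold,
                        "mask_maternal": config.mask_maternal,
                    }, "stages": {}}

    # -- introgression: per-sample origin calls, union of maternal blocks --
    genome_size = int(sum(data["genome"].values()))
    block_parts = []
    origin_summaries = {}
    for sample in samples["sample"]:
        filtered = introgression.filter_snp_calls(
            data["snp_calls"][sample], config.min_depth, config.min_quality)
        origins = introgression.classify_origin(filtered, data["panel"])
        blocks = introgression.call_maternal_blocks(
            origins, config.introgression_threshold_bp)
        block_parts.append(blocks)
        origin_summaries[sample] = introgression.summarize_introgression(
            origins, blocks, genome_size)
        origins.to_csv(out / f"origin.{sample}.tsv", sep="\t", index=False)
    merged = _merge_blocks(pd.concat(block_parts, ignore_index=True))
    io.write_bed(introgression.blocks_to_bed(merged), out / "masked_regions.bed")
    report["stages"]["introgression"] = {
        "per_sample": origin_summaries,
        "n_masked_blocks": int(len(merged)),
        "masked_bp": int((merged["end"] - merged["start"] + 1).sum()) if len(merged) else 0,
    }
    mask_blocks = merged if config.mask_maternal else merged.iloc[0:0]

    # -- genes overlapping masked blocks are excluded everywhere --
    genes = data["genes"]
    gene_masked = np.zeros(len(genes), dtype=bool)
    for _, blk in mask_blocks.iterrows():
        gene_masked |= ((genes["chrom"] == blk["chrom"])
                        & (genes["start"] <= blk["end"])
                        & (genes["end"] >= blk["start"])).to_numpy()
    kept_genes = genes.loc[~gene_masked].reset_index(drop=True)
    report["stages"]["masking"] = {"n_genes_masked": int(gene_masked.sum()),
                                   "n_genes_kept": int(len(kept_genes))}

    # -- strand combination, conversion error, site classification --
    site_counts, calls = {}, {}
    conv = {}
    for sample in samples["sample"]:
        combined = methylation.combine_strand_counts(data["strand_counts"][sample])
        combined, _ = introgression.mask_intervals(mask_blocks, combined)
        site_counts[sample] = combined
        conv[sample] = methylation.estimate_conversion_error(data["lambda_counts"][sample])
        calls[sample] = methylation.classify_site_methylation(
            combined, sample, conv[sample], config.alpha)
        io.write_site_counts(combined, out / f"cpg_counts.{sample}.tsv")
    all_calls = pd.concat(calls.values(), ignore_index=True)
    testable = diffmeth.select_testable_sites(all_calls)
    report["stages"]["methylation"] = {
        "conversion_error": conv,
        "conversion_efficiency_percent": {s: 100 * (1 - e) for s, e in conv.items()},
        "n_testable_sites": int(len(testable)),
    }

    # -- differential methylation --
    m_mat, n_mat = _site_matrices(testable, site_counts, list(samples["sample"]))
    dm = diffmeth.test_differential_methylation(m_mat, n_mat, conditions)
    dm = pd.concat([testable.reset_index(drop=True), dm.reset_index(drop=True)], axis=1)
    dm.to_csv(out / "dmp_results.tsv", sep="\t", index=False)
    dmps, dmp_summary = diffmeth.call_dmps(dm, config.alpha)
    assign, dmgs, dmg_summary = diffmeth.assign_dmps_to_genes(dmps, kept_genes)
    dmgs.to_csv(out / "dmgs.tsv", sep="\t", index=False)
    report["stages"]["differential_methylation"] = {**dmp_summary, **dmg_summary}

    # -- expression: size factors, DE, fold-change summary, DEU --
    gene_counts = data["gene_counts"].loc[
        data["gene_counts"].index.isin(kept_genes["gene_id"])]
    sf = expression.estimate_size_factors(gene_counts)
    de = expression.fit_nb_de(gene_counts, sf, conditions, config.alpha)
    de.to_csv(out / "de_results.tsv", sep="\t")
    fc_summary = expression.summarize_fold_changes(de)
    exon_to_gene = data["exons"].set_index("exon_id")["gene_id"]
    exon_counts = data["exon_counts"].loc[
        data["exon_counts"].index.map(exon_to_gene).isin(kept_genes["gene_id"])]
    deu = expression.fit_deu(exon_counts, exon_to_gene, conditions, sf, config.alpha)
    deu.to_csv(out / "deu_results.tsv", sep="\t")
    report["stages"]["differential_expression"] = {
        "size_factors": sf.to_dict(), **fc_summary,
        "n_genes_tested": int(de["tested"].sum()),
    }
    report["stages"]["differential_exon_usage"] = {
        "n_exons_tested": int(deu["testable"].sum()),
        "n_deu_exons": int(deu["is_deu"].sum()),
        "n_deu_genes": int(deu.loc[deu["is_deu"], "gene_id"].nunique()),
    }

    # -- gene-body methylation per condition + gene classes --
    gm_parts = []
    for cond in ("infected", "cured"):
        cols = samples.loc[samples["condition"] == cond, "sample"]
        frames = []
        for s in cols:
            c = calls[s]
            frames.append(c.set_index(["chrom", "pos"])["fractional_methylation"].rename(s))
        frac = pd.concat(frames, axis=1).mean(axis=1).rename("fractional_methylation")
        frac = frac.reset_index()
        gm = methylation.compute_gene_body_methylation(frac, kept_genes)
        gm["condition"] = cond
        gm_parts.append(gm)
    gene_meth = pd.concat(gm_parts, ignore_index=True)
    gene_meth = methylation.classify_gene_methylation(
        gene_meth, config.gene_methylation_threshold)
    gene_meth.to_csv(out / "gene_methylation.tsv", sep="\t", index=False)

    # -- transcriptional noise --
    norm = expression.normalize_counts(gene_counts, sf)
    cv = noise.compute_percent_cv(norm, conditions)
    records = noise.build_noise_records(cv, gene_meth, kept_genes)
    records.to_csv(out / "noise_records.tsv", sep="\t", index=False)
    _, noise_summary = noise.fit_noise_regression(records)
    noise_ttest = noise.compare_noise_between_conditions(records)
    report["stages"]["noise"] = {"model": noise_summary, "condition_t_test": noise_ttest}

    # -- gene-class expression comparison + overlap statistics --
    deg_set = set(de.index[de["is_deg"]])
    dmg_set = set(dmgs["gene_id"])
    deu_gene_set = set(deu.loc[deu["is_deu"], "gene_id"])
    universe = set(kept_genes["gene_id"]) & set(gene_counts.index)
    cls = pd.Series("other", index=sorted(universe))
    cls[cls.index.isin(dmg_set)] = "DMG"
    cls[cls.index.isin(deg_set)] = "DEG"
    mean_expr = norm.mean(axis=1).reindex(cls.index)
    try:
        class_cmp = noise.compare_expression_by_class(mean_expr, cls)
    except ValueError as exc:
        class_cmp = {"error": str(exc)}
    overlaps = {
        "dmg_vs_deu_genes": _overlap_test(dmg_set, deu_gene_set, universe),
        "deg_vs_deu_genes": _overlap_test(deg_set, deu_gene_set, universe),
        "deg_vs_dmg": _overlap_test(deg_set, dmg_set, universe),
    }
    report["stages"]["overlaps"] = overlaps
    report["stages"]["expression_by_class"] = class_cmp

    write_report(report, out)
    return report


def _merge_blocks(blocks: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly overlapping blocks across samples."""
    if blocks.empty:
        return blocks
    rows = []
    for chrom, sub in blocks.sort_values(["chrom", "start"]).groupby("chrom"):
        cur_s = cur_e = None
        for _, r in sub.iterrows():
            if cur_s is None:
                cur_s, cur_e = r["start"], r["end"]
            elif r["start"] <= cur_e + 1:
                cur_e = max(cur_e, r["end"])
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = r["start"], r["end"]
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _site_matrices(sites: pd.DataFrame, site_counts: dict, sample_order: list):
    """Methylated/total count matrices (site x sample) for the testable sites."""
    key = pd.MultiIndex.from_frame(sites[["chrom", "pos"]])
    m_cols, n_cols = {}, {}
    for s in sample_order:
        tab = site_counts[s].set_index(["chrom", "pos"])
        m_cols[s] = tab["count_methylated"].reindex(key, fill_value=0).to_numpy()
        n_cols[s] = tab["count_total"].reindex(key, fill_value=0).to_numpy()
    return pd.DataFrame(m_cols), pd.DataFrame(n_cols)


def _overlap_test(set_a: set, set_b: set, universe: set) -> dict:
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    res = enrichment.fisher_exact_2x2(a, b, c, d)
    return {"n_overlap": a, "n_a_only": b, "n_b_only": c, "n_neither": d, **res}


def write_report(report: dict, out_dir) -> None:
    """Machine-readable JSON plus a short text summary of headline tallies."""
    out_dir = Path(out_dir)
    io.write_json(report, out_dir / "report.json")
    dm = report["stages"].get("differential_methylation", {})
    de = report["stages"].get("differential_expression", {})
    deu = report["stages"].get("differential_exon_usage", {})
    ov = report["stages"].get("overlaps", {}).get("dmg_vs_deu_genes", {})
    lines = [
        "wolbmeth run summary",
        "====================",
        f"testable CpGs: {report['stages'].get('methylation', {}).get('n_testable_sites', 0)}",
        f"DMPs: {dm.get('n_dmps', 0)} ({dm.get('n_hyper', 0)} hyper / {dm.get('n_hypo', 0)} hypo"
        + (f"; {dm.get('hyper_percent'):.0f}% hyper" if dm.get("n_dmps") else "") + ")",
        f"DMGs: {dm.get('n_dmgs', 0)} "
        f"({dm.get('n_genic', 0)} genic + {dm.get('n_intergenic', 0)} intergenic DMPs)",
        f"DEGs: {de.get('n_degs', 0)} ({de.get('n_up', 0)} up / {de.get('n_down', 0)} down"
        + (f"; {de.get('up_percent'):.0f}% up" if de.get("n_degs") else "") + ")",
        f"DEU exons: {deu.get('n_deu_exons', 0)} in {deu.get('n_deu_genes', 0)} genes",
    ]
    if ov:
        lines.append(
            f"DMG/DEU-gene overlap: {ov.get('n_overlap', 0)} genes, "
            f"OR={ov.get('odds_ratio', float('nan')):.2f}, P={ov.get('p_value', float('nan')):.3g}")
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
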