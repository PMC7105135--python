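"""Readers and writers for the pipeline's on-disk formats.

Coordinates are normalized to 1-based inclusive internally; BED output is
0-based half-open. Parsers raise errors that carry the file and line
number of the offending record.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


class ParseError(ValueError):
    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------- CpG counts

STRAND_COLUMNS = ["chrom", "pos", "strand", "count_methylated", "count_unmethylated"]


def write_strand_counts(df: pd.DataFrame, path) -> None:
    df[STRAND_COLUMNS].to_csv(path, sep="\t", index=False)


def read_strand_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(STRAND_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns {sorted(missing)}")
    bad = df.index[(df["count_methylated"] < 0) | (df["count_unmethylated"] < 0)]
    if len(bad):
        raise ParseError(path, int(bad[0]) + 2, "negative count")
    return df


def write_site_counts(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "count_methylated", "count_total"]].to_csv(path, sep="\t", index=False)


def read_site_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    bad = df.index[df["count_methylated"] > df["count_total"]]
    if len(bad):
        raise ParseError(path, int(bad[0]) + 2, "methylated count exceeds total")
    return df


# ------------------------------------------------------------------ SNP calls

def write_snp_calls_vcf(calls: pd.DataFrame, path, contig_lengths: dict | None = None,
                        sample: str = "sample") -> None:
    """Minimal single-sample VCF with GT, DP and GQ."""
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in (contig_lengths or {}).items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for _, r in calls.iterrows():
        gt = "1/1" if r["zygosity"] == "hom" else "0/1"
        lines.append(
            f"{r['chrom']}\t{r['pos']}\t.\tN\t{r['allele']}\t{r['quality']:.0f}\t.\t.\t"
            f"GT:DP:GQ\t{gt}:{int(r['depth'])}:{int(round(r['quality']))}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_snp_calls_vcf(path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            sample = rec.samples[list(rec.samples)[0]]
            gt = sample.get("GT")
            zyg = "hom" if gt is not None and len(set(a for a in gt if a is not None)) == 1 else "het"
            allele = rec.alts[0] if rec.alts else rec.ref
            rows.append((rec.chrom, rec.pos, allele, zyg,
                         int(sample.get("DP") or 0), float(sample.get("GQ") or 0)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "allele", "zygosity", "depth", "quality"])


SNP_TSV_COLUMNS = ["chrom", "pos", "allele", "zygosity", "depth", "quality"]


def write_snp_calls_tsv(calls: pd.DataFrame, path) -> None:
    calls[SNP_TSV_COLUMNS].to_csv(path, sep="\t", index=False)


def read_snp_calls_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SNP_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns {sorted(missing)}")
    return df


def write_parental_panel(panel: pd.DataFrame, path) -> None:
    panel[["chrom", "pos", "maternal_allele", "paternal_allele"]].to_csv(
        path, sep="\t", index=False)


def read_parental_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    bad = df.index[df["maternal_allele"] == df["paternal_allele"]]
    if len(bad):
        raise ParseError(path, int(bad[0]) + 2, "maternal and paternal alleles identical")
    return df


# ----------------------------------------------------------------------- GFF3

def write_gff3(genes: pd.DataFrame, exons: pd.DataFrame, path) -> None:
    lines = ["##gff-version 3"]
    exons_by_gene = dict(tuple(exons.groupby("gene_id", sort=False)))
    for _, g in genes.iterrows():
        gid = g["gene_id"]
        lines.append(f"{g['chrom']}\tsim\tgene\t{g['start']}\t{g['end']}\t.\t+\t.\tID={gid}")
        for _, e in exons_by_gene.get(gid, pd.DataFrame()).iterrows():
            lines.append(
                f"{e['chrom']}\tsim\texon\t{e['start']}\t{e['end']}\t.\t+\t.\t"
                f"ID={e['exon_id']};Parent={gid}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path):
    """Gene and exon tables from GFF3 via gffutils; validates exon containment."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    gene_rows, exon_rows = [], []
    spans = {}
    for g in db.features_of_type("gene"):
        gene_rows.append((g.id, g.seqid, g.start, g.end))
        spans[g.id] = (g.seqid, g.start, g.end)
    for e in db.features_of_type("exon"):
        parent = e.attributes.get("Parent", [""])[0]
        if parent in spans:
            chrom, gs, ge = spans[parent]
            if e.seqid != chrom or e.start < gs or e.end > ge:
                raise ParseError(path, 0,
                                 f"exon {e.id} ({e.seqid}:{e.start}-{e.end}) outside "
                                 f"gene {parent} span {chrom}:{gs}-{ge}")
        exon_rows.append((e.id, parent, e.seqid, e.start, e.end))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end"])
    exons = pd.DataFrame(exon_rows, columns=["exon_id", "gene_id", "chrom", "start", "end"])
    return genes, exons


# ----------------------------------------------------------- count matrices

def write_count_matrix(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=True)


def read_count_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ParseError(path, 1, "non-numeric entries in count matrix")
    bad = np.argwhere(arr < 0)
    if len(bad):
        raise ParseError(path, int(bad[0][0]) + 2,
                         f"negative count in column {df.columns[bad[0][1]]!r}")
    return df


# ------------------------------------------------------------------------ BED

def write_bed(bed: pd.DataFrame, path) -> None:
    """0-based half-open intervals, no header."""
    bed[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(path, lineno, "fewer than 3 BED columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from exc
        if start < 0 or end < start:
            raise ParseError(path, lineno, f"invalid interval [{start}, {end})")
        rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def bed_to_blocks(bed: pd.DataFrame) -> pd.DataFrame:
    """0-based half-open BED records as internal 1-based inclusive intervals."""
    return pd.DataFrame({"chrom": bed["chrom"], "start": bed["start"] + 1, "end": bed["end"]})


# ----------------------------------------------------------------------- JSON

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
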