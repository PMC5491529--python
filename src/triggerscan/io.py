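"""Readers and writers for the pipeline's tabular and sequence formats.

All tables are plain TSV; sequences are FASTA via Biopython; genotypes can
additionally round-trip through a minimal single-sample-per-column VCF.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthdata import MISSING

__all__ = [
    "read_bed",
    "write_bed3",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "read_genotypes_vcf",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_phenotypes_tsv",
    "write_phenotypes_tsv",
    "read_ppi_tsv",
    "write_ppi_tsv",
    "read_gene_set",
    "write_fasta",
    "read_fasta",
    "read_hic_tsv",
    "write_hic_tsv",
]

_BROADPEAK_COLS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "signalValue",
    "pValue",
    "qValue",
]


def read_bed(path, signal_column: int | None = 6) -> pd.DataFrame:
    """Read BED/broadPeak intervals into (chrom, start, end, signal).

    ``signal_column`` is the 0-based column holding the enrichment signal
    (6 = broadPeak signalValue); ``None`` sets signal to 0 for plain BED3.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _BROADPEAK_COLS[: df.shape[1]] + list(df.columns[9:])
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    if signal_column is not None and signal_column < df.shape[1]:
        out["signal"] = pd.to_numeric(df.iloc[:, signal_column])
    else:
        out["signal"] = 0.0
    return out


def write_bed3(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_genotypes_tsv(path) -> pd.DataFrame:
    """Samples x variants dosage matrix; first column = sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(np.int8)


def write_genotypes_tsv(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index_label="sample")


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_GT_DECODE = {v: k for k, v in _GT_CODE.items()}


def write_genotypes_vcf(
    genotypes: pd.DataFrame,
    path,
    chrom: str = "chr7",
    start_pos: int = 1_000_000,
    spacing: int = 1_000,
) -> None:
    """Minimal VCF 4.2 with one record per variant, GT fields only.

    Variant coordinates are synthetic (evenly spaced) unless the caller
    supplies real ones downstream; minor allele is written as ALT.
    """
    samples = list(genotypes.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, var in enumerate(genotypes.columns):
            gts = "\t".join(
                _GT_CODE[int(genotypes.iloc[i, j])] for i in range(len(samples))
            )
            fh.write(
                f"{chrom}\t{start_pos + j * spacing}\t{var}\tG\tA\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_genotypes_vcf(path) -> pd.DataFrame:
    """Read a GT-only VCF back into a samples x variants dosage matrix."""
    header = None
    rows: list[tuple[str, list[int]]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                header = fields[9:]
                continue
            var = fields[2]
            gts = [
                _GT_DECODE.get(g.split(":")[0].replace("|", "/"), MISSING)
                for g in fields[9:]
            ]
            rows.append((var, gts))
    if header is None:
        raise ValueError(f"{path}: missing #CHROM header line")
    data = {var: gts for var, gts in rows}
    return pd.DataFrame(data, index=header).astype(np.int8)


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x samples matrix; first column = gene id, header = sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_phenotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_phenotypes_tsv(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index_label="sample")


def read_ppi_tsv(path) -> pd.DataFrame:
    """Edge list with columns nodeA, nodeB, score, source (score may be NA)."""
    return pd.read_csv(path, sep="\t")


def write_ppi_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_gene_set(path) -> list[str]:
    """One gene symbol per line (Human-DNA-Repair-Genes-style list)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_fasta(seqs: pd.DataFrame, path) -> None:
    """Write a table with columns ``name``/``seq`` as FASTA."""
    records = [
        SeqRecord(Seq(s), id=n, description="")
        for n, s in zip(seqs["name"], seqs["seq"])
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> pd.DataFrame:
    records = list(SeqIO.parse(path, "fasta"))
    return pd.DataFrame(
        {"name": [r.id for r in records], "seq": [str(r.seq).upper() for r in records]}
    )


def read_hic_tsv(path) -> pd.DataFrame:
    """Binned contact signal: bin, chrom, start, end, signal."""
    return pd.read_csv(path, sep="\t")


def write_hic_tsv(bins: pd.DataFrame, path) -> None:
    bins.to_csv(path, sep="\t", index=False)
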