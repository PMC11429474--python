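"""Readers and writers for the pipeline's flat-file interfaces.

All genomic intervals are 0-based, half-open. Tables are plain TSV so that
every artifact of a run is diffable and re-derivable from config + seed.
"""

from __future__ import annotations

import os

import pandas as pd

BEDGRAPH_COLS = ["chrom", "start", "end", "depth"]
QTL_COLS = ["chrom", "start", "end", "category", "trait_name"]
GENE_MODEL_COLS = [
    "gene_id",
    "chrom",
    "start",
    "end",
    "strand",
    "cds_start",
    "cds_end",
    "exon_starts",
    "exon_ends",
    "tss",
]


def write_bedgraph(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a 4-column bedGraph (chrom, start, end, depth), no header."""
    df.loc[:, BEDGRAPH_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BEDGRAPH_COLS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_manifest(breeds: dict[str, str], path: str | os.PathLike) -> None:
    """Sample manifest: two columns, sample_id and breed."""
    pd.DataFrame(
        {"sample_id": list(breeds), "breed": list(breeds.values())}
    ).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample_id"], df["breed"]))


def write_expression(expr: pd.DataFrame, path: str | os.PathLike) -> None:
    """Expression matrix, genes (rows) x samples (columns)."""
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_gene_models(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    genes.loc[:, GENE_MODEL_COLS].to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"exon_starts": str, "exon_ends": str})
    if "tss" not in df.columns:
        df["tss"] = df["start"].where(df["strand"] == "+", df["end"])
    return df


def write_qtl_table(qtl: pd.DataFrame, path: str | os.PathLike) -> None:
    qtl.loc[:, QTL_COLS].to_csv(path, sep="\t", index=False)


def read_qtl_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_chrom_sizes(sizes: dict[str, int], path: str | os.PathLike) -> None:
    pd.DataFrame({"chrom": list(sizes), "size": list(sizes.values())}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))
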