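"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinate conventions: internal representation is 0-based half-open
throughout. BED/bedGraph files are 0-based half-open on disk; GFF3 and
"printed table" gene lists are 1-based inclusive and converted on load.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd
import yaml

from .simulate import CountMatrix, GeneAnnotation, SimConfig


# -- annotation --------------------------------------------------------------

def write_annotation_bed(annotation: GeneAnnotation, path: str | Path) -> None:
    """6-column BED (0-based half-open), score column unused (0)."""
    g = annotation.genes
    out = pd.DataFrame(
        {
            "chrom": g["chrom"],
            "start": g["start"],
            "end": g["end"],
            "name": g["gene_id"],
            "score": 0,
            "strand": g["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_annotation_gff3(annotation: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, L in annotation.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {L}\n")
        for row in annotation.genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tchillseq\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_annotation_bed(path: str | Path, chrom_lengths: dict[str, int] | None = None) -> GeneAnnotation:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str},
    )
    genes = df[["gene_id", "chrom", "start", "end", "strand"]].copy()
    if chrom_lengths is None:
        chrom_lengths = dict(genes.groupby("chrom")["end"].max())
    return GeneAnnotation(genes=genes, chrom_lengths=chrom_lengths)


def read_gene_table(
    path: str | Path, coords: str = "1-based", chrom_lengths: dict[str, int] | None = None
) -> GeneAnnotation:
    """Load a TSV gene table (gene_id, chrom, start, end, strand[, annotation]).

    ``coords="1-based"`` treats start/end as 1-based inclusive (the usual
    convention of printed gene tables and GFF) and converts to the internal
    0-based half-open representation; ``coords="0-based"`` takes them as-is.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes = df.copy()
    if coords == "1-based":
        genes["start"] = genes["start"] - 1
    elif coords != "0-based":
        raise ValueError(f"unknown coordinate convention {coords!r}")
    if chrom_lengths is None:
        chrom_lengths = dict(genes.groupby("chrom")["end"].max())
    return GeneAnnotation(genes=genes, chrom_lengths=chrom_lengths)


def load_qtl_region_genes() -> GeneAnnotation:
    """Bundled reference table: the 22 cold-responsive DEGs spanning the
    cucumber cold-tolerance QTL region qLTT6.2 on chromosome 6 (Chinese
    Long v3 coordinates, stored 1-based inclusive)."""
    with importlib.resources.as_file(
        importlib.resources.files("chillseq.data") / "qtl_region_genes.tsv"
    ) as p:
        return read_gene_table(p, coords="1-based")


# -- matrices and tables -----------------------------------------------------

def write_counts(cm: CountMatrix, counts_path: str | Path, design_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.design.to_csv(design_path, sep="\t", index=False)


def read_counts(counts_path: str | Path, design_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t")
    return CountMatrix(counts=counts, design=design)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# -- BED / bedGraph ----------------------------------------------------------

def write_bed(df: pd.DataFrame, path: str | Path, columns: list[str] | None = None) -> None:
    cols = columns or ["chrom", "start", "end", "name"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = names[: df.shape[1]]
    return df


def write_bedgraph(bins: pd.DataFrame, path: str | Path, value_col: str = "index") -> None:
    """Per-bin track; bins with undefined values are skipped."""
    out = bins.dropna(subset=[value_col])
    out[["chrom", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False
    )


# -- config ------------------------------------------------------------------

def write_sim_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_sim_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        return SimConfig.from_dict(yaml.safe_load(fh))
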