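"""Chromosomal DEG-hotspot scan: the distribution enrichment index.

The genome is tiled into fixed-size bins and each bin b is scored with

    index(b) = (DEGs_b / DEGs_total) / (genes_b / genes_total),

the ratio of the bin's share of DEGs to its share of genes. Index 1 means
DEGs follow gene density; bins with index above a threshold (default 3)
are merged into candidate enrichment regions, which can then be
intersected with known QTL intervals (e.g. the cucumber cold-tolerance
QTL qLTT6.2 on chromosome 6) and have their member genes listed.

Because each gene is assigned to exactly one bin (by start coordinate,
optionally midpoint), the gene-count-weighted mean index over non-empty
bins is identically 1 — a conservation property the tests rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ChillseqError, InvalidIntervalError
from .simulate import GeneAnnotation

#: Calling threshold on the enrichment index (exclusive).
DEFAULT_INDEX_THRESHOLD = 3.0
#: Default bin size. A 5-kb bin over a genome of ~25k genes in ~190 Mb
#: leaves almost every bin with 0-1 genes and a degenerate index, while
#: reported enrichment regions span >1 Mb; 500 kb gives each bin enough
#: genes for the index to be meaningful at desk scale. Always configurable.
DEFAULT_BIN_SIZE = 500_000
#: Minimum DEGs per region, suppressing single-gene spikes in sparse bins.
DEFAULT_MIN_DEGS = 3
#: Sub-threshold/empty bins a region may bridge.
DEFAULT_MAX_GAP_BINS = 1


@dataclass
class EnrichedRegion:
    """A maximal run of above-threshold bins merged into one interval."""

    chrom: str
    start: int
    end: int
    peak_index: float
    n_bins: int  # above-threshold member bins
    deg_count: int
    gene_count: int
    qtl_names: list[str] = field(default_factory=list)


def bin_genome(annotation: GeneAnnotation, bin_size: int = DEFAULT_BIN_SIZE,
               assign: str = "start") -> pd.DataFrame:
    """Tile each chromosome with half-open bins and count genes per bin.

    Each gene lands in exactly one bin — the one containing its start
    (``assign="start"``, default) or its midpoint (``assign="midpoint"``)
    — so bin gene counts sum to the total gene number.
    """
    if bin_size <= 0:
        raise ChillseqError("bin_size must be positive")
    if assign not in ("start", "midpoint"):
        raise ChillseqError(f"unknown assignment rule {assign!r}")
    rows = []
    for chrom, L in annotation.chrom_lengths.items():
        n_bins = int(np.ceil(L / bin_size))
        for i in range(n_bins):
            rows.append((chrom, i * bin_size, min((i + 1) * bin_size, L)))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    bins["n_genes"] = 0

    g = annotation.genes
    anchor = g["start"] if assign == "start" else (g["start"] + g["end"]) // 2
    for chrom, sub_anchor in anchor.groupby(g["chrom"]):
        L = annotation.chrom_lengths[chrom]
        if ((sub_anchor < 0) | (sub_anchor >= L)).any():
            raise InvalidIntervalError(f"gene anchor outside bounds of {chrom}")
        idx = (sub_anchor // bin_size).astype(int)
        counts = idx.value_counts()
        sel = bins["chrom"] == chrom
        offset = bins.index[sel][0]
        for b, c in counts.items():
            bins.loc[offset + b, "n_genes"] += int(c)
    return bins


def enrichment_index(
    bins: pd.DataFrame, deg_set: set[str], annotation: GeneAnnotation,
    assign: str = "start",
) -> pd.DataFrame:
    """Fill per-bin DEG counts and the distribution enrichment index.

    index = (DEGs_b/DEGs_total) / (genes_b/genes_total); NaN for bins
    without genes (undefined, not zero). The DEG set must be a non-empty
    subset of the annotation's genes.
    """
    if not deg_set:
        raise ChillseqError("empty DEG set: enrichment index undefined")
    unknown = deg_set - set(annotation.gene_ids)
    if unknown:
        raise ChillseqError(f"DEGs not in annotation: {sorted(unknown)[:5]} ...")
    out = bins.copy()
    out["n_degs"] = 0

    g = annotation.genes
    degs = g[g["gene_id"].isin(deg_set)]
    anchor = degs["start"] if assign == "start" else (degs["start"] + degs["end"]) // 2
    bin_size = int((bins["end"] - bins["start"]).max())
    for chrom, sub_anchor in anchor.groupby(degs["chrom"]):
        idx = (sub_anchor // bin_size).astype(int)
        sel = out["chrom"] == chrom
        offset = out.index[sel][0]
        for b, c in idx.value_counts().items():
            out.loc[offset + b, "n_degs"] += int(c)

    total_genes = int(out["n_genes"].sum())
    total_degs = int(out["n_degs"].sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        out["index"] = (out["n_degs"] / total_degs) / (out["n_genes"] / total_genes)
    out.loc[out["n_genes"] == 0, "index"] = np.nan
    return out


def call_enriched_regions(
    bins: pd.DataFrame,
    threshold: float = DEFAULT_INDEX_THRESHOLD,
    min_degs: int = DEFAULT_MIN_DEGS,
    max_gap_bins: int = DEFAULT_MAX_GAP_BINS,
) -> list[EnrichedRegion]:
    """Merge maximal runs of bins with index > threshold into regions.

    Runs may bridge up to ``max_gap_bins`` consecutive sub-threshold or
    empty bins; a merged region is kept only if its total DEG count
    (summed over the whole span) reaches ``min_degs``. Regions are sorted
    by chromosome and start.
    """
    if "index" not in bins.columns:
        raise ChillseqError("bins lack an index column; run enrichment_index first")
    regions: list[EnrichedRegion] = []
    for chrom, sub in bins.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        above = (sub["index"] > threshold).fillna(False).to_numpy()
        hits = np.flatnonzero(above)
        if hits.size == 0:
            continue
        # Group above-threshold bins separated by <= max_gap_bins gaps.
        run_start = hits[0]
        prev = hits[0]
        runs = []
        for h in hits[1:]:
            if h - prev - 1 > max_gap_bins:
                runs.append((run_start, prev))
                run_start = h
            prev = h
        runs.append((run_start, prev))
        for a, b in runs:
            span = sub.iloc[a : b + 1]
            n_deg = int(span["n_degs"].sum()) if "n_degs" in span else 0
            if n_deg < min_degs:
                continue
            member = span[(span["index"] > threshold).fillna(False)]
            regions.append(
                EnrichedRegion(
                    chrom=str(chrom),
                    start=int(span["start"].iloc[0]),
                    end=int(span["end"].iloc[-1]),
                    peak_index=float(span["index"].max()),
                    n_bins=len(member),
                    deg_count=n_deg,
                    gene_count=int(span["n_genes"].sum()),
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def overlap_qtl(
    regions: list[EnrichedRegion],
    qtls: pd.DataFrame,
    known_chroms: set[str] | None = None,
) -> list[EnrichedRegion]:
    """Annotate each region with names of intersecting QTL intervals.

    Both sides are 0-based half-open; any overlap of >= 1 bp counts. QTLs
    on chromosomes absent from ``known_chroms`` (when given) draw a
    warning and never overlap.
    """
    if known_chroms is not None:
        for chrom in qtls["chrom"].unique():
            if chrom not in known_chroms:
                warnings.warn(f"QTL chromosome {chrom!r} not in annotation", stacklevel=2)
    for r in regions:
        m = (
            (qtls["chrom"] == r.chrom)
            & (qtls["start"] < r.end)
            & (qtls["end"] > r.start)
        )
        r.qtl_names = list(qtls.loc[m, "name"])
    return regions


def genes_in_region(
    annotation: GeneAnnotation, chrom: str, start: int, end: int
) -> pd.DataFrame:
    """All genes whose interval intersects [start, end) on ``chrom``,
    sorted by start (half-open intersection, >= 1 bp)."""
    if start >= end:
        raise InvalidIntervalError(f"region {chrom}:{start}-{end} has start >= end")
    g = annotation.genes
    m = (g["chrom"] == chrom) & (g["start"] < end) & (g["end"] > start)
    return g[m].sort_values("start").reset_index(drop=True)


def regions_table(regions: list[EnrichedRegion]) -> pd.DataFrame:
    """Flatten regions into a report frame (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "peak_index": r.peak_index,
                "n_bins": r.n_bins,
                "deg_count": r.deg_count,
                "gene_count": r.gene_count,
                "qtl_names": ",".join(r.qtl_names),
            }
            for r in regions
        ],
        columns=[
            "chrom", "start", "end", "peak_index", "n_bins",
            "deg_count", "gene_count", "qtl_names",
        ],
    )


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard similarity of two half-open intervals on one chromosome."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def plot_enrichment_track(bins: pd.DataFrame, path, threshold: float = DEFAULT_INDEX_THRESHOLD) -> None:
    """Per-chromosome line plot of the enrichment index."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(bins["chrom"].unique())
    fig, axes = plt.subplots(len(chroms), 1, figsize=(8, 1.2 * len(chroms)), sharex=False)
    if len(chroms) == 1:
        axes = [axes]
    for ax, chrom in zip(axes, chroms):
        sub = bins[bins["chrom"] == chrom]
        mid = (sub["start"] + sub["end"]) / 2e6
        ax.plot(mid, sub["index"].fillna(0.0), lw=0.8)
        ax.axhline(threshold, color="red", lw=0.5, ls="--")
        ax.set_ylabel(chrom, fontsize=7)
    axes[-1].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
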