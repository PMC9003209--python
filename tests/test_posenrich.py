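"""Binning, the distribution enrichment index, region calling, QTL overlap."""

import numpy as np
import pandas as pd
import pytest

import chillseq as cs
from chillseq.errors import ChillseqError, InvalidIntervalError
from chillseq.io import load_qtl_region_genes
from chillseq.posenrich import DEFAULT_INDEX_THRESHOLD


def _annotation(starts, chrom_len=100_000, gene_len=100, chrom="chr1"):
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(starts))],
            "chrom": [chrom] * len(starts),
            "start": starts,
            "end": [s + gene_len for s in starts],
            "strand": ["+"] * len(starts),
        }
    )
    return cs.GeneAnnotation(genes=genes, chrom_lengths={chrom: chrom_len})


def test_bin_tiling_counts_and_conservation():
    ann = _annotation([100, 2_000, 7_000], chrom_len=10_000)
    bins = cs.bin_genome(ann, bin_size=5_000)
    assert len(bins) == 2  # 10 kb / 5 kb
    assert bins["n_genes"].tolist() == [2, 1]
    assert bins["n_genes"].sum() == ann.n_genes


def test_gene_on_bin_boundary_assigned_by_start():
    # gene spans the 5-kb boundary; its start (4,900) decides the bin
    ann = _annotation([4_900], chrom_len=10_000, gene_len=400)
    bins = cs.bin_genome(ann, bin_size=5_000)
    assert bins["n_genes"].tolist() == [1, 0]
    mid = cs.bin_genome(ann, bin_size=5_000, assign="midpoint")
    assert mid["n_genes"].tolist() == [0, 1]  # midpoint 5,100 flips it


def test_enrichment_index_hand_case():
    """Bin holding 2 of 10 DEGs among 5 of 100 genes: index = 4.0 exact."""
    starts = [i * 900 for i in range(95)] + [90_000 + i * 100 for i in range(5)]
    ann = _annotation(starts, chrom_len=100_000, gene_len=50)
    degs = {f"g{i}" for i in range(8)} | {"g95", "g96"}  # 8 elsewhere + 2 in last bin
    bins = cs.bin_genome(ann, bin_size=90_000)
    bins = cs.enrichment_index(bins, degs, ann)
    last = bins.iloc[-1]
    assert last["n_genes"] == 5 and last["n_degs"] == 2
    assert last["index"] == pytest.approx((2 / 10) / (5 / 100))  # == 4.0
    assert last["index"] == 4.0


def test_enrichment_index_uniform_and_empty_bins():
    # DEGs proportional to gene counts -> index 1 in every non-empty bin
    starts = [1_000, 2_000, 11_000, 12_000, 31_000, 32_000]
    ann = _annotation(starts, chrom_len=40_000)
    bins = cs.bin_genome(ann, bin_size=10_000)
    degs = {"g0", "g2", "g4"}  # one of two genes in each occupied bin
    bins = cs.enrichment_index(bins, degs, ann)
    occupied = bins[bins["n_genes"] > 0]
    np.testing.assert_allclose(occupied["index"], 1.0)
    assert bins.loc[bins["n_genes"] == 0, "index"].isna().all()
    # zero DEGs in an occupied bin -> index 0
    bins2 = cs.enrichment_index(cs.bin_genome(ann, bin_size=10_000), {"g0"}, ann)
    assert bins2.iloc[1]["index"] == 0.0
    with pytest.raises(ChillseqError):
        cs.enrichment_index(cs.bin_genome(ann, bin_size=10_000), set(), ann)


def test_index_conservation_weighted_mean_is_one(default_sim):
    """Gene-count-weighted mean index over non-empty bins is exactly 1."""
    _, ann, _, truth = default_sim
    bins = cs.bin_genome(ann, bin_size=500_000)
    bins = cs.enrichment_index(bins, truth.de_gene_ids, ann)
    occ = bins[bins["n_genes"] > 0]
    total = occ["n_genes"].sum()
    weighted = (occ["index"] * occ["n_genes"] / total).sum()
    assert weighted == pytest.approx(1.0, abs=1e-12)
    assert (occ["n_degs"] / occ["n_degs"].sum()).sum() == pytest.approx(1.0, abs=1e-12)
    assert (occ["n_degs"] <= occ["n_genes"]).all()


def test_index_monotone_in_deg_membership():
    starts = [1_000, 2_000, 11_000, 12_000]
    ann = _annotation(starts, chrom_len=20_000)
    base = cs.enrichment_index(cs.bin_genome(ann, 10_000), {"g0", "g2"}, ann)
    more = cs.enrichment_index(cs.bin_genome(ann, 10_000), {"g0", "g1", "g2"}, ann)
    assert more.iloc[0]["index"] > base.iloc[0]["index"]
    assert more.iloc[1]["index"] < base.iloc[1]["index"]


def _track(chrom, rows):
    """rows: (start, end, n_genes, n_degs, index)"""
    return pd.DataFrame(
        [(chrom, s, e, g, d, i) for s, e, g, d, i in rows],
        columns=["chrom", "start", "end", "n_genes", "n_degs", "index"],
    )


def test_region_calling_basic_cases():
    quiet = _track("chr1", [(0, 10, 5, 1, 1.0), (10, 20, 5, 1, 2.9)])
    assert cs.call_enriched_regions(quiet, threshold=3.0, min_degs=1) == []

    lone = _track("chr1", [(0, 10, 5, 0, 0.0), (10, 20, 5, 4, 4.0), (20, 30, 5, 0, 0.0)])
    regions = cs.call_enriched_regions(lone, threshold=3.0, min_degs=1, max_gap_bins=0)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end, r.n_bins) == (10, 20, 1)
    assert r.peak_index == 4.0 and r.deg_count == 4

    # min_degs suppresses sparse spikes
    assert cs.call_enriched_regions(lone, threshold=3.0, min_degs=5) == []


def test_region_calling_bridges_gaps():
    track = _track(
        "chr1",
        [
            (0, 10, 5, 3, 4.0),
            (10, 20, 0, 0, np.nan),  # empty bin inside the run
            (20, 30, 5, 3, 5.0),
            (30, 40, 5, 0, 0.0),
            (40, 50, 5, 0, 0.0),
            (50, 60, 5, 3, 6.0),  # too far at max_gap_bins=1
        ],
    )
    regions = cs.call_enriched_regions(track, threshold=3.0, min_degs=1, max_gap_bins=1)
    assert [(r.start, r.end) for r in regions] == [(0, 30), (50, 60)]
    merged = cs.call_enriched_regions(track, threshold=3.0, min_degs=1, max_gap_bins=2)
    assert [(r.start, r.end) for r in merged] == [(0, 60)]


def _oracle_regions(above, max_gap):
    """Exhaustive grouping of above-threshold bin indices by gap rule."""
    hits = [i for i, a in enumerate(above) if a]
    runs = []
    for h in hits:
        if runs and h - runs[-1][-1] - 1 <= max_gap:
            runs[-1].append(h)
        else:
            runs.append([h])
    return [(r[0], r[-1]) for r in runs]


def test_region_calling_matches_enumeration_oracle():
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(1, 6))
        idx = rng.choice([0.0, 2.0, 4.0, 6.0, np.nan], size=n)
        max_gap = int(rng.integers(0, 3))
        track = _track(
            "chr1",
            [(10 * i, 10 * (i + 1), 5, 3, idx[i]) for i in range(n)],
        )
        got = [
            (r.start // 10, r.end // 10 - 1)
            for r in cs.call_enriched_regions(track, threshold=3.0, min_degs=0, max_gap_bins=max_gap)
        ]
        above = [(not np.isnan(v)) and v > 3.0 for v in idx]
        assert got == _oracle_regions(above, max_gap)


def test_qtl_overlap_half_open_semantics():
    regions = [
        cs.EnrichedRegion("chr6", 9_700_000, 11_000_000, 5.0, 2, 10, 30),
        cs.EnrichedRegion("chr1", 0, 100_000, 4.0, 1, 3, 10),
    ]
    qtls = cs.generate_qtl_bed(
        [
            ("chr6", 9_900_000, 10_500_000, "qLTT6.2"),
            ("chr1", 100_000, 200_000, "adjacent"),  # end == start: no overlap
        ]
    )
    out = cs.overlap_qtl(regions, qtls, known_chroms={"chr1", "chr6"})
    assert out[0].qtl_names == ["qLTT6.2"]
    assert out[1].qtl_names == []

    # empty QTL set leaves regions unchanged
    out = cs.overlap_qtl(regions, cs.generate_qtl_bed([]))
    assert all(r.qtl_names == [] for r in out)

    with pytest.warns(UserWarning, match="not in annotation"):
        cs.overlap_qtl(regions, cs.generate_qtl_bed([("chrX", 0, 10, "stray")]),
                       known_chroms={"chr1", "chr6"})


def test_qtl_region_gene_extraction():
    """The bundled qLTT6.2-region table: the ~1.25-Mb query returns all 22
    genes; a query covering only the first gene returns exactly it."""
    ann = load_qtl_region_genes()
    full = cs.genes_in_region(ann, "chr6", 9_736_464 - 1, 10_982_661)
    assert len(full) == 22
    assert full.iloc[0]["gene_id"] == "CsaV3_6G013600"
    assert full.iloc[-1]["gene_id"] == "CsaV3_6G015130"

    narrow = cs.genes_in_region(ann, "chr6", 9_736_464 - 1, 9_740_433)
    assert list(narrow["gene_id"]) == ["CsaV3_6G013600"]

    assert cs.genes_in_region(ann, "chr6", 0, 1000).empty
    with pytest.raises(InvalidIntervalError):
        cs.genes_in_region(ann, "chr6", 10, 10)


def test_hotspot_recovered_end_to_end(default_sim):
    """Planted 1-Mb hotspot is called with index > 3 and Jaccard >= 0.5
    after the full simulate -> DE -> scan chain."""
    cfg, ann, cm, truth = default_sim
    res = cs.call_degs(cs.nb_test(cm, genotypes=("CT57S", "CT90R"), tissue="leaf"))
    degs = cs.deg_set(res)
    bins = cs.enrichment_index(cs.bin_genome(ann), degs, ann)
    regions = cs.call_enriched_regions(bins)
    chrom, start, end, _ = truth.hot_regions[0]
    best = max(
        (cs.interval_jaccard((r.start, r.end), (start, end))
         for r in regions if r.chrom == chrom),
        default=0.0,
    )
    assert best >= 0.5
    assert any(r.peak_index > DEFAULT_INDEX_THRESHOLD for r in regions)
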