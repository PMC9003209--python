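"""Synthetic data with known ground truth for the cold-tolerance pipeline.

Emulates the statistical structure of a two-genotype (cold-tolerant vs
cold-sensitive) x two-tissue (leaf, root) cucumber experiment:

* a 7-chromosome genome with non-uniform gene density,
* negative-binomial fragment counts with planted differentially expressed
  genes, a configurable fraction of which are positionally clustered inside
  designated "hot regions" (emulating DEG hotspots such as the one over the
  cold-tolerance QTL qLTT6.2 on chromosome 6),
* a 17-analyte phytohormone panel with genotype-dependent means and
  multiplicative (lognormal) replicate noise,
* QTL intervals and term->gene-set annotations for the overlap and
  over-representation stages.

All generators are pure functions of (config, seed): the same configuration
always yields byte-identical outputs. Randomness is drawn from named
substreams of a single root seed so each generator is independently
reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import DimensionError, InvalidConfigError, InvalidIntervalError

# Substream indices off the root seed, one per generator.
_STREAM_ANNOTATION = 0
_STREAM_COUNTS = 1
_STREAM_HORMONES = 2
_STREAM_TERMS = 3

#: Approximate chromosome lengths (bp) of the cucumber (Chinese Long v3)
#: nuclear genome, used as the default simulated genome.
CUCUMBER_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 29_900_000,
    "chr2": 24_200_000,
    "chr3": 33_000_000,
    "chr4": 23_900_000,
    "chr5": 28_800_000,
    "chr6": 28_100_000,
    "chr7": 19_900_000,
}


@dataclass(frozen=True)
class HormoneSpec:
    """Per-analyte simulation parameters for the phytohormone panel.

    ``mean_a``/``mean_b`` are true group means in ng/g fresh weight;
    ``cv`` is the multiplicative replicate coefficient of variation.
    """

    name: str
    rt_min: float
    mean_a: float
    mean_b: float
    cv: float = 0.15
    n_replicates: int = 3


def default_hormone_panel() -> list[HormoneSpec]:
    """17-analyte phytohormone panel with 7 true genotype differences.

    The seven differing analytes carry the measured leaf contents of the
    cold-sensitive (group A, CT57S) and cold-tolerant (group B, CT90R)
    cucumber genotypes after 24 h at 6 degC; the remaining ten analytes of
    the LC-MS/MS standard mixture are given equal group means (no true
    difference).
    """
    differing = [
        HormoneSpec("IPR", 5.35, 0.88, 0.27),
        HormoneSpec("ABA", 4.10, 28.22, 23.06),
        HormoneSpec("BR", 7.93, 17.30, 5.41),
        HormoneSpec("DZ", 4.02, 1.02, 0.51),
        HormoneSpec("IBA", 4.40, 5.28, 10.35),
        HormoneSpec("IP", 5.40, 1.58, 1.26),
        HormoneSpec("JA-ILE", 5.25, 3.05, 8.50),
    ]
    equal = [
        ("IAA", 4.55, 12.0),
        ("SA", 3.80, 45.0),
        ("JA", 5.10, 20.0),
        ("MeJA", 6.20, 2.5),
        ("GA1", 4.75, 0.8),
        ("GA3", 4.60, 1.5),
        ("GA4", 6.05, 0.6),
        ("TZ", 3.55, 0.9),
        ("TZR", 4.20, 1.1),
        ("ACC", 2.90, 30.0),
    ]
    return differing + [HormoneSpec(n, rt, m, m) for n, rt, m in equal]


@dataclass
class SimConfig:
    """Configuration of one synthetic experiment.

    ``hot_regions`` are (chrom, start, end, planted_de_fraction) tuples in
    0-based half-open coordinates; the fraction says which share of the
    planted DE genes must fall inside that region. ``density_boost``
    multiplies the gene-placement density inside hot regions so that a
    hotspot holds enough genes to absorb its plantings (gene density along
    real chromosomes is non-uniform; this is the configurable stand-in).
    """

    n_chromosomes: int = 7
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: dict(CUCUMBER_CHROM_LENGTHS)
    )
    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (500, 5000)
    hot_regions: list[tuple[str, int, int, float]] = field(
        default_factory=lambda: [("chr6", 9_700_000, 10_700_000, 1.0)]
    )
    density_boost: float = 10.0
    n_de_genes: int = 50
    de_log2fc_range: tuple[float, float] = (2.0, 3.0)
    nb_mean_range: tuple[float, float] = (5.0, 500.0)
    #: NB dispersion (var = m + d*m^2). 0.03 (biological CV ~17%) is
    #: typical of triplicates of genetically identical plant material and
    #: keeps replicate log-expression correlations above the r^2 > 0.9
    #: reproducibility bar the emulated experiment reports.
    nb_dispersion: float = 0.03
    design: list[tuple[str, str, int]] = field(
        default_factory=lambda: [
            ("CT57S", "leaf", 3),
            ("CT57S", "root", 3),
            ("CT90R", "leaf", 3),
            ("CT90R", "root", 3),
        ]
    )
    hormone_spec: list[HormoneSpec] = field(default_factory=default_hormone_panel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise InvalidConfigError("need at least one chromosome")
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise InvalidConfigError(
                f"n_chromosomes={self.n_chromosomes} but "
                f"{len(self.chromosome_lengths)} lengths given"
            )
        if self.n_genes < 1:
            raise InvalidConfigError("need at least one gene")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise InvalidConfigError("gene_length_range must be positive and ordered")
        if any(L <= hi for L in self.chromosome_lengths.values()):
            raise InvalidConfigError("chromosome lengths must exceed max gene length")
        total_frac = 0.0
        for chrom, start, end, frac in self.hot_regions:
            if chrom not in self.chromosome_lengths:
                raise InvalidConfigError(f"hot region on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= self.chromosome_lengths[chrom]):
                raise InvalidConfigError(
                    f"hot region {chrom}:{start}-{end} outside chromosome bounds"
                )
            if not (0.0 <= frac <= 1.0):
                raise InvalidConfigError("planted DE fraction must be in [0, 1]")
            total_frac += frac
        if total_frac > 1.0 + 1e-9:
            raise InvalidConfigError("hot-region DE fractions sum to more than 1")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise InvalidConfigError("n_de_genes must be in [0, n_genes]")
        if self.nb_dispersion <= 0:
            raise InvalidConfigError("NB dispersion must be positive")
        if not self.design:
            raise InvalidConfigError("design must list at least one sample group")
        if any(n < 1 for _, _, n in self.design):
            raise InvalidConfigError("every design cell needs >=1 replicate")
        for h in self.hormone_spec:
            if h.mean_a <= 0 or h.mean_b <= 0:
                raise InvalidConfigError(f"analyte {h.name}: means must be positive")
            if h.cv < 0:
                raise InvalidConfigError(f"analyte {h.name}: CV must be >= 0")
            if h.n_replicates < 1:
                raise InvalidConfigError(f"analyte {h.name}: need >=1 replicate")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hot_regions"] = [list(r) for r in self.hot_regions]
        d["design"] = [list(r) for r in self.design]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "hormone_spec" in d:
            d["hormone_spec"] = [
                h if isinstance(h, HormoneSpec) else HormoneSpec(**h)
                for h in d["hormone_spec"]
            ]
        for key in ("hot_regions", "design"):
            if key in d:
                d[key] = [tuple(r) for r in d[key]]
        for key in ("gene_length_range", "de_log2fc_range", "nb_mean_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GeneAnnotation:
    """Gene coordinates over a known genome.

    ``genes`` has columns gene_id, chrom, start, end, strand with 0-based
    half-open coordinates, sorted by (chrom, start); gene ids are unique.
    """

    genes: pd.DataFrame
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        g = self.genes
        if g["gene_id"].duplicated().any():
            raise InvalidConfigError("gene ids must be unique")
        for chrom, sub in g.groupby("chrom", observed=True):
            if chrom not in self.chrom_lengths:
                raise InvalidIntervalError(f"gene on unknown chromosome {chrom!r}")
            L = self.chrom_lengths[chrom]
            if ((sub["start"] < 0) | (sub["end"] > L)).any():
                raise InvalidIntervalError(f"gene outside bounds of {chrom}")
        if (g["start"] >= g["end"]).any():
            raise InvalidIntervalError("degenerate gene interval (start >= end)")

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.genes["gene_id"])

    @property
    def lengths(self) -> pd.Series:
        """Gene length in bp, indexed by gene id."""
        g = self.genes
        return pd.Series(
            (g["end"] - g["start"]).to_numpy(), index=g["gene_id"], name="length"
        )

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class CountMatrix:
    """Integer fragment counts (genes x samples) with a sample design table."""

    counts: pd.DataFrame
    design: pd.DataFrame  # sample, genotype, tissue, replicate

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.design["sample"]):
            raise DimensionError("count columns and design rows do not match")

    def samples_for(self, genotype: str | None = None, tissue: str | None = None) -> list[str]:
        d = self.design
        if genotype is not None:
            d = d[d["genotype"] == genotype]
        if tissue is not None:
            d = d[d["tissue"] == tissue]
        return list(d["sample"])


@dataclass
class GroundTruth:
    """What the simulator actually planted, for judging downstream calls."""

    de_gene_ids: set[str]
    true_log2fc: pd.Series  # indexed by gene id, 0 for non-DE genes
    hot_regions: list[tuple[str, int, int, float]]
    hot_planted: dict[int, set[str]]  # hot-region index -> planted gene ids
    hormone_true_means: pd.DataFrame  # analyte, mean_a, mean_b


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config_seed), stream]))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SimConfig) -> GeneAnnotation:
    """Place ``n_genes`` non-overlapping-id genes on the simulated genome.

    Placement is uniform per chromosome weighted by chromosome length, with
    the density inside hot regions multiplied by ``config.density_boost``.
    Every gene lies fully inside its chromosome.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_ANNOTATION)

    chroms = list(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in chroms], dtype=float)
    # Effective weight per chromosome: its length plus the extra mass the
    # boost adds over its hot regions.
    extra = np.zeros(len(chroms))
    hot_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, _frac in config.hot_regions:
        i = chroms.index(chrom)
        extra[i] += (config.density_boost - 1.0) * (end - start)
        hot_by_chrom.setdefault(chrom, []).append((start, end))
    weights = lengths + extra
    chrom_idx = rng.choice(len(chroms), size=config.n_genes, p=weights / weights.sum())

    lo, hi = config.gene_length_range
    gene_len = rng.integers(lo, hi + 1, size=config.n_genes)
    starts = np.empty(config.n_genes, dtype=np.int64)
    for i, ci in enumerate(chrom_idx):
        chrom = chroms[ci]
        L = config.chromosome_lengths[chrom]
        hots = hot_by_chrom.get(chrom, [])
        hot_mass = sum((config.density_boost - 1.0) * (e - s) for s, e in hots)
        # Mixture: uniform over the whole chromosome (mass L) plus extra
        # uniform mass over each hot region.
        if hots and rng.random() < hot_mass / (L + hot_mass):
            lens = np.array([e - s for s, e in hots], dtype=float)
            j = rng.choice(len(hots), p=lens / lens.sum())
            s, e = hots[j]
            pos = int(rng.integers(s, e))
        else:
            pos = int(rng.integers(0, L))
        starts[i] = min(pos, L - int(gene_len[i]))

    strand = rng.choice(np.array(["+", "-"]), size=config.n_genes)
    df = pd.DataFrame(
        {
            "chrom": pd.Categorical([chroms[i] for i in chrom_idx], categories=chroms),
            "start": starts,
            "end": starts + gene_len,
            "strand": strand,
        }
    )
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    width = max(4, len(str(config.n_genes)))
    df.insert(0, "gene_id", [f"gene_{i + 1:0{width}d}" for i in range(len(df))])
    df["chrom"] = df["chrom"].astype(str)
    return GeneAnnotation(genes=df, chrom_lengths=dict(config.chromosome_lengths))


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _genes_in_interval(annotation: GeneAnnotation, chrom: str, start: int, end: int) -> list[str]:
    g = annotation.genes
    m = (g["chrom"] == chrom) & (g["start"] >= start) & (g["start"] < end)
    return list(g.loc[m, "gene_id"])


def _choose_de_genes(
    annotation: GeneAnnotation, config: SimConfig, rng: np.random.Generator
) -> tuple[list[str], dict[int, set[str]]]:
    """Pick DE genes: floor(fraction * n_de) inside each hot region (but at
    least one when the fraction is positive, so every active hot region is
    actually hot), the remainder uniformly over the rest of the genome."""
    all_ids = list(annotation.gene_ids)
    chosen: list[str] = []
    hot_planted: dict[int, set[str]] = {}
    for ri, (chrom, start, end, frac) in enumerate(config.hot_regions):
        want = math.floor(frac * config.n_de_genes)
        if want == 0 and frac > 0 and config.n_de_genes > 0:
            want = 1
        pool = [g for g in _genes_in_interval(annotation, chrom, start, end) if g not in chosen]
        if want > len(pool):
            warnings.warn(
                f"hot region {chrom}:{start}-{end} holds only {len(pool)} genes; "
                f"planting those instead of the requested {want}",
                stacklevel=3,
            )
            want = len(pool)
        picked = list(rng.choice(pool, size=want, replace=False)) if want else []
        chosen.extend(picked)
        hot_planted[ri] = set(picked)
    remaining = config.n_de_genes - len(chosen)
    if remaining > 0:
        pool = [g for g in all_ids if g not in set(chosen)]
        chosen.extend(rng.choice(pool, size=remaining, replace=False))
    return chosen, hot_planted


def generate_counts(
    annotation: GeneAnnotation, config: SimConfig
) -> tuple[CountMatrix, GroundTruth]:
    """Draw NB(mean, dispersion) counts for every design sample.

    The count variance follows var = m + d * m**2 (gamma-Poisson mixture).
    Planted DE genes get group means differing by their true log2FC between
    the two genotypes (the second genotype in design order carries the
    shift); tissues share gene means so the genotype contrast is the only
    planted signal.
    """
    config.validate()
    if annotation.n_genes != config.n_genes:
        raise DimensionError(
            f"annotation has {annotation.n_genes} genes, config expects {config.n_genes}"
        )
    rng = _rng(config.seed, _STREAM_COUNTS)
    gene_ids = list(annotation.gene_ids)
    n = len(gene_ids)

    lo, hi = config.nb_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    de_genes, hot_planted = _choose_de_genes(annotation, config, rng)
    de_idx = pd.Index(gene_ids).get_indexer(de_genes)
    flo, fhi = config.de_log2fc_range
    lfc = np.zeros(n)
    if len(de_idx):
        mag = rng.uniform(flo, fhi, size=len(de_idx))
        sign = rng.choice([-1.0, 1.0], size=len(de_idx))
        lfc[de_idx] = mag * sign

    genotypes = list(dict.fromkeys(g for g, _, _ in config.design))
    shifted = genotypes[1] if len(genotypes) > 1 else None

    cols, rows = [], []
    d = config.nb_dispersion
    for genotype, tissue, n_rep in config.design:
        mean = base_mean * np.power(2.0, lfc) if genotype == shifted else base_mean
        for r in range(1, n_rep + 1):
            lam = rng.gamma(shape=1.0 / d, scale=mean * d)
            cols.append(rng.poisson(lam))
            rows.append((f"{genotype}_{tissue}_{r}", genotype, tissue, r))

    counts = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(gene_ids, name="gene_id"),
        columns=[r[0] for r in rows],
    )
    design = pd.DataFrame(rows, columns=["sample", "genotype", "tissue", "replicate"])
    truth = GroundTruth(
        de_gene_ids=set(de_genes),
        true_log2fc=pd.Series(lfc, index=counts.index, name="true_log2fc"),
        hot_regions=list(config.hot_regions),
        hot_planted=hot_planted,
        hormone_true_means=pd.DataFrame(
            {
                "analyte": [h.name for h in config.hormone_spec],
                "mean_a": [h.mean_a for h in config.hormone_spec],
                "mean_b": [h.mean_b for h in config.hormone_spec],
            }
        ),
    )
    return CountMatrix(counts=counts, design=design), truth


# ---------------------------------------------------------------------------
# Hormones
# ---------------------------------------------------------------------------

def generate_hormone_panel(config: SimConfig) -> pd.DataFrame:
    """Simulate replicate analyte contents (long table).

    Replicates are lognormal around the true group mean with the analyte's
    CV: content = exp(N(mu, sigma^2)) with sigma^2 = ln(1 + CV^2) and
    mu = ln(mean) - sigma^2/2, so the arithmetic mean is exactly the group
    mean and CV = 0 degenerates to the mean itself. Columns: analyte,
    rt_min, group, replicate, content.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_HORMONES)
    genotypes = list(dict.fromkeys(g for g, _, _ in config.design))
    group_a = genotypes[0] if genotypes else "groupA"
    group_b = genotypes[1] if len(genotypes) > 1 else "groupB"

    rows = []
    for h in config.hormone_spec:
        sigma2 = math.log1p(h.cv**2)
        sigma = math.sqrt(sigma2)
        for group, mean in ((group_a, h.mean_a), (group_b, h.mean_b)):
            mu = math.log(mean) - sigma2 / 2.0
            draws = np.exp(rng.normal(mu, sigma, size=h.n_replicates)) if sigma > 0 else np.full(h.n_replicates, mean)
            for r, content in enumerate(draws, start=1):
                rows.append((h.name, h.rt_min, group, r, float(content)))
    return pd.DataFrame(rows, columns=["analyte", "rt_min", "group", "replicate", "content"])


# ---------------------------------------------------------------------------
# QTL intervals and term annotations
# ---------------------------------------------------------------------------

def generate_qtl_bed(intervals: list[tuple[str, int, int, str]]) -> pd.DataFrame:
    """Validate named QTL intervals (0-based half-open) into a BED-like frame."""
    for chrom, start, end, name in intervals:
        if start >= end:
            raise InvalidIntervalError(f"QTL {name!r}: start {start} >= end {end}")
        if start < 0:
            raise InvalidIntervalError(f"QTL {name!r}: negative start")
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end", "name"])
    df["width"] = df["end"] - df["start"]
    return df


def generate_term_annotation(
    annotation: GeneAnnotation,
    n_terms: int,
    size_range: tuple[int, int],
    enriched_terms: list[tuple[str, int, float]] | None = None,
    seed: int = 0,
    de_genes: set[str] | None = None,
) -> dict[str, set[str]]:
    """Random term -> gene-set map over the annotation's gene universe.

    ``enriched_terms`` are (term_id, size, de_fraction) triples whose
    members oversample from ``de_genes`` at the stated rate; background
    terms draw uniformly with sizes uniform in ``size_range``.
    """
    lo, hi = size_range
    if not (1 <= lo <= hi <= annotation.n_genes):
        raise InvalidConfigError("size_range must lie within [1, n_genes]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_TERMS]))
    universe = np.array(annotation.gene_ids)
    terms: dict[str, set[str]] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        terms[f"TERM:{i + 1:04d}"] = set(rng.choice(universe, size=size, replace=False))
    for name, size, rate in enriched_terms or []:
        if not (0.0 <= rate <= 1.0):
            raise InvalidConfigError(f"term {name!r}: oversample rate must be in [0,1]")
        de_pool = np.array(sorted(de_genes or set()))
        n_de = min(round(rate * size), len(de_pool))
        members = set(rng.choice(de_pool, size=n_de, replace=False)) if n_de else set()
        rest_pool = np.array([g for g in universe if g not in members])
        members |= set(rng.choice(rest_pool, size=size - len(members), replace=False))
        terms[name] = members
    return terms
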