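# Methods

## Scope and data model

chillseq analyzes a two-genotype × two-tissue × triplicate bulk RNA-seq
design together with a replicated targeted phytohormone panel. Internal
genomic coordinates are 0-based half-open everywhere; BED/bedGraph files
keep that convention on disk, while GFF3 and printed gene tables are
1-based inclusive and converted on load. Counts are integer fragment
counts (genes × samples) with a sample design table (genotype, tissue,
replicate); hormone data are long tables of replicate contents in ng/g.

## Expression stage

FPKM(g, s) = count · 10⁹ / (librarySize(s) · length(g)), with library
sizes defaulting to column sums of the count matrix (true mapped-fragment
totals can be supplied when known). The transformation is exactly
invertible given lengths and library sizes, which the tests exploit as a
round-trip property.

"Detected" has no universal definition; the default rule is
FPKM ≥ 0.1 in ≥ 1 replicate of the tissue, both knobs exposed. Tissue
specificity is plain set difference of the two detection calls.

Replicate QC computes pairwise Pearson r² on log₂(FPKM+1) (pseudocount 1;
the data are zero-inflated at low expression) and flags replicate pairs
below r² = 0.9, the conventional reproducibility bar for biological
replicates of this kind. Samples with constant log expression have
undefined correlations and are reported, not fatal. PCA coordinates come
from the SVD of the sample-centered log matrix.

## Differential expression

The test is a deliberately transparent NB Wald test, not a GLM
re-implementation; on real data it will not agree gene-for-gene with
full-featured packages, and is not meant to.

1. **Size factors** — median-of-ratios: per-gene geometric-mean
   reference over genes positive in all samples; median ratio per
   sample. Fallback to library-size ratios (normalized to geometric mean
   1, with a warning) when no gene is positive everywhere.
2. **Dispersion** — per-gene pooled method of moments on normalized
   counts, then shrunk toward the across-genes **mean** with prior
   weight 20 pseudo-df and floored at 0.01. Two choices matter here and
   were made for calibration, verified on null simulations:
   * a raw 3v3 moment estimate is far too noisy to plug into a Wald
     variance (anti-conservative: null KS distance from uniform up to
     0.09); heavy shrinkage toward a pooled value fixes this while a
     heavy-tailed t reference would instead destroy power at FDR < 0.01;
   * the pooled value is the *mean*, not the median, of the gene-wise
     estimates: the estimator is right-skewed, and a median biases the
     pooled dispersion low (0.07 for a true 0.1), which again makes the
     test anti-conservative.
   With both in place, null p-values are uniform to KS < 0.05 per
   2,000-gene simulation.
3. **Wald test** — L = ln(m₂+ε) − ln(m₁+ε) with ε = 0.5 normalized
   counts; delta-method variance from Var(mean) = (m/s̄ + d·m²)/n per
   group; two-sided normal p-value. All-zero genes get p = 1, log2FC = 0.
4. **FDR and calling** — Benjamini–Hochberg (statsmodels) and the DEG
   rule |log2FC| ≥ log2(2) with FDR < 0.01, the FDR inequality strict.
   The FC threshold is applied symmetrically to up- and down-regulation.

Benchmarks computed by the test suite at the generator's defaults:
null DEG fraction ≈ 0 (≤ 0.02 required), recall ≥ 0.8 for planted
|log2FC| ≥ 2 at mean ≥ 50, 3v3. The precision of the log2FC estimate is
dispersion-limited (sampling sd ≈ sqrt(Σ(1/m+d)/n)/ln2 ≈ 0.22 at the
default d = 0.03), which bounds how tightly point estimates can be
expected to cluster around truth.

## Positional enrichment scan

Each chromosome is tiled with fixed, non-overlapping, half-open bins;
each gene is assigned to exactly one bin by its start coordinate
(midpoint rule available). Single assignment yields an exact
conservation law — the gene-count-weighted mean index over non-empty
bins is identically 1 — which the tests assert to 10⁻¹².

Empty bins have an *undefined* index (not 0) and are excluded from
calling, though they may be bridged inside a region. Regions are maximal
runs of bins with index > threshold (default 3, exclusive), bridging up
to `max_gap_bins` (default 1) sub-threshold or empty bins, kept when the
span holds ≥ `min_degs` (default 3 — a guard against single-gene spikes
in sparse bins, not an externally given value). QTL overlap is half-open
interval intersection of ≥ 1 bp; QTLs on unknown chromosomes warn and
never match.

**Bin size.** The index formula is scale-free but its variance is not:
at 5-kb bins a genome of this gene density leaves nearly every bin with
0–1 genes and a degenerate index, while reported enrichment regions span
more than a megabase. The default is therefore 500 kb, always
configurable; at desk scale (2,000 genes over ~190 Mb) this yields ~5
genes per bin, enough for index > 3 to be meaningful.

## Hormone panel

Per analyte: fold change of group arithmetic means and a two-sample
t-test on replicates (pooled-variance Student's t by default — the
common reading of an unqualified "two-sample t-test" — Welch by flag).
Reports round FC to 2 decimals and p to 3, the usual table precision.
The report prints both FC orientations (A/B and B/A) because published
panel tables are inconsistent about which group is the numerator; the
headline `fc` column is first-group / second-group in table order.
Constant replicate vectors are detected by exact range (a variance
computed around an unrepresentable mean is ~10⁻³² rather than 0) and map
to p = 1 for equal means, p = 0 otherwise. No multiple-testing
correction is applied across analytes, matching standard practice for
small targeted panels.

## Over-representation

Upper-tail hypergeometric test per term: p = P(X ≥ k) for
X ~ Hypergeom(|universe|, term size, |query|), BH-corrected across
terms. The recommended universe is the set of genes detected in the
relevant tissue. Term genes outside the universe are dropped before
testing. Depletion is not reported. No ontology structure (DAG
propagation, pathway topology) is modelled.

## Synthetic data generator

The generator emulates the *statistical* structure of the emulated
experiment, not its biology:

* **Genome** — 7 chromosomes at approximately cucumber (Chinese Long v3)
  lengths, default 2,000 genes (desk scale; configurable up to real-size
  gene counts), lengths uniform in 0.5–5 kb. Placement is uniform per
  chromosome weighted by length, with density inside designated hot
  regions multiplied by `density_boost` (default 10) — a stand-in for
  non-uniform gene density that also guarantees hot regions hold enough
  genes to absorb their plantings (~110 genes per default 1-Mb region).
* **Counts** — gamma-Poisson (NB) with var = m + d·m², baseline means
  log-uniform in 5–500, dispersion d = 0.03 by default. This value
  represents biological CV ≈ 17%, typical of triplicates of genetically
  identical plant material, and makes default-simulation replicates
  clear the r² > 0.9 reproducibility bar that the emulated experiment's
  QC reports — the generator is calibrated to that property, and the
  acceptance script recomputes the resulting r² floor.
* **Planted DE** — default 50 genes with |log2FC| uniform in [2, 3],
  random sign, applied to the second genotype in all tissues. A per-hot-
  region fraction (default: one 1-Mb chr6 region, fraction 1.0) fixes
  how many land inside hot regions: floor(fraction × n_de), but at least
  one when the fraction is positive; the remainder uniform genome-wide.
* **Hormones** — 17 analytes; seven carry the measured leaf contents of
  the two genotypes under chilling (true group differences from 1.22× to
  3.26×), ten have equal means. Replicates are lognormal with CV 0.15
  around the true mean, parametrized so the arithmetic mean is exact
  (σ² = ln(1+CV²), μ = ln(mean) − σ²/2); CV = 0 degenerates to the mean.
* **Terms** — random gene sets, with designated enriched terms
  oversampling planted DE genes at a stated rate.

All generators are pure functions of (config, seed), drawing from named
substreams of one root `SeedSequence`, so stages are independently
byte-reproducible.

What passing tests do *not* show about real data: no read-level error,
mapping ambiguity, batch structure, length bias, isoform mixing,
gene–gene correlation, or mean-dependent dispersion is simulated, and
the true distribution of the emulated experiment's data is unknown
beyond its design — the distributional choices above are documented
stand-ins.

## Problem sizes and numerical choices

The test suite and acceptance script run simulations at 2,000 genes,
3 replicates per cell, 20–50 seeds per stochastic claim — sizes chosen
so the whole suite completes in seconds while leaving Monte-Carlo margins
(e.g. hotspot recovery is required at ≥ 90% and measured at 100%).
Degenerate inputs are defined, not crashed: all-zero genes are null
results, empty bins have undefined index, constant QC samples are
flagged, empty QTL sets annotate nothing. Ties in BH are handled by the
step-up running minimum; region calling breaks no ties (runs are
deterministic given the track).

## Known limitations

* The DE test is two-group only: no covariates, no shrinkage of fold
  changes, no outlier handling.
* The enrichment scan has no statistical null (no permutation/Poisson
  significance); index > 3 is a heuristic cutoff inherited from the
  analysis style it reproduces, and calls in sparse bins lean on
  `min_degs`.
* FPKM is the only expression unit (by design); library size defaults to
  column sums, which differs from true mapped-fragment totals.
* The hormone stage models only the downstream statistics of a targeted
  panel, not acquisition, peak integration or calibration.
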