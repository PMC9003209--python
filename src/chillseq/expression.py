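"""FPKM normalization, detection calls, tissue specificity, replicate QC."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ChillseqError, DimensionError
from .simulate import CountMatrix

#: Default detection rule: FPKM >= 0.1 in at least one replicate of the
#: tissue. How "detected" was defined upstream of the published gene counts
#: is not stated anywhere we know of; this is the package's documented
#: assumption and both knobs are exposed.
DEFAULT_DETECT_FPKM = 0.1
DEFAULT_DETECT_MIN_REPLICATES = 1

#: Replicate-QC bar: biological replicates are expected to correlate with
#: r^2 > 0.9 on log2(FPKM+1).
DEFAULT_R2_MIN = 0.9


@dataclass
class ExpressionMatrix:
    """FPKM values (genes x samples) with the lengths and library sizes
    used to compute them, so counts can be reconstructed exactly."""

    values: pd.DataFrame
    gene_lengths: pd.Series
    library_sizes: pd.Series


@dataclass
class QCReport:
    """Pairwise sample correlation, PCA coordinates and replicate flags."""

    r2: pd.DataFrame  # symmetric, unit diagonal; NaN where undefined
    pca: pd.DataFrame  # samples x (PC1, PC2)
    flagged_pairs: list[tuple[str, str, float]]  # replicate pairs with r2 < r2_min
    degenerate_samples: list[str]  # constant log-expression vectors


def compute_fpkm(
    counts: CountMatrix | pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM(g, s) = count(g, s) * 1e9 / (librarySize(s) * length(g)).
    Library sizes default to the column sums of the count matrix.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    lengths = lengths.reindex(mat.index)
    if lengths.isna().any():
        raise DimensionError("gene lengths missing for some genes in the count matrix")
    if (lengths <= 0).any():
        raise ChillseqError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = mat.sum(axis=0)
    else:
        library_sizes = library_sizes.reindex(mat.columns)
        if library_sizes.isna().any():
            raise DimensionError("library sizes missing for some samples")
    if (library_sizes <= 0).any():
        raise ChillseqError("library sizes must be positive")
    fpkm = mat * 1e9
    fpkm = fpkm.div(library_sizes, axis=1).div(lengths, axis=0)
    return ExpressionMatrix(
        values=fpkm, gene_lengths=lengths.astype(float), library_sizes=library_sizes.astype(float)
    )


def counts_from_fpkm(expr: ExpressionMatrix) -> pd.DataFrame:
    """Invert the FPKM formula (floating-point reconstruction of counts)."""
    return (
        expr.values.mul(expr.library_sizes, axis=1).mul(expr.gene_lengths, axis=0) / 1e9
    )


def detect_genes(
    expr: ExpressionMatrix,
    samples: list[str],
    threshold: float = DEFAULT_DETECT_FPKM,
    min_replicates: int = DEFAULT_DETECT_MIN_REPLICATES,
) -> set[str]:
    """Genes with FPKM >= threshold in at least ``min_replicates`` of the
    given samples (typically all replicates of one tissue)."""
    if not samples:
        raise ChillseqError("detection requires at least one sample")
    missing = [s for s in samples if s not in expr.values.columns]
    if missing:
        raise DimensionError(f"samples not in expression matrix: {missing}")
    hits = (expr.values[samples] >= threshold).sum(axis=1)
    return set(expr.values.index[hits >= min_replicates])


def tissue_specific(
    detected_a: set[str], detected_b: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """(a_only, b_only, shared) set decomposition of two detection calls."""
    return detected_a - detected_b, detected_b - detected_a, detected_a & detected_b


def replicate_qc(
    expr: ExpressionMatrix,
    design: pd.DataFrame,
    r2_min: float = DEFAULT_R2_MIN,
) -> QCReport:
    """Reproducibility check on log2(FPKM+1).

    Computes the full pairwise Pearson r^2 matrix, flags biological
    replicate pairs (same genotype and tissue) falling below ``r2_min``,
    and projects samples onto the first two principal components of the
    centered log matrix (via SVD). Samples with constant log expression
    have undefined correlations; they are reported rather than erroring.
    """
    log = np.log2(expr.values + 1.0)
    if log.shape[1] < 2:
        raise ChillseqError("replicate QC needs at least two samples")
    samples = list(log.columns)
    sd = log.std(axis=0, ddof=0)
    degenerate = list(sd.index[sd == 0])
    if degenerate:
        warnings.warn(
            f"constant log-expression in samples {degenerate}; correlations undefined",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(log.to_numpy().T)
    r2 = pd.DataFrame(r**2, index=samples, columns=samples)
    for s in degenerate:
        r2.loc[s, :] = np.nan
        r2.loc[:, s] = np.nan
    np.fill_diagonal(r2.values, 1.0)

    flagged: list[tuple[str, str, float]] = []
    for _, grp in design.groupby(["genotype", "tissue"]):
        reps = [s for s in grp["sample"] if s in samples]
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                val = r2.loc[reps[i], reps[j]]
                if np.isnan(val) or val < r2_min:
                    flagged.append((reps[i], reps[j], float(val)))

    X = log.to_numpy().T  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(2, U.shape[1])
    coords = U[:, :k] * S[:k]
    if k < 2:  # pad when fewer than two informative components exist
        coords = np.pad(coords, ((0, 0), (0, 2 - k)))
    pca = pd.DataFrame(coords, index=samples, columns=["PC1", "PC2"])
    return QCReport(r2=r2, pca=pca, flagged_pairs=flagged, degenerate_samples=degenerate)


def plot_qc(report: QCReport, path) -> None:
    """PCA scatter of samples, one point per sample, labelled."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(report.pca["PC1"], report.pca["PC2"], s=20)
    for name, row in report.pca.iterrows():
        ax.annotate(name, (row["PC1"], row["PC2"]), fontsize=6)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
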