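"""Hypergeometric over-representation analysis of a gene set.

Generic replacement for GO/KEGG enrichment: the caller supplies the
term -> gene-set map (any annotation source), a query set (typically the
DEGs of one comparison) and a background universe (typically all genes
detected in the relevant tissue). Only over-representation (upper tail)
is scored; depletion is not reported.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .errors import ChillseqError
from .diffexp import adjust_bh


def hypergeom_enrich(
    query: set[str],
    universe: set[str],
    terms: dict[str, set[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric test per term, BH-corrected across terms.

    For a term with n members in a universe of M genes and a query of N
    genes, k observed hits give p = P(X >= k), X ~ Hypergeom(M, n, N).
    Columns: term, term_size, hits, cluster_frequency (hits/|query|),
    genome_frequency (term_size/|universe|), p, padj; sorted by padj then
    p. Term genes outside the universe are ignored (annotation wider than
    the measured background).
    """
    if not query:
        raise ChillseqError("empty query set")
    stray = query - universe
    if stray:
        raise ChillseqError(
            f"query genes outside the universe: {sorted(stray)[:5]} ..."
        )
    M, N = len(universe), len(query)
    rows = []
    for term, genes in terms.items():
        members = genes & universe
        n = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append(
            {
                "term": term,
                "term_size": n,
                "hits": k,
                "cluster_frequency": k / N,
                "genome_frequency": n / M,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "term_size", "hits", "cluster_frequency",
                       "genome_frequency", "p"],
    )
    if len(out):
        out["padj"] = adjust_bh(out["p"].to_numpy())
        out = out.sort_values(["padj", "p"], kind="stable").reset_index(drop=True)
    else:
        out["padj"] = pd.Series(dtype=float)
    return out


def read_term_annotation(path) -> dict[str, set[str]]:
    """2-column TSV (term, gene) -> term->gene-set map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"])
    return {t: set(sub["gene"]) for t, sub in df.groupby("term")}


def write_term_annotation(terms: dict[str, set[str]], path) -> None:
    rows = [(t, g) for t in terms for g in sorted(terms[t])]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
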