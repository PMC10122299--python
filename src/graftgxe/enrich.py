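"""Hypergeometric functional-term enrichment with Bonferroni correction.

Query gene sets (SOM clusters, heavy PCA loaders) are tested against a
filtered gene -> term annotation: for each term the upper-tail probability
P(X >= k) of drawing k or more annotated genes in a query of size n from a
universe of N genes containing K term members. The correction follows the
source procedure — Bonferroni by the number of genes considered — with
term-count Bonferroni and Benjamini-Hochberg available as clearly labeled
alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import AnnotationMap

__all__ = [
    "EnrichmentResult",
    "filter_annotation",
    "hypergeom_enrich",
    "correct_and_flag",
]


@dataclass
class EnrichmentResult:
    """Per-term overlap counts and p-values.

    Columns: term, N (universe), K (term size), n (query), k (overlap),
    p_value; after correction also p_corrected, significant, alpha, scheme.
    """

    data: pd.DataFrame


def filter_annotation(
    annotation: AnnotationMap, max_evalue: float = 1e-10, keep_missing: bool = False
) -> AnnotationMap:
    """Keep records with E-value strictly below ``max_evalue``.

    Records without an E-value are dropped unless ``keep_missing``.
    """
    df = annotation.data
    has = df["evalue"].notna()
    keep = has & (df["evalue"] < max_evalue)
    if keep_missing:
        keep = keep | ~has
    return AnnotationMap(df[keep].reset_index(drop=True))


def hypergeom_enrich(
    query_genes, annotation: AnnotationMap, universe_genes
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of each term in the query.

    Annotation records are intersected with the universe first; the query
    must be a subset of the universe. An empty query yields p = 1 everywhere.
    """
    universe = list(dict.fromkeys(universe_genes))
    if not universe:
        raise ValueError("empty universe")
    uset = set(universe)
    query = list(dict.fromkeys(query_genes))
    stray = [g for g in query if g not in uset]
    if stray:
        raise ValueError(f"query gene(s) not in universe: {stray[:3]}")
    ann = annotation.data[annotation.data["gene"].isin(uset)]
    N = len(universe)
    n = len(query)
    qset = set(query)
    rows = []
    for term, group in ann.groupby("term", sort=True):
        members = set(group["gene"])
        K = len(members)
        k = len(members & qset)
        # P(X >= k) under sampling n from N with K marked
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append({"term": term, "N": N, "K": K, "n": n, "k": k, "p_value": min(p, 1.0)})
    cols = ["term", "N", "K", "n", "k", "p_value"]
    return EnrichmentResult(pd.DataFrame(rows, columns=cols))


def correct_and_flag(
    result: EnrichmentResult, alpha: float = 1e-5, scheme: str = "gene-bonferroni"
) -> EnrichmentResult:
    """Multiple-testing correction and significance flags.

    Schemes: ``gene-bonferroni`` multiplies p by the universe gene count (the
    source procedure's stated convention, unconventional but implemented as
    stated); ``term-bonferroni`` multiplies by the number of terms tested;
    ``bh`` applies Benjamini-Hochberg. Corrected p-values are capped at 1;
    significant iff corrected p < alpha.
    """
    df = result.data.copy()
    if df.empty:
        df["p_corrected"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    elif scheme == "gene-bonferroni":
        df["p_corrected"] = np.minimum(df["p_value"] * df["N"], 1.0)
    elif scheme == "term-bonferroni":
        df["p_corrected"] = np.minimum(df["p_value"] * len(df), 1.0)
    elif scheme == "bh":
        p = df["p_value"].to_numpy()
        order = np.argsort(p, kind="stable")
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            adj[i] = running
        df["p_corrected"] = adj
    else:
        raise ValueError(
            "scheme must be 'gene-bonferroni', 'term-bonferroni' or 'bh'"
        )
    if not df.empty:
        df["significant"] = df["p_corrected"] < alpha
    df["alpha"] = alpha
    df["scheme"] = scheme
    return EnrichmentResult(
        df.sort_values(["p_corrected", "p_value", "term"]).reset_index(drop=True)
    )
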