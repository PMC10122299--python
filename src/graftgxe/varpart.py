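"""Per-gene linear-model variance partitioning and gene selection.

Each gene's VST expression is modeled on the full design — tissue, year,
phenology, irrigation, and rootstock main effects plus all pairwise
interactions among {rootstock, tissue, year, phenology} — and each term's
share of the total sum of squares is computed by a sequential (Type-I)
decomposition in a fixed, documented order. Under that scheme term fractions
plus the residual sum exactly to one, which makes "variance explained by
rootstock" unambiguous. Genes at or above a percentile of rootstock variance
explained are selected for clustering.

Year and phenology are treated as unordered factors. Columns aliased by
missing design cells are dropped (and recorded) before fitting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SampleTable
from .normalize import ExpressionMatrix

__all__ = [
    "DesignMatrix",
    "VariancePartition",
    "MAIN_TERMS",
    "INTERACTION_FACTORS",
    "build_design",
    "variance_explained",
    "sequential_ss",
    "select_top_percentile",
]

#: Fixed main-effect order for the sequential decomposition: rootstock last
#: among mains so its fraction is net of the large structural factors.
MAIN_TERMS = ("tissue", "year", "phenology", "irrigation", "rootstock")
#: Factors whose pairwise interactions enter the model.
INTERACTION_FACTORS = ("rootstock", "tissue", "year", "phenology")


@dataclass
class DesignMatrix:
    """Treatment-coded design with a coefficient -> term map.

    ``matrix`` has full column rank: columns aliased in the declared order
    (e.g. interaction contrasts lost to an empty design cell) are removed and
    listed in ``aliased``.
    """

    matrix: np.ndarray
    columns: list
    term_of: list
    terms: list
    aliased: list = field(default_factory=list)
    row_ids: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def term_blocks(self) -> dict:
        blocks: dict = {t: [] for t in self.terms}
        for j, t in enumerate(self.term_of):
            blocks[t].append(j)
        return blocks


def _dummies(values: pd.Series, name: str) -> tuple:
    """Treatment-coded indicator columns (first level dropped), levels in
    sorted order for determinism."""
    levels = sorted(pd.unique(values), key=str)
    if len(levels) < 2:
        raise ValueError(f"factor {name!r} has a single level: {levels}")
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((values == lev).to_numpy(float))
        names.append(f"{name}[{lev}]")
    return cols, names


def build_design(
    meta: SampleTable,
    main_terms=MAIN_TERMS,
    interaction_factors=INTERACTION_FACTORS,
    interactions: bool = True,
) -> DesignMatrix:
    """Build the treatment-coded design in the fixed term order.

    Order: intercept, main effects as declared, then pairwise interactions of
    ``interaction_factors`` in declared pair order. Rank-deficient columns
    are dropped in order (later columns lose) and recorded.
    """
    df = meta.data
    for t in main_terms:
        if t not in df.columns:
            raise ValueError(f"term {t!r} not in metadata")
    cols = [np.ones(len(df))]
    names = ["intercept"]
    term_of = ["intercept"]
    terms = ["intercept"]

    factor_cols: dict = {}
    for t in main_terms:
        c, n = _dummies(df[t].astype(str), t)
        factor_cols[t] = (c, n)
        cols.extend(c)
        names.extend(n)
        term_of.extend([t] * len(c))
        terms.append(t)

    if interactions:
        for f1, f2 in itertools.combinations(interaction_factors, 2):
            term = f"{f1}:{f2}"
            terms.append(term)
            c1, n1 = factor_cols[f1] if f1 in factor_cols else _dummies(df[f1].astype(str), f1)
            c2, n2 = factor_cols[f2] if f2 in factor_cols else _dummies(df[f2].astype(str), f2)
            for (a, na), (b, nb) in itertools.product(zip(c1, n1), zip(c2, n2)):
                cols.append(a * b)
                names.append(f"{na}:{nb}")
                term_of.append(term)

    X = np.column_stack(cols)
    keep, aliased = _rank_select(X)
    return DesignMatrix(
        matrix=X[:, keep],
        columns=[names[j] for j in keep],
        term_of=[term_of[j] for j in keep],
        terms=terms,
        aliased=[names[j] for j in range(X.shape[1]) if j not in set(keep)],
        row_ids=df["sample"].tolist(),
    )


def _rank_select(X: np.ndarray, tol: float = 1e-8) -> tuple:
    """Greedy in-order selection of linearly independent columns via
    Gram-Schmidt; returns (kept indices, dropped indices)."""
    n, p = X.shape
    Q = np.empty((n, 0))
    keep, drop = [], []
    for j in range(p):
        v = X[:, j].astype(float)
        norm0 = np.linalg.norm(v)
        if norm0 == 0:
            drop.append(j)
            continue
        for _ in range(2):  # re-orthogonalize for stability
            v = v - Q @ (Q.T @ v)
        if np.linalg.norm(v) <= tol * norm0:
            drop.append(j)
            continue
        Q = np.column_stack([Q, v / np.linalg.norm(v)])
        keep.append(j)
    return keep, drop


def sequential_ss(Y: np.ndarray, design: DesignMatrix) -> tuple:
    """Sequential (Type-I) sums of squares for each response column of Y.

    Returns ``(ss, terms, total_ss)`` where ``ss[t]`` maps each non-intercept
    term to a vector of per-response sums of squares, computed by projecting
    onto an in-order orthonormal basis of the design. Total SS is centered
    (about the intercept fit).
    """
    X = design.matrix
    Q, _ = np.linalg.qr(X)  # column order preserved; X has full rank
    proj = Q.T @ Y  # basis x responses
    sq = proj**2
    blocks = design.term_blocks()
    # map columns of X to columns of Q: QR without pivoting keeps order 1:1
    col_pos = {j: j for j in range(X.shape[1])}
    ss = {}
    for term in design.terms:
        if term == "intercept":
            continue
        idx = [col_pos[j] for j in blocks.get(term, [])]
        ss[term] = sq[idx].sum(axis=0) if idx else np.zeros(Y.shape[1])
    mean = Y.mean(axis=0, keepdims=True)
    total = ((Y - mean) ** 2).sum(axis=0)
    return ss, [t for t in design.terms if t != "intercept"], total


@dataclass
class VariancePartition:
    """Per-gene variance-explained fractions per term plus residual.

    Fractions lie in [0, 1] and sum to 1 with the residual under the
    sequential scheme. Genes with zero total SS are excluded and listed.
    """

    fractions: pd.DataFrame  # genes x (terms..., residual)
    excluded_genes: list = field(default_factory=list)


def variance_explained(expr: ExpressionMatrix, design: DesignMatrix) -> VariancePartition:
    """Decompose each gene's total SS over the design terms (sequential)."""
    if design.row_ids and design.row_ids != list(expr.samples):
        raise ValueError("design rows do not align with expression samples")
    Y = expr.values.T  # samples x genes
    ss, terms, total = sequential_ss(Y, design)
    nonzero = total > 1e-12
    frac = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for t in terms:
            frac[t] = np.where(nonzero, ss[t] / np.where(nonzero, total, 1.0), np.nan)
    df = pd.DataFrame(frac, index=expr.genes)
    df["residual"] = 1.0 - df.sum(axis=1)
    df = df.clip(lower=0.0, upper=1.0)
    excluded = [g for g, nz in zip(expr.genes, nonzero) if not nz]
    return VariancePartition(df.loc[[g for g in expr.genes if g not in set(excluded)]], excluded)


def select_top_percentile(
    partition: VariancePartition, term: str = "rootstock", q: float = 0.75
) -> tuple:
    """Genes whose variance-explained fraction for ``term`` is at or above
    the q-th percentile (linear-interpolation quantile, inclusive threshold).

    Returns ``(genes, threshold)``.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    if term not in partition.fractions.columns:
        raise ValueError(f"term {term!r} not in partition")
    vals = partition.fractions[term]
    if vals.empty:
        raise ValueError("empty variance partition")
    threshold = float(np.quantile(vals.to_numpy(), q, method="linear"))
    genes = vals.index[vals >= threshold].tolist()
    return genes, threshold
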