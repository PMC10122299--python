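"""Filtering, median-of-ratios normalization, dispersion trend, and VST.

The count matrix is normalized with per-sample size factors (median of the
ratios of each sample's counts to per-gene geometric means), a parametric
mean-dispersion trend alpha(mu) = a1/mu + a0 is fitted by robust regression
of method-of-moments gene dispersions on 1/mu, and counts are transformed
with the closed-form variance-stabilizing transform implied by that trend,
rescaled so the transform approaches log2 of the normalized count for large
counts.

Only the transform is carried downstream; no shrinkage or testing happens
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import CountMatrix, SampleTable

__all__ = [
    "SizeFactors",
    "DispersionTrend",
    "ExpressionMatrix",
    "filter_genes",
    "size_factors",
    "fit_dispersion_trend",
    "vst",
    "vst_values",
    "scale_genes",
    "housekeeping_profile",
]


@dataclass
class SizeFactors:
    """Per-sample positive scale factors, rescaled to geometric mean 1.

    Computed from the reference set of genes with no zero count across
    samples (or a pseudo-reference over positive counts when requested).
    """

    samples: list
    values: np.ndarray
    n_reference_genes: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if (self.values <= 0).any() or not np.isfinite(self.values).all():
            raise ValueError("size factors must be positive and finite")


@dataclass
class DispersionTrend:
    """Fitted alpha(mu) = a1/mu + a0 with a0, a1 >= 0.

    ``degenerate`` flags an all-zero-dispersion fit (e.g. Poisson or
    constant-count input).
    """

    a0: float
    a1: float
    n_genes_used: int = 0
    residual_spread: float = float("nan")
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.a0 < 0 or self.a1 < 0:
            raise ValueError("trend coefficients must be non-negative")

    def alpha(self, mu):
        mu = np.asarray(mu, float)
        with np.errstate(divide="ignore"):
            return self.a1 / mu + self.a0


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample matrix on the VST (or scaled) scale."""

    genes: list
    samples: list
    values: np.ndarray
    provenance: dict = field(default_factory=dict)
    constant_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("expression matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.genes)}
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            list(genes), self.samples, self.values[rows], dict(self.provenance)
        )


# ---------------------------------------------------------------------------


def size_factors(matrix: CountMatrix, pseudo_reference: bool = False) -> SizeFactors:
    """Median-of-ratios size factors.

    s_j = median over reference genes g of count_gj / geomean_g, rescaled to
    geometric mean 1. The reference set is genes with all counts positive;
    with ``pseudo_reference`` the geometric mean is taken over positive
    counts only so sparse matrices can still be normalized.
    """
    counts = matrix.counts.astype(float)
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logc = np.log(counts)
        logc[counts == 0] = np.nan
        ref = (counts > 0).any(axis=1)
        loggeo = np.nanmean(logc[ref], axis=1)
        with np.errstate(invalid="ignore"):
            s = np.nanmedian(np.exp(logc[ref] - loggeo[:, None]), axis=0)
    else:
        ref = (counts > 0).all(axis=1)
        if not ref.any():
            raise ValueError(
                "no gene has all counts positive; re-run with pseudo_reference=True"
            )
        loggeo = np.log(counts[ref]).mean(axis=1)
        s = np.median(np.exp(np.log(counts[ref]) - loggeo[:, None]), axis=0)
    if (s <= 0).any() or not np.isfinite(s).all():
        raise ValueError("degenerate size factors; check for all-zero samples")
    s = s / np.exp(np.mean(np.log(s)))
    return SizeFactors(matrix.samples, s, n_reference_genes=int(np.sum(ref)))


def filter_genes(
    matrix: CountMatrix,
    min_count: float = 4,
    min_samples: int = 4,
    sf: SizeFactors | None = None,
    scale: str = "normalized",
) -> CountMatrix:
    """Retain gene g iff its (normalized) count exceeds ``min_count`` —
    strictly — in at least ``min_samples`` samples.

    ``scale='raw'`` applies the rule to raw counts instead; by default size
    factors are computed on the fly when not supplied.
    """
    if min_samples > len(matrix.samples):
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {len(matrix.samples)}"
        )
    counts = matrix.counts.astype(float)
    if scale == "normalized":
        if sf is None:
            sf = size_factors(matrix, pseudo_reference=True)
        counts = counts / sf.values[None, :]
    elif scale != "raw":
        raise ValueError("scale must be 'normalized' or 'raw'")
    keep = (counts > min_count).sum(axis=1) >= min_samples
    genes = [g for g, k in zip(matrix.genes, keep) if k]
    return CountMatrix(genes, matrix.samples, matrix.counts[keep])


def fit_dispersion_trend(matrix: CountMatrix, sf: SizeFactors, min_mu: float = 1.0) -> DispersionTrend:
    """Fit alpha(mu) = a1/mu + a0 from method-of-moments gene dispersions.

    Per gene: alpha_hat = max(0, (var - mu) / mu^2) on normalized counts,
    regressed on 1/mu by Huber robust least squares; negative coefficients
    are clipped to zero. Genes with mean below ``min_mu`` are excluded.
    """
    if len(matrix.genes) < 20:
        raise ValueError("need at least 20 genes to fit a dispersion trend")
    q = matrix.counts / sf.values[None, :]
    mu = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    use = mu > min_mu
    mu_u, var_u = mu[use], var[use]
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.clip((var_u - mu_u) / mu_u**2, 0.0, None)
    alpha_hat = np.nan_to_num(alpha_hat)
    if not alpha_hat.any():
        return DispersionTrend(0.0, 0.0, int(use.sum()), 0.0, degenerate=True)
    X = np.column_stack([np.ones(mu_u.size), 1.0 / mu_u])
    fit = sm.RLM(alpha_hat, X, M=sm.robust.norms.HuberT()).fit()
    a0 = max(0.0, float(fit.params[0]))
    a1 = max(0.0, float(fit.params[1]))
    spread = float(np.median(np.abs(fit.resid - np.median(fit.resid))))
    return DispersionTrend(a0, a1, int(use.sum()), spread, degenerate=False)


def vst_values(q, trend: DispersionTrend):
    """Closed-form VST of normalized counts ``q`` under the fitted trend.

    The transform integrates 1/sqrt(w(q)) with variance function
    w(q) = (1 + a1) q + a0 q^2 and is rescaled to the asymptotic log2 scale:
    vst(q) = log2(2 a0 q + b + 2 sqrt(a0 q (a0 q + b))) - log2(4 a0), b = 1+a1,
    so vst(q) - log2(q) -> 0 as q grows. In the a0 -> 0 (Poisson-like) limit
    there is no log asymptote and the square-root stabilization
    2 sqrt(q / b) / ln 2 is used instead.
    """
    q = np.asarray(q, float)
    if (q < 0).any():
        raise ValueError("normalized counts must be non-negative")
    b = 1.0 + trend.a1
    a0 = trend.a0
    if a0 < 1e-12:
        return 2.0 * np.sqrt(q / b) / np.log(2.0)
    inner = 2.0 * a0 * q + b + 2.0 * np.sqrt(a0 * q * (a0 * q + b))
    return np.log2(inner) - np.log2(4.0 * a0)


def vst(matrix: CountMatrix, sf: SizeFactors, trend: DispersionTrend) -> ExpressionMatrix:
    """Apply the closed-form VST to size-factor-normalized counts."""
    q = matrix.counts / sf.values[None, :]
    values = vst_values(q, trend)
    prov = {
        "size_factors": dict(zip(sf.samples, sf.values.tolist())),
        "trend": {"a0": trend.a0, "a1": trend.a1},
    }
    return ExpressionMatrix(list(matrix.genes), list(matrix.samples), values, prov)


def scale_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score across samples (mean 0, sd 1).

    Idempotent; genes constant across samples become all-zero rows and are
    listed in ``constant_genes`` so callers can drop them.
    """
    v = expr.values
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] < 1e-12
    safe_sd = np.where(sd < 1e-12, 1.0, sd)
    z = (v - mean) / safe_sd
    z[constant] = 0.0
    out = ExpressionMatrix(
        list(expr.genes), list(expr.samples), z, dict(expr.provenance)
    )
    out.constant_genes = [g for g, c in zip(expr.genes, constant) if c]
    return out


def housekeeping_profile(
    expr: ExpressionMatrix,
    gene_sets: dict,
    meta: SampleTable,
    factors=("tissue",),
) -> pd.DataFrame:
    """Survey putatively constitutive gene families across design factors.

    For each named gene set, returns the per-gene mean and sd of VST
    expression within every level of each requested factor (long format).
    Genes absent from the expression matrix are dropped; a set with no
    surviving gene raises.
    """
    df = expr.to_frame()
    md = meta.indexed().loc[[s for s in expr.samples]]
    rows = []
    for set_name, genes in gene_sets.items():
        present = [g for g in genes if g in df.index]
        if not present:
            raise ValueError(f"gene set {set_name!r} has no gene in the expression matrix")
        for factor in factors:
            for level, group in md.groupby(factor, sort=True):
                sub = df.loc[present, group.index]
                for g in present:
                    vals = sub.loc[g]
                    rows.append({
                        "set": set_name,
                        "gene": g,
                        "factor": factor,
                        "level": level,
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=0)),
                        "n": int(len(vals)),
                    })
    return pd.DataFrame(rows)
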