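"""Environmental composite statistics, double PCA, and G x E screening.

The hourly weather record is condensed to daily composite statistics
(min / max / change / mean per averaged feature over a 24-hour window; sums
for precipitation and radiation density), which are standardized and
collapsed with PCA into environmental PCs (ePCs). Gene expression is
collapsed the same way into expression PCs (gPCs). Each (gPC, ePC) pair is
modeled with environment, tissue, and rootstock effects plus all
interactions; terms explaining more than a variance threshold are flagged,
rootstock-specific environment slopes get Tukey-adjusted pairwise contrasts,
and genes loading heavily on implicated gPCs (beyond mean +/- 1.96 sd) form
query sets for functional enrichment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .io import HourlyWeather, SampleTable
from .varpart import DesignMatrix, sequential_ss

__all__ = [
    "SUM_FEATURES",
    "CompositeEnvTable",
    "PCAResult",
    "GxEModelResult",
    "LoaderSets",
    "composite_stats",
    "build_env_table",
    "pca",
    "select_components",
    "attach_env",
    "fit_gpc_model",
    "screen_effects",
    "posthoc_slopes",
    "heavy_loaders",
]

#: Features summarized by their sum over the window rather than min/max/
#: change/mean (accumulation-type quantities).
SUM_FEATURES = ("precipitation", "radiation_density")


@dataclass
class CompositeEnvTable:
    """Daily composite statistics: one row per day (or sampling date),
    columns ``<feature>_{min,max,change,mean}`` for averaged features and
    ``<feature>_sum`` for accumulated ones."""

    data: pd.DataFrame  # indexed by date
    window_hours: int = 24


def composite_stats(
    weather: HourlyWeather,
    anchor_datetime,
    window_h: int = 24,
    sum_features=SUM_FEATURES,
    max_missing_frac: float = 0.25,
) -> pd.Series:
    """Composite statistics of the ``window_h`` hours preceding the anchor.

    The window is the half-open interval (anchor - window, anchor]. Averaged
    features yield min, max, change (max - min) and mean; accumulation
    features yield their sum. Errors if more than ``max_missing_frac`` of the
    expected hours are missing.
    """
    anchor = pd.Timestamp(anchor_datetime)
    df = weather.indexed()
    start = anchor - pd.Timedelta(hours=window_h)
    win = df.loc[(df.index > start) & (df.index <= anchor)]
    if len(win) == 0:
        raise ValueError(f"no weather data in the {window_h} h window ending {anchor}")
    if len(win) < window_h * (1.0 - max_missing_frac):
        raise ValueError(
            f"window ending {anchor} has only {len(win)}/{window_h} hours "
            f"(missing fraction above {max_missing_frac:.0%})"
        )
    out = {}
    for feat in weather.features:
        vals = win[feat].to_numpy(float)
        if feat in sum_features:
            out[f"{feat}_sum"] = float(np.nansum(vals))
        else:
            lo, hi = float(np.nanmin(vals)), float(np.nanmax(vals))
            out[f"{feat}_min"] = lo
            out[f"{feat}_max"] = hi
            out[f"{feat}_change"] = hi - lo
            out[f"{feat}_mean"] = float(np.nanmean(vals))
    return pd.Series(out, name=anchor.normalize())


def build_env_table(
    weather: HourlyWeather,
    meta: SampleTable | None = None,
    all_days: bool = False,
    window_h: int = 24,
    sum_features=SUM_FEATURES,
    max_missing_frac: float = 0.25,
) -> CompositeEnvTable:
    """Composite-statistic table, one row per day.

    With ``all_days`` every calendar day covered by the record gets a row
    (window = that day's 24 hours, anchored at the following midnight); this
    is the table the environmental PCA is fitted on. Otherwise only the
    distinct sampling dates in ``meta`` are summarized (duplicates collapse).
    """
    if all_days:
        dates = sorted(pd.unique(weather.data["timestamp"].dt.normalize()))
    else:
        if meta is None:
            raise ValueError("need sample metadata unless all_days=True")
        dates = sorted(pd.unique(meta.data["datetime"].dt.normalize()))
    rows = []
    for day in dates:
        anchor = pd.Timestamp(day) + pd.Timedelta(hours=24)
        rows.append(
            composite_stats(weather, anchor, window_h, sum_features, max_missing_frac)
        )
    df = pd.DataFrame(rows)
    df.index = pd.DatetimeIndex([pd.Timestamp(d) for d in dates], name="date")
    return CompositeEnvTable(df, window_hours=window_h)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    """SVD-based PCA with a fixed sign convention.

    ``scores`` are observations x components, ``loadings`` variables x
    components (orthonormal), ``variance_fraction`` non-increasing. The sign
    of each component is chosen so its largest-magnitude loading is positive,
    making outputs reproducible across platforms.
    """

    scores: np.ndarray
    loadings: np.ndarray
    variance_fraction: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    row_ids: list = field(default_factory=list)
    col_ids: list = field(default_factory=list)
    dropped_columns: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def pca(table, standardize: bool = True, row_ids=None, col_ids=None) -> PCAResult:
    """PCA via SVD of the centered (and optionally unit-scaled) matrix.

    Zero-variance columns are dropped with a record when standardizing.
    """
    if isinstance(table, CompositeEnvTable):
        table = table.data
    if isinstance(table, pd.DataFrame):
        row_ids = list(table.index) if row_ids is None else row_ids
        col_ids = list(table.columns) if col_ids is None else col_ids
        X = table.to_numpy(float)
    else:
        X = np.asarray(table, float)
        row_ids = row_ids or list(range(X.shape[0]))
        col_ids = col_ids or list(range(X.shape[1]))
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two observations")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    dropped = []
    if standardize:
        keep = sd > 1e-12
        dropped = [c for c, k in zip(col_ids, keep) if not k]
        X = X[:, keep]
        mean, sd = mean[keep], sd[keep]
        col_ids = [c for c, k in zip(col_ids, keep) if k]
        Z = (X - mean) / sd
    else:
        sd = np.ones_like(mean)
        Z = X - mean
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    return PCAResult(
        scores=U * s,
        loadings=Vt.T,
        variance_fraction=frac,
        mean=mean,
        scale=sd,
        row_ids=list(row_ids),
        col_ids=list(col_ids),
        dropped_columns=dropped,
    )


def select_components(result: PCAResult, cum_var: float = 0.80) -> list:
    """Smallest prefix of components whose variance fractions sum to at
    least ``cum_var`` (indices are 0-based)."""
    csum = np.cumsum(result.variance_fraction)
    k = int(np.searchsorted(csum, cum_var - 1e-12) + 1)
    k = min(k, result.n_components)
    return list(range(k))


def attach_env(
    meta: SampleTable, env_table: CompositeEnvTable, epca: PCAResult, components=None
) -> pd.DataFrame:
    """Per-sample ePC scores inherited from the sampling date.

    Errors, naming the sample, when a sampling date has no environment row.
    """
    components = components if components is not None else list(range(epca.n_components))
    score_df = pd.DataFrame(
        epca.scores[:, components],
        index=pd.DatetimeIndex(epca.row_ids),
        columns=[f"ePC{k + 1}" for k in components],
    )
    dates = meta.data["datetime"].dt.normalize()
    missing = ~dates.isin(score_df.index)
    if missing.any():
        bad = meta.data.loc[missing, "sample"].iloc[0]
        raise ValueError(f"sample {bad!r} has no environment row for its date")
    out = score_df.loc[dates].reset_index(drop=True)
    out.insert(0, "sample", meta.data["sample"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# G x E models


#: Fixed sequential term order for the per-(gPC, ePC) model.
GXE_TERMS = (
    "env",
    "tissue",
    "rootstock",
    "env:tissue",
    "env:rootstock",
    "tissue:rootstock",
    "env:tissue:rootstock",
)


@dataclass
class GxEModelResult:
    """One (gPC, ePC) linear model: sequential variance fractions per term,
    per-rootstock environment slopes with a covariance for contrasts."""

    gpc: int
    epc: int
    fractions: dict
    residual: float
    slopes: dict  # rootstock level -> slope of gPC on ePC (tissue-averaged)
    slope_cov: np.ndarray  # covariance of the slope estimates (levels x levels)
    df_resid: int
    rootstock_levels: list
    aliased: list = field(default_factory=list)


def _factor_dummies(values: np.ndarray) -> tuple:
    levels = sorted(pd.unique(values), key=str)
    cols = [(values == lev).astype(float) for lev in levels[1:]]
    return levels, cols


def fit_gpc_model(
    gpc_scores: np.ndarray,
    epc_scores: np.ndarray,
    meta: SampleTable,
    gpc: int = 0,
    epc: int = 0,
) -> GxEModelResult:
    """Model one gPC on one ePC with tissue and rootstock and all
    interactions; sequential-SS variance fractions per term.

    The per-rootstock slope is the derivative of the fitted mean with
    respect to the ePC, averaged over tissue levels with equal weight; its
    covariance supports Tukey pairwise contrasts.
    """
    y = np.asarray(gpc_scores, float)
    e = np.asarray(epc_scores, float)
    md = meta.data
    if not (len(y) == len(e) == len(md)):
        raise ValueError("gPC scores, ePC scores and metadata must align")
    ti_levels, ti_cols = _factor_dummies(md["tissue"].astype(str).to_numpy())
    rs_levels, rs_cols = _factor_dummies(md["rootstock"].astype(str).to_numpy())
    if len(rs_levels) < 2:
        raise ValueError("need at least two rootstock levels")

    cols = [np.ones(len(y))]
    names = ["intercept"]
    term_of = ["intercept"]

    def add(term, arrs, labels):
        for a, lab in zip(arrs, labels):
            cols.append(a)
            names.append(lab)
            term_of.append(term)

    add("env", [e], ["env"])
    add("tissue", ti_cols, [f"tissue[{t}]" for t in ti_levels[1:]])
    add("rootstock", rs_cols, [f"rootstock[{r}]" for r in rs_levels[1:]])
    add("env:tissue", [e * t for t in ti_cols], [f"env:tissue[{t}]" for t in ti_levels[1:]])
    add("env:rootstock", [e * r for r in rs_cols], [f"env:rootstock[{r}]" for r in rs_levels[1:]])
    add(
        "tissue:rootstock",
        [t * r for t, r in itertools.product(ti_cols, rs_cols)],
        [f"tissue[{t}]:rootstock[{r}]" for t, r in itertools.product(ti_levels[1:], rs_levels[1:])],
    )
    add(
        "env:tissue:rootstock",
        [e * t * r for t, r in itertools.product(ti_cols, rs_cols)],
        [f"env:tissue[{t}]:rootstock[{r}]" for t, r in itertools.product(ti_levels[1:], rs_levels[1:])],
    )

    X = np.column_stack(cols)
    from .varpart import _rank_select

    keep, drop = _rank_select(X)
    aliased = [names[j] for j in drop]
    design = DesignMatrix(
        matrix=X[:, keep],
        columns=[names[j] for j in keep],
        term_of=[term_of[j] for j in keep],
        terms=["intercept", *GXE_TERMS],
        row_ids=md["sample"].tolist(),
    )
    ss, terms, total = sequential_ss(y[:, None], design)
    fractions = {t: float(ss[t][0] / total[0]) if total[0] > 0 else 0.0 for t in terms}
    residual = 1.0 - sum(fractions.values())

    # OLS coefficients and covariance for slope contrasts
    Xk = design.matrix
    beta, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ beta
    df_resid = len(y) - Xk.shape[1]
    sigma2 = float(resid @ resid) / max(df_resid, 1)
    XtX_inv = np.linalg.inv(Xk.T @ Xk)
    cov = sigma2 * XtX_inv

    n_t = len(ti_levels)
    contrast = {}
    for r in rs_levels:
        c = np.zeros(Xk.shape[1])
        for j, (name, term) in enumerate(zip(design.columns, design.term_of)):
            if term == "env":
                c[j] = 1.0
            elif term == "env:tissue":
                c[j] = 1.0 / n_t
            elif term == "env:rootstock" and name == f"env:rootstock[{r}]":
                c[j] = 1.0
            elif term == "env:tissue:rootstock" and name.endswith(f"rootstock[{r}]"):
                c[j] = 1.0 / n_t
        contrast[r] = c
    slopes = {r: float(contrast[r] @ beta) for r in rs_levels}
    C = np.array([contrast[r] for r in rs_levels])
    slope_cov = C @ cov @ C.T
    return GxEModelResult(
        gpc=gpc,
        epc=epc,
        fractions=fractions,
        residual=residual,
        slopes=slopes,
        slope_cov=slope_cov,
        df_resid=df_resid,
        rootstock_levels=list(rs_levels),
        aliased=aliased,
    )


def screen_effects(results, threshold: float = 0.05) -> list:
    """Flag (gPC, ePC, term) triples whose variance fraction strictly
    exceeds the threshold."""
    flagged = []
    for res in results:
        for term, frac in res.fractions.items():
            if frac > threshold:
                flagged.append((res.gpc, res.epc, term))
    return flagged


def posthoc_slopes(result: GxEModelResult, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-adjusted pairwise contrasts of per-rootstock environment slopes.

    The studentized-range statistic q = |diff| * sqrt(2) / SE(diff) is
    referred to the studentized-range distribution with k = number of
    rootstock levels on the model's residual df. For k = 2 this reduces
    exactly to the two-sided t-test.
    """
    levels = result.rootstock_levels
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two rootstock levels for contrasts")
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = result.slopes[levels[i]] - result.slopes[levels[j]]
        var = (
            result.slope_cov[i, i]
            + result.slope_cov[j, j]
            - 2.0 * result.slope_cov[i, j]
        )
        se = float(np.sqrt(max(var, 0.0)))
        if se == 0.0:
            p = 1.0 if diff == 0 else 0.0
            q = np.inf if diff != 0 else 0.0
        else:
            q = abs(diff) * np.sqrt(2.0) / se
            p = float(scipy.stats.studentized_range.sf(q, k, result.df_resid))
        rows.append({
            "pair": f"{levels[i]} - {levels[j]}",
            "slope_diff": float(diff),
            "se": se,
            "q": float(q),
            "p_tukey": p,
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows)


@dataclass
class LoaderSets:
    """Heavy-loading gene sets for one component: loadings beyond
    mean +/- z sd, split by sign."""

    component: int
    positive: list
    negative: list
    z: float
    mean_loading: float
    sd_loading: float


def heavy_loaders(result: PCAResult, component: int, z: float = 1.96) -> LoaderSets:
    """Genes whose loading on ``component`` is more than z sd from the mean
    loading (positive and negative sets; empty when sd is zero)."""
    if not 0 <= component < result.n_components:
        raise ValueError(f"component {component} out of range")
    if z <= 0:
        raise ValueError("z must be positive")
    load = result.loadings[:, component]
    mean, sd = float(load.mean()), float(load.std(ddof=0))
    if sd < 1e-15:
        pos, neg = [], []
    else:
        pos = [g for g, v in zip(result.col_ids, load) if v > mean + z * sd]
        neg = [g for g, v in zip(result.col_ids, load) if v < mean - z * sd]
    return LoaderSets(component, pos, neg, z, mean, sd)
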