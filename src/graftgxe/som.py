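"""Self-organizing map clustering of scaled expression profiles.

Selected genes' z-scored VST profiles are clustered on a hexagonally
connected grid (9 x 9 by default). Training is classic online competitive
learning: genes are presented in seeded random order for a fixed number of
epochs; each presentation moves every node weight toward the input with a
Gaussian neighborhood kernel in grid-plane distance, while the learning rate
decays linearly (0.05 -> 0.01 by default) and the neighborhood radius
shrinks linearly from two thirds of the grid diameter to 0.5 over the run.

Each node is a candidate cluster: genes map to their best-matching unit
(BMU), the core half of each node (distance to the node weight at or below
the node median) is retained, and nodes with enough retained genes are
tested for a rootstock effect on the per-sample cluster mean with a
node-count Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .io import SampleTable
from .normalize import ExpressionMatrix

__all__ = [
    "HexGrid",
    "TrainingSchedule",
    "Codebook",
    "ClusterTable",
    "init_codebook",
    "train_som",
    "assign_bmu",
    "retain_core_genes",
    "cluster_summary",
    "cluster_rootstock_test",
    "quantization_error",
]


@dataclass(frozen=True)
class HexGrid:
    """Hexagonal node lattice in offset-row layout with unit nearest-neighbor
    spacing: node (r, c) sits at x = c + (r mod 2)/2, y = r sqrt(3)/2."""

    n_rows: int = 9
    n_cols: int = 9

    @property
    def n_nodes(self) -> int:
        return self.n_rows * self.n_cols

    def coordinates(self) -> np.ndarray:
        r, c = np.divmod(np.arange(self.n_nodes), self.n_cols)
        x = c + 0.5 * (r % 2)
        y = r * (np.sqrt(3.0) / 2.0)
        return np.column_stack([x, y]).astype(float)

    def pairwise_sq_distances(self) -> np.ndarray:
        xy = self.coordinates()
        diff = xy[:, None, :] - xy[None, :, :]
        return (diff**2).sum(-1)

    @property
    def diameter(self) -> float:
        d2 = self.pairwise_sq_distances()
        return float(np.sqrt(d2.max()))


@dataclass(frozen=True)
class TrainingSchedule:
    """Online-training schedule: epochs of full-data presentation with the
    learning rate and neighborhood radius interpolated linearly over the
    total update count. ``radius_start=None`` means 2/3 of the grid
    diameter."""

    epochs: int = 500
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    radius_start: float | None = None
    radius_end: float = 0.5
    neighborhood: str = "gaussian"  # or "bubble"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_start < self.alpha_end or self.alpha_end < 0:
            raise ValueError("learning rate must be positive and non-increasing")
        if self.radius_start is not None and self.radius_start < self.radius_end:
            raise ValueError("radius must be non-increasing")
        if self.neighborhood not in ("gaussian", "bubble"):
            raise ValueError("neighborhood must be 'gaussian' or 'bubble'")


@dataclass
class Codebook:
    """Node x feature weight matrix plus grid and schedule provenance."""

    weights: np.ndarray
    grid: HexGrid
    schedule: TrainingSchedule | None = None
    quantization_error: float = float("nan")

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if self.weights.shape[0] != self.grid.n_nodes:
            raise ValueError("codebook rows must equal grid node count")
        if not np.isfinite(self.weights).all():
            raise ValueError("codebook weights must be finite")


@dataclass
class ClusterTable:
    """Per-gene BMU assignments and per-node cluster summaries."""

    assignments: pd.DataFrame  # gene, node, distance, retained
    nodes: pd.DataFrame = field(default_factory=pd.DataFrame)
    # nodes columns: node, size, retained_size, tested, p_value, significant


def init_codebook(
    data: np.ndarray, grid: HexGrid, seed: int = 0, method: str = "sample"
) -> Codebook:
    """Initialize node weights from the data.

    ``sample``: a seeded random draw of distinct gene profiles (default).
    ``pca``: a regular lattice spanning the first two principal components.
    """
    data = np.asarray(data, float)
    n, p = data.shape
    if n < grid.n_nodes:
        raise ValueError(
            f"{n} genes < {grid.n_nodes} nodes; use a smaller grid"
        )
    if method == "sample":
        rng = np.random.default_rng(seed)
        rows = rng.choice(n, size=grid.n_nodes, replace=False)
        W = data[rows].copy()
    elif method == "pca":
        centered = data - data.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        sd = s[:2] / np.sqrt(max(n - 1, 1))
        span_r = np.linspace(-2, 2, grid.n_rows)
        span_c = np.linspace(-2, 2, grid.n_cols)
        W = np.empty((grid.n_nodes, p))
        for k in range(grid.n_nodes):
            r, c = divmod(k, grid.n_cols)
            W[k] = data.mean(axis=0) + span_c[c] * sd[0] * vt[0] + span_r[r] * sd[min(1, len(sd) - 1)] * vt[min(1, len(s) - 1)]
    else:
        raise ValueError("method must be 'sample' or 'pca'")
    cb = Codebook(W, grid)
    cb.quantization_error = quantization_error(data, cb)
    return cb


def quantization_error(data: np.ndarray, codebook: Codebook) -> float:
    """Mean Euclidean distance from inputs to their BMU weights."""
    d2 = _sq_dist(np.asarray(data, float), codebook.weights)
    return float(np.sqrt(d2.min(axis=1)).mean())


def _sq_dist(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    return ((X[:, None, :] - W[None, :, :]) ** 2).sum(-1)


def train_som(
    data: np.ndarray, codebook: Codebook, schedule: TrainingSchedule
) -> Codebook:
    """Train the codebook with online updates.

    Per epoch, genes are presented in a seeded random order; for each gene
    the BMU is the Euclidean-nearest node (ties -> lowest node index) and
    every node k moves by alpha * h(d_grid(BMU, k)) * (x - w_k), with h
    Gaussian (exp(-d^2 / 2 r^2)) or bubble (d <= r). alpha and r are
    interpolated linearly over the total number of updates.
    """
    X = np.asarray(data, float)
    if not np.isfinite(X).all():
        bad = int(np.argwhere(~np.isfinite(X).all(axis=1))[0][0])
        raise ValueError(f"non-finite value in input row {bad}")
    W = codebook.weights.copy()
    grid = codebook.grid
    gd2 = grid.pairwise_sq_distances()
    r_start = schedule.radius_start
    if r_start is None:
        r_start = (2.0 / 3.0) * grid.diameter
    rng = np.random.default_rng(schedule.seed)
    n = X.shape[0]
    total = max(schedule.epochs * n - 1, 1)
    t = 0
    for _ in range(schedule.epochs):
        order = rng.permutation(n)
        for i in order:
            frac = t / total
            alpha = schedule.alpha_start + frac * (schedule.alpha_end - schedule.alpha_start)
            radius = r_start + frac * (schedule.radius_end - r_start)
            t += 1
            if alpha == 0.0:
                continue
            x = X[i]
            bmu = int(np.argmin(((W - x) ** 2).sum(axis=1)))
            if schedule.neighborhood == "gaussian":
                h = np.exp(-gd2[bmu] / (2.0 * radius**2))
            else:
                h = (gd2[bmu] <= radius**2).astype(float)
            W += (alpha * h)[:, None] * (x - W)
    out = Codebook(W, grid, schedule)
    out.quantization_error = quantization_error(X, out)
    return out


def assign_bmu(
    data: np.ndarray, codebook: Codebook, gene_ids=None
) -> ClusterTable:
    """Map each gene to its nearest node (ties -> lowest node index)."""
    X = np.asarray(data, float)
    d2 = _sq_dist(X, codebook.weights)
    nodes = d2.argmin(axis=1)
    dist = np.sqrt(d2[np.arange(len(X)), nodes])
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(len(X))]
    df = pd.DataFrame({
        "gene": list(gene_ids),
        "node": nodes.astype(int),
        "distance": dist,
        "retained": True,
    })
    return ClusterTable(df)


def retain_core_genes(table: ClusterTable, q: float = 0.5) -> ClusterTable:
    """Keep, within each node, genes with distance at or below the node's
    q-quantile of distances (inclusive; singletons are kept)."""
    df = table.assignments.copy()
    med = df.groupby("node")["distance"].transform(lambda d: d.quantile(q))
    df["retained"] = df["distance"] <= med
    return ClusterTable(df, table.nodes)


def cluster_summary(
    scaled_expr: ExpressionMatrix,
    table: ClusterTable,
    meta: SampleTable,
    group_factors=("rootstock", "year"),
) -> pd.DataFrame:
    """Mean scaled expression per cluster x factor-level combination over
    retained genes (long format)."""
    df = scaled_expr.to_frame()
    md = meta.indexed().loc[list(scaled_expr.samples)]
    retained = table.assignments[table.assignments["retained"]]
    rows = []
    for node, group in retained.groupby("node"):
        genes = [g for g in group["gene"] if g in df.index]
        if not genes:
            continue
        sub = df.loc[genes]
        for levels, samples in md.groupby(list(group_factors), sort=True):
            if not isinstance(levels, tuple):
                levels = (levels,)
            vals = sub[samples.index].to_numpy()
            rows.append({
                "node": int(node),
                **dict(zip(group_factors, levels)),
                "mean_scaled": float(vals.mean()),
                "n_genes": len(genes),
                "n_samples": len(samples),
            })
    return pd.DataFrame(rows)


def cluster_rootstock_test(
    scaled_expr: ExpressionMatrix,
    table: ClusterTable,
    meta: SampleTable,
    alpha: float = 0.05,
    min_size: int = 16,
    factor: str = "rootstock",
) -> ClusterTable:
    """One-way rootstock F-test per sufficiently large cluster.

    The per-sample cluster mean of retained genes is the response; a cluster
    is significant iff p < alpha / n_nodes (Bonferroni over the node count).
    Clusters with fewer retained genes than ``min_size`` are marked untested.
    """
    df = scaled_expr.to_frame()
    md = meta.indexed().loc[list(scaled_expr.samples)]
    groups = md[factor].to_numpy()
    n_nodes = int(table.assignments["node"].max()) + 1 if len(table.assignments) else 0
    assigned = table.assignments
    rows = []
    for node in range(n_nodes):
        sub = assigned[assigned["node"] == node]
        retained = sub[sub["retained"]]
        genes = [g for g in retained["gene"] if g in df.index]
        tested, p = False, np.nan
        if len(genes) >= min_size:
            response = df.loc[genes].to_numpy().mean(axis=0)
            samples = [response[groups == g] for g in pd.unique(groups)]
            if len(samples) > 1:
                tested = True
                p = float(scipy.stats.f_oneway(*samples).pvalue)
        rows.append({
            "node": node,
            "size": int(len(sub)),
            "retained_size": int(len(genes)),
            "tested": tested,
            "p_value": p,
            "significant": bool(tested and p < alpha / max(n_nodes, 1)),
        })
    return ClusterTable(assigned, pd.DataFrame(rows))
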