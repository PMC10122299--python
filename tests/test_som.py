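import numpy as np
import pandas as pd
import pytest

from graftgxe.io import FactorDomains, SampleTable
from graftgxe.normalize import ExpressionMatrix
from graftgxe.som import (
    Codebook,
    HexGrid,
    TrainingSchedule,
    assign_bmu,
    cluster_rootstock_test,
    cluster_summary,
    init_codebook,
    quantization_error,
    retain_core_genes,
    train_som,
)


def group_meta(rootstocks, n_per=10) -> SampleTable:
    rows = []
    for r in rootstocks:
        for i in range(n_per):
            rows.append({
                "sample": f"{r}_{i}",
                "tissue": "leaf",
                "year": 2017,
                "phenology": "anthesis",
                "rootstock": r,
                "irrigation": "none",
                "block": f"b{i}",
                "datetime": "2017-06-01 10:00",
            })
    return SampleTable(pd.DataFrame(rows))


class TestHexGrid:
    def test_default_grid_81_nodes(self):
        grid = HexGrid()
        assert grid.n_nodes == 81

    def test_unit_nearest_neighbor_distance(self):
        grid = HexGrid(4, 5)
        d2 = grid.pairwise_sq_distances()
        off_diag = d2[~np.eye(grid.n_nodes, dtype=bool)]
        assert np.min(off_diag) == pytest.approx(1.0)

    def test_row_offset_layout(self):
        xy = HexGrid(2, 2).coordinates()
        # second row shifted by half a spacing
        assert xy[2, 0] == pytest.approx(0.5)
        assert xy[2, 1] == pytest.approx(np.sqrt(3) / 2)


class TestInitCodebook:
    def test_deterministic(self, rng):
        data = rng.normal(size=(50, 8))
        grid = HexGrid(3, 3)
        a = init_codebook(data, grid, seed=4)
        b = init_codebook(data, grid, seed=4)
        assert np.array_equal(a.weights, b.weights)

    def test_sample_init_rows_from_data(self, rng):
        data = rng.normal(size=(40, 6))
        cb = init_codebook(data, HexGrid(3, 3), seed=0)
        for w in cb.weights:
            assert any(np.allclose(w, x) for x in data)

    def test_pca_init_spans_top_plane(self, rng):
        basis = rng.normal(size=(2, 10))
        data = rng.normal(size=(60, 2)) @ basis  # exactly rank 2
        cb = init_codebook(data, HexGrid(3, 3), seed=0, method="pca")
        centered = cb.weights - data.mean(axis=0)
        # residual outside the top-2 PC plane is numerically zero
        _, _, vt = np.linalg.svd(data - data.mean(axis=0), full_matrices=False)
        resid = centered - centered @ vt[:2].T @ vt[:2]
        assert np.abs(resid).max() < 1e-8

    def test_too_few_genes(self, rng):
        with pytest.raises(ValueError, match="smaller grid"):
            init_codebook(rng.normal(size=(5, 3)), HexGrid(3, 3), seed=0)


class TestTrainSOM:
    def test_zero_learning_rate_leaves_codebook(self, rng):
        data = rng.normal(size=(30, 5))
        cb = init_codebook(data, HexGrid(3, 3), seed=1)
        sched = TrainingSchedule(epochs=3, alpha_start=0.0, alpha_end=0.0, seed=1)
        out = train_som(data, cb, sched)
        assert np.array_equal(out.weights, cb.weights)

    def test_single_node_stays_in_convex_box(self, rng):
        data = rng.normal(size=(20, 4))
        cb = init_codebook(data, HexGrid(1, 1), seed=2)
        sched = TrainingSchedule(epochs=10, radius_start=0.5, radius_end=0.5, seed=2)
        out = train_som(data, cb, sched)
        lo = np.minimum(data.min(axis=0), cb.weights[0])
        hi = np.maximum(data.max(axis=0), cb.weights[0])
        assert np.all(out.weights[0] >= lo - 1e-12)
        assert np.all(out.weights[0] <= hi + 1e-12)

    def test_training_reduces_quantization_error(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            centers = r.normal(scale=3, size=(4, 6))
            data = np.vstack([c + r.normal(size=(25, 6)) for c in centers])
            cb = init_codebook(data, HexGrid(3, 3), seed=seed)
            out = train_som(data, cb, TrainingSchedule(epochs=20, seed=seed))
            assert out.quantization_error <= cb.quantization_error

    def test_nan_input_rejected(self, rng):
        data = rng.normal(size=(20, 4))
        data[3, 1] = np.nan
        cb = init_codebook(np.nan_to_num(data), HexGrid(2, 2), seed=0)
        with pytest.raises(ValueError, match="row 3"):
            train_som(data, cb, TrainingSchedule(epochs=1, seed=0))

    def test_deterministic(self, rng):
        data = rng.normal(size=(30, 5))
        cb = init_codebook(data, HexGrid(3, 3), seed=7)
        sched = TrainingSchedule(epochs=5, seed=7)
        a = train_som(data, cb, sched)
        b = train_som(data, cb, sched)
        assert np.array_equal(a.weights, b.weights)


class TestAssignBMU:
    def test_toy_assignment(self):
        cb = Codebook(np.array([[0.0, 0.0], [10.0, 10.0]]), HexGrid(1, 2))
        table = assign_bmu(np.array([[1.0, 1.0]]), cb)
        assert table.assignments.loc[0, "node"] == 0
        assert table.assignments.loc[0, "distance"] == pytest.approx(np.sqrt(2))

    def test_exact_match_distance_zero(self):
        W = np.array([[1.0, 2.0], [3.0, 4.0]])
        cb = Codebook(W, HexGrid(1, 2))
        table = assign_bmu(W[[1]], cb)
        assert table.assignments.loc[0, "node"] == 1
        assert table.assignments.loc[0, "distance"] == 0.0

    def test_brute_force_oracle(self, rng):
        data = rng.normal(size=(1000, 7))
        cb = Codebook(rng.normal(size=(12, 7)), HexGrid(3, 4))
        table = assign_bmu(data, cb)
        for i in rng.choice(1000, 50, replace=False):
            d = [np.linalg.norm(data[i] - w) for w in cb.weights]
            assert table.assignments.loc[i, "node"] == int(np.argmin(d))


class TestRetainCoreGenes:
    def test_median_rule_inclusive(self):
        df = pd.DataFrame({
            "gene": ["a", "b", "c", "d"],
            "node": 0,
            "distance": [1.0, 2.0, 3.0, 4.0],
            "retained": True,
        })
        from graftgxe.som import ClusterTable

        out = retain_core_genes(ClusterTable(df))
        kept = out.assignments.loc[out.assignments["retained"], "gene"].tolist()
        assert kept == ["a", "b"]  # median 2.5, inclusive <=

    def test_all_equal_all_retained(self):
        from graftgxe.som import ClusterTable

        df = pd.DataFrame({"gene": list("abc"), "node": 0,
                           "distance": [1.0, 1.0, 1.0], "retained": True})
        out = retain_core_genes(ClusterTable(df))
        assert out.assignments["retained"].all()

    def test_singleton_node_kept(self):
        from graftgxe.som import ClusterTable

        df = pd.DataFrame({"gene": ["a"], "node": 3, "distance": [9.9],
                           "retained": True})
        out = retain_core_genes(ClusterTable(df))
        assert out.assignments["retained"].all()


class TestClusterSummary:
    def _scaled(self, values, meta):
        return ExpressionMatrix(
            [f"g{i}" for i in range(values.shape[0])], meta.samples, values
        )

    def test_single_gene_cluster_equals_group_means(self, rng):
        meta = group_meta(["ungrafted", "1103P"], n_per=5)
        values = rng.normal(size=(1, 10))
        expr = self._scaled(values, meta)
        table = assign_bmu(values, Codebook(values.copy(), HexGrid(1, 1)),
                           gene_ids=["g0"])
        summary = cluster_summary(expr, table, meta, group_factors=("rootstock",))
        for _, row in summary.iterrows():
            mask = (meta.data["rootstock"] == row["rootstock"]).to_numpy()
            assert row["mean_scaled"] == pytest.approx(values[0, mask].mean())

    def test_gene_order_invariance(self, rng):
        meta = group_meta(["ungrafted", "1103P"], n_per=5)
        values = rng.normal(size=(6, 10))
        expr = self._scaled(values, meta)
        cb = Codebook(rng.normal(size=(4, 10)), HexGrid(2, 2))
        t1 = assign_bmu(values, cb, gene_ids=expr.genes)
        s1 = cluster_summary(expr, t1, meta, ("rootstock",))
        perm = [5, 3, 1, 0, 2, 4]
        expr2 = ExpressionMatrix([expr.genes[i] for i in perm], meta.samples,
                                 values[perm])
        t2 = assign_bmu(values[perm], cb, gene_ids=expr2.genes)
        s2 = cluster_summary(expr2, t2, meta, ("rootstock",))
        merged = s1.merge(s2, on=["node", "rootstock"], suffixes=("_a", "_b"))
        assert np.allclose(merged["mean_scaled_a"], merged["mean_scaled_b"])


class TestClusterRootstockTest:
    def _setup(self, rng, effect=0.0, n_genes=20):
        meta = group_meta(["ungrafted", "1103P", "3309C", "SO4"], n_per=12)
        shift = np.array([0.0, effect, effect, effect])
        groups = np.repeat(np.arange(4), 12)
        values = shift[groups][None, :] + rng.normal(size=(n_genes, 48))
        expr = ExpressionMatrix([f"g{i}" for i in range(n_genes)],
                                meta.samples, values)
        cb = Codebook(np.zeros((1, 48)), HexGrid(1, 1))
        table = assign_bmu(values, cb, gene_ids=expr.genes)
        return expr, table, meta

    def test_null_cluster_not_significant(self, rng):
        expr, table, meta = self._setup(rng, effect=0.0)
        out = cluster_rootstock_test(expr, table, meta, min_size=16)
        assert out.nodes.loc[0, "tested"]
        assert not out.nodes.loc[0, "significant"]

    def test_planted_pattern_detected(self, rng):
        expr, table, meta = self._setup(rng, effect=1.0)
        out = cluster_rootstock_test(expr, table, meta, min_size=16)
        assert out.nodes.loc[0, "significant"]

    def test_small_cluster_untested(self, rng):
        expr, table, meta = self._setup(rng)
        out = cluster_rootstock_test(expr, table, meta, min_size=10**6)
        assert not out.nodes["tested"].any()

    def test_bonferroni_uses_node_count(self, rng):
        expr, table, meta = self._setup(rng, effect=0.3)
        out = cluster_rootstock_test(expr, table, meta, alpha=0.05, min_size=16)
        p = out.nodes.loc[0, "p_value"]
        expected = bool(p < 0.05 / 1)  # single-node grid
        assert out.nodes.loc[0, "significant"] == expected
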