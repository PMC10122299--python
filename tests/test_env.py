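import numpy as np
import pandas as pd
import pytest
import scipy.stats

from graftgxe.env import (
    attach_env,
    build_env_table,
    composite_stats,
    fit_gpc_model,
    heavy_loaders,
    pca,
    posthoc_slopes,
    screen_effects,
    select_components,
)
from graftgxe.io import HourlyWeather, SampleTable

ALL_FEATURES = [
    "temperature", "precipitation", "wind_speed", "relative_humidity",
    "solar_radiance", "radiation_density", "pressure", "dew_point",
    "ref_evapotranspiration", "clear_sky_radiation",
]


def toy_weather(n_hours=48, start="2018-06-01", temp=None, precip=None):
    ts = pd.date_range(start, periods=n_hours, freq="h")
    df = pd.DataFrame({"timestamp": ts})
    for f in ALL_FEATURES:
        df[f] = 1.0
    if temp is not None:
        df.loc[: len(temp) - 1, "temperature"] = temp
    if precip is not None:
        df.loc[: len(precip) - 1, "precipitation"] = precip
    return HourlyWeather(df)


def meta_with_dates(dates) -> SampleTable:
    rows = []
    for i, d in enumerate(dates):
        rows.append({
            "sample": f"s{i}", "tissue": "leaf", "year": pd.Timestamp(d).year,
            "phenology": "anthesis", "rootstock": "ungrafted",
            "irrigation": "none", "block": "b1", "datetime": d,
        })
    return SampleTable(pd.DataFrame(rows))


class TestCompositeStats:
    def test_hand_arithmetic_window(self):
        # hourly stamps at 00..03; the 4 h window ending at 03:00 covers them
        w = toy_weather(temp=[10.0, 12.0, 14.0, 16.0])
        row = composite_stats(w, "2018-06-01 03:00", window_h=4)
        assert row["temperature_min"] == 10
        assert row["temperature_max"] == 16
        assert row["temperature_change"] == 6
        assert row["temperature_mean"] == 13

    def test_constant_feature_zero_change(self):
        w = toy_weather()
        row = composite_stats(w, "2018-06-02 00:00")
        assert row["pressure_change"] == 0.0

    def test_precipitation_summed_not_averaged(self):
        w = toy_weather(precip=[0.0, 1.0, 0.0, 2.0])
        row = composite_stats(w, "2018-06-01 03:00", window_h=4)
        assert row["precipitation_sum"] == 3.0
        assert "precipitation_mean" not in row

    def test_empty_window_errors(self):
        w = toy_weather()
        with pytest.raises(ValueError, match="no weather data"):
            composite_stats(w, "2020-01-01 00:00")

    def test_gap_fraction_enforced(self):
        df = toy_weather().data
        w = HourlyWeather(df.iloc[:10])  # 10 of 24 hours
        with pytest.raises(ValueError, match="missing fraction"):
            composite_stats(w, "2018-06-02 00:00", window_h=24)


class TestBuildEnvTable:
    def test_one_row_per_sampling_date(self):
        w = toy_weather(n_hours=24 * 12, start="2018-06-01")
        dates = [f"2018-06-{d:02d} 11:00" for d in range(2, 11)]
        table = build_env_table(w, meta_with_dates(dates))
        assert len(table.data) == 9

    def test_duplicate_dates_collapse(self):
        w = toy_weather(n_hours=24 * 4)
        meta = meta_with_dates(["2018-06-02 10:00", "2018-06-02 13:00"])
        assert len(build_env_table(w, meta).data) == 1

    def test_all_days_mode(self):
        w = toy_weather(n_hours=24 * 5)
        table = build_env_table(w, all_days=True)
        assert len(table.data) == 5
        # 8 averaged features x 4 stats + 2 summed
        assert table.data.shape[1] == 34


class TestPCA:
    def test_single_axis_data(self, rng):
        t = rng.normal(size=20)
        X = np.outer(t, [1.0, 2.0, -1.0])
        res = pca(X, standardize=False)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_orthonormal_loadings(self, rng):
        res = pca(rng.normal(size=(20, 6)), standardize=True)
        gram = res.loadings.T @ res.loadings
        assert np.allclose(gram, np.eye(res.n_components), atol=1e-8)

    def test_row_duplication_invariance(self, rng):
        X = rng.normal(size=(15, 4))
        r1 = pca(X, standardize=True)
        r2 = pca(np.vstack([X, X]), standardize=True)
        assert np.allclose(r1.loadings, r2.loadings, atol=1e-8)
        assert np.allclose(r1.variance_fraction, r2.variance_fraction, atol=1e-8)

    def test_zero_variance_column_dropped(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 7.0
        res = pca(pd.DataFrame(X, columns=["a", "b", "c"]), standardize=True)
        assert res.dropped_columns == ["b"]

    def test_reconstruction(self, rng):
        X = rng.normal(size=(12, 5))
        res = pca(X, standardize=True)
        Z = (X - X.mean(0)) / X.std(0)
        assert np.allclose(res.scores @ res.loadings.T, Z, atol=1e-8)

    def test_deterministic_sign(self, rng):
        res = pca(rng.normal(size=(30, 5)), standardize=True)
        for k in range(res.n_components):
            j = np.argmax(np.abs(res.loadings[:, k]))
            assert res.loadings[j, k] > 0


class TestSelectComponents:
    @pytest.mark.parametrize("fracs,cum,expected", [
        ((0.5, 0.3, 0.15, 0.05), 0.8, 2),
        ((0.5, 0.3, 0.15, 0.05), 1.0, 4),
        ((0.81, 0.1, 0.09), 0.8, 1),
    ])
    def test_prefix_selection(self, fracs, cum, expected):
        res = pca(np.eye(5), standardize=False)
        res.variance_fraction = np.array(fracs)
        res.loadings = res.loadings[:, : len(fracs)]
        assert len(select_components(res, cum)) == expected


class TestAttachEnv:
    def _setup(self):
        w = toy_weather(n_hours=24 * 12)
        rng = np.random.default_rng(0)
        df = w.data
        df["temperature"] = rng.normal(20, 3, len(df))
        w = HourlyWeather(df)
        table = build_env_table(w, all_days=True)
        return w, table, pca(table, standardize=True)

    def test_same_day_identical_scores(self):
        _, table, epca = self._setup()
        meta = meta_with_dates(["2018-06-03 10:00", "2018-06-03 14:00"])
        out = attach_env(meta, table, epca, components=[0])
        assert out.loc[0, "ePC1"] == out.loc[1, "ePC1"]

    def test_unmatched_date_errors(self):
        _, table, epca = self._setup()
        meta = meta_with_dates(["2021-01-01 10:00"])
        with pytest.raises(ValueError, match="s0"):
            attach_env(meta, table, epca)

    def test_distinct_days_bound_scores(self):
        _, table, epca = self._setup()
        dates = [f"2018-06-{d:02d} 11:00" for d in range(2, 11)] * 3
        out = attach_env(meta_with_dates(dates), table, epca, components=[0])
        assert out["ePC1"].nunique() <= 9


def gxe_meta(n_per=12, rootstocks=("ungrafted", "1103P", "3309C", "SO4")):
    rows = []
    i = 0
    for r in rootstocks:
        for t in ("leaf", "reproductive"):
            for k in range(n_per):
                rows.append({
                    "sample": f"s{i}", "tissue": t, "year": 2017,
                    "phenology": "anthesis", "rootstock": r,
                    "irrigation": "none", "block": f"b{k}",
                    "datetime": "2017-06-01 10:00",
                })
                i += 1
    return SampleTable(pd.DataFrame(rows))


class TestGxEModel:
    def test_independent_response_all_noise(self, rng):
        meta = gxe_meta()
        n = len(meta)
        res = fit_gpc_model(rng.normal(size=n), rng.normal(size=n), meta)
        assert res.residual > 0.8
        assert all(f < 0.1 for f in res.fractions.values())

    def test_pure_environment_signal(self, rng):
        meta = gxe_meta()
        e = rng.normal(size=len(meta))
        y = 2.0 * e + rng.normal(0, 0.01, len(meta))
        res = fit_gpc_model(y, e, meta)
        assert res.fractions["env"] > 0.99

    def test_planted_cross_pattern_flagged_and_contrasted(self, rng):
        meta = gxe_meta()
        slopes = {"ungrafted": 1.0, "3309C": 1.0, "1103P": -1.0, "SO4": -1.0}
        e = rng.normal(size=len(meta))
        s = meta.data["rootstock"].map(slopes).to_numpy()
        y = s * e + rng.normal(0, 0.5, len(meta))
        res = fit_gpc_model(y, e, meta)
        flagged = screen_effects([res], 0.05)
        assert (0, 0, "env:rootstock") in flagged
        ph = posthoc_slopes(res).set_index("pair")
        cross = ["1103P - ungrafted", "SO4 - ungrafted",
                 "1103P - 3309C", "3309C - SO4"]
        within = ["3309C - ungrafted", "1103P - SO4"]
        assert ph.loc[cross, "significant"].all()
        assert not ph.loc[within, "significant"].any()

    def test_slope_estimates_match_planted(self, rng):
        meta = gxe_meta(n_per=30)
        slopes = {"ungrafted": 1.0, "3309C": 1.0, "1103P": -1.0, "SO4": -1.0}
        e = rng.normal(size=len(meta))
        y = meta.data["rootstock"].map(slopes).to_numpy() * e + rng.normal(
            0, 0.3, len(meta))
        res = fit_gpc_model(y, e, meta)
        for r, true in slopes.items():
            assert res.slopes[r] == pytest.approx(true, abs=0.15)

    def test_sample_order_invariance(self, rng):
        meta = gxe_meta()
        n = len(meta)
        e = rng.normal(size=n)
        y = rng.normal(size=n)
        res1 = fit_gpc_model(y, e, meta)
        perm = rng.permutation(n)
        meta2 = SampleTable(meta.data.iloc[perm].reset_index(drop=True))
        res2 = fit_gpc_model(y[perm], e[perm], meta2)
        for t in res1.fractions:
            assert res1.fractions[t] == pytest.approx(res2.fractions[t], abs=1e-9)


class TestScreenEffects:
    def test_boundary_is_strict(self):
        class R:
            gpc, epc = 0, 0
            fractions = {"env": 0.05, "rootstock": 0.051}

        flagged = screen_effects([R()], 0.05)
        assert (0, 0, "rootstock") in flagged
        assert (0, 0, "env") not in flagged

    def test_empty_results(self):
        assert screen_effects([], 0.05) == []


class TestPosthocSlopes:
    def test_two_groups_reduce_to_t_test(self, rng):
        meta = gxe_meta(rootstocks=("ungrafted", "1103P"))
        e = rng.normal(size=len(meta))
        y = 0.3 * e + rng.normal(0, 1, len(meta))
        res = fit_gpc_model(y, e, meta)
        ph = posthoc_slopes(res)
        assert len(ph) == 1
        diff = ph.loc[0, "slope_diff"]
        se = ph.loc[0, "se"]
        p_t = 2 * scipy.stats.t.sf(abs(diff) / se, res.df_resid)
        assert ph.loc[0, "p_tukey"] == pytest.approx(p_t, abs=1e-10)

    def test_null_type_one_error_controlled(self):
        """Equal planted slopes: any-pair rejection rate stays near the
        nominal family level."""
        hits = 0
        reps = 200
        meta = gxe_meta(n_per=6)
        for rep in range(reps):
            r = np.random.default_rng(rep)
            e = r.normal(size=len(meta))
            y = 0.5 * e + r.normal(0, 1, len(meta))
            ph = posthoc_slopes(fit_gpc_model(y, e, meta))
            hits += int(ph["significant"].any())
        assert hits / reps <= 0.06 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestHeavyLoaders:
    def test_normal_loadings_flag_about_five_percent(self, rng):
        X = rng.normal(size=(60, 4000))
        res = pca(X, standardize=False)
        ls = heavy_loaders(res, 0)
        frac = (len(ls.positive) + len(ls.negative)) / 4000
        assert frac == pytest.approx(0.05, abs=0.015)
        assert not set(ls.positive) & set(ls.negative)

    def test_constant_loadings_empty(self):
        res = pca(np.eye(4), standardize=False)
        res.loadings = np.full((4, 1), 0.5)
        res.col_ids = list("abcd")
        ls = heavy_loaders(res, 0)
        assert ls.positive == [] and ls.negative == []

    def test_single_extreme_loader(self, rng):
        res = pca(rng.normal(size=(10, 5)), standardize=False)
        load = np.zeros(5)
        load[2] = 10.0
        res.loadings = load[:, None]
        res.col_ids = list("abcde")
        ls = heavy_loaders(res, 0)
        assert ls.positive == ["c"] and ls.negative == []
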