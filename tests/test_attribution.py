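"""Correlation summaries, stratified sampling and forest importances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vegdyn import attribution
from vegdyn.containers import AnnualStack, DriverStack, RasterGrid


def annual(values):
    values = np.asarray(values, dtype=float)
    grid = RasterGrid(n_rows=values.shape[1], n_cols=values.shape[2])
    return AnnualStack(grid, list(range(2000, 2000 + len(values))), values)


class TestPixelwisePearson:
    def test_identical_series_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, (23, 3, 3))
        r, p = attribution.pixelwise_pearson(annual(vals), annual(vals.copy()))
        np.testing.assert_allclose(r, 1.0, atol=1e-12)
        assert np.all(p < 1e-12)

    def test_negated_series_correlate_at_minus_one(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, (23, 2, 2))
        r, _ = attribution.pixelwise_pearson(annual(vals), annual(-vals))
        np.testing.assert_allclose(r, -1.0, atol=1e-12)

    def test_seeded_gaussian_pair_matches_the_textbook_formula(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (23, 4, 4))
        y = 0.4 * x + rng.normal(0, 1, (23, 4, 4))
        r, p = attribution.pixelwise_pearson(annual(y), annual(x))
        n = 23
        for i in range(4):
            for j in range(4):
                xi, yi = x[:, i, j], y[:, i, j]
                num = n * np.sum(xi * yi) - xi.sum() * yi.sum()
                den = np.sqrt((n * np.sum(xi**2) - xi.sum()**2)
                              * (n * np.sum(yi**2) - yi.sum()**2))
                r_o = num / den
                t_o = r_o * np.sqrt((n - 2) / (1 - r_o**2))
                p_o = 2 * stats.t.sf(abs(t_o), n - 2)
                assert r[i, j] == pytest.approx(r_o, abs=1e-12)
                assert p[i, j] == pytest.approx(p_o, abs=1e-12)

    def test_zero_variance_series_flag_as_nodata(self):
        x = np.broadcast_to(np.arange(23.0)[:, None, None], (23, 1, 1)).copy()
        const = np.full((23, 1, 1), 5.0)
        r, p = attribution.pixelwise_pearson(annual(const), annual(x))
        assert np.isnan(r[0, 0]) and np.isnan(p[0, 0])

    def test_mismatched_year_axes_are_rejected(self):
        with pytest.raises(ValueError, match="year axes"):
            attribution.pixelwise_pearson(
                annual(np.zeros((5, 1, 1))), annual(np.zeros((6, 1, 1)))
            )


class TestSummarizeCorrelations:
    def test_perfect_positive_field_is_fully_significant_and_positive(self):
        r = np.ones((10, 10))
        p = np.zeros((10, 10))
        out = attribution.summarize_correlations({("NDVI", "Pre"): (r, p)})
        row = out.iloc[0]
        assert row["percent_significant"] == 100.0
        assert row["percent_positive"] == 100.0
        assert row["percent_negative"] == 0.0

    def test_nothing_significant_leaves_sign_shares_undefined(self):
        r = np.full((5, 5), 0.1)
        p = np.full((5, 5), 0.9)
        row = attribution.summarize_correlations({("CV", "Pop"): (r, p)}).iloc[0]
        assert row["percent_significant"] == 0.0
        assert np.isnan(row["percent_positive"])

    def test_random_fields_match_a_counting_oracle_and_signs_sum_to_100(self):
        rng = np.random.default_rng(3)
        results = {}
        for var in ("Pre", "Temp", "Graz"):
            r = rng.uniform(-1, 1, (30, 30))
            p = rng.uniform(0, 1, (30, 30))
            r[rng.random((30, 30)) < 0.05] = np.nan
            p[np.isnan(r)] = np.nan
            results[("NDVI", var)] = (r, p)
        out = attribution.summarize_correlations(results, alpha=0.05)
        for _, row in out.iterrows():
            r, p = results[(row["response"], row["variable"])]
            valid = ~np.isnan(r)
            sig = valid & (p < 0.05)
            assert row["percent_significant"] == pytest.approx(100 * sig.sum() / valid.sum())
            assert row["percent_positive"] + row["percent_negative"] == pytest.approx(100.0, abs=0.1)


def make_sample_inputs(n_side=40, n_years=23, seed=0):
    rng = np.random.default_rng(seed)
    grid_shape = (n_side, n_side)
    classes = np.zeros(grid_shape, dtype=np.int16)
    classes[: n_side // 2] = 1          # a large "improving" stratum
    classes[n_side // 2: n_side // 2 + 2] = 4
    grassland = np.ones(grid_shape, dtype=np.int16)  # all steppe
    resp = annual(rng.uniform(0, 1, (n_years,) + grid_shape))
    cv = annual(rng.uniform(0, 1, (n_years,) + grid_shape))
    drivers = DriverStack(
        resp.grid, resp.years,
        {name: rng.normal(0, 1, (n_years,) + grid_shape)
         for name in ("Pre", "Temp", "RH", "SPEI", "Graz", "Pop")},
    )
    return classes, grassland, resp, cv, drivers


class TestExtractStrataSamples:
    def test_oversized_strata_are_capped_exactly_and_reproducibly(self):
        classes, grass, resp, cv, drivers = make_sample_inputs()
        # improving stratum: 20*40 pixels x 23 years = 18,400 observations
        a = attribution.extract_strata_samples(classes, grass, resp, cv, drivers,
                                               sample_cap=10000, seed=42)
        b = attribution.extract_strata_samples(classes, grass, resp, cv, drivers,
                                               sample_cap=10000, seed=42)
        counts = a.groupby("stratum").size()
        assert counts["steppe_improving"] == 10000
        assert counts["steppe_medium_degradation"] == 2 * 40 * 23  # under the cap: all kept
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_draw_different_subsamples(self):
        classes, grass, resp, cv, drivers = make_sample_inputs()
        a = attribution.extract_strata_samples(classes, grass, resp, cv, drivers,
                                               sample_cap=1000, seed=1)
        b = attribution.extract_strata_samples(classes, grass, resp, cv, drivers,
                                               sample_cap=1000, seed=2)
        assert not a.equals(b)

    def test_rows_with_missing_values_are_dropped_before_capping(self):
        classes, grass, resp, cv, drivers = make_sample_inputs(n_side=10)
        resp.values[:, 0, :] = np.nan  # first pixel row unusable
        out = attribution.extract_strata_samples(classes, grass, resp, cv, drivers,
                                                 sample_cap=10**6, seed=0)
        assert not out.isna().any().any()
        assert out["pixel_id"].min() >= 10  # the NaN row's pixels are gone

    def test_pixel_unit_averages_each_series(self):
        classes, grass, resp, cv, drivers = make_sample_inputs(n_side=8)
        out = attribution.extract_strata_samples(classes, grass, resp, cv, drivers,
                                                 sample_cap=10**6, seed=0, unit="pixel")
        pid = int(out["pixel_id"].iloc[0])
        i, j = divmod(pid, 8)
        assert out["response_ndvi"].iloc[0] == pytest.approx(resp.values[:, i, j].mean())


class TestFitImportance:
    @staticmethod
    def toy_samples(n=400, seed=0, signal="Temp", noise=0.1):
        rng = np.random.default_rng(seed)
        frame = {name: rng.normal(0, 1, n)
                 for name in ("Pre", "Temp", "RH", "SPEI", "Graz", "Pop")}
        df = pd.DataFrame(frame)
        if signal is None:
            df["response_ndvi"] = rng.normal(0, 1, n)
        else:
            df["response_ndvi"] = 2 * df[signal] + rng.normal(0, noise * 2, n)
        df["response_cv"] = rng.normal(0, 1, n)
        df["stratum"] = "steppe_improving"
        return df

    def test_dominant_driver_gets_the_largest_importance(self):
        wins = 0
        for seed in range(5):
            imp = attribution.fit_importance(
                self.toy_samples(seed=seed), "NDVI",
                tree_grid=(50, 100), cv_folds=3, seed=seed,
            ).iloc[0]
            vals = {v: imp[v] for v in ("Pre", "Temp", "RH", "SPEI", "Graz", "Pop")}
            wins += max(vals, key=vals.get) == "Temp"
            assert sum(vals.values()) == pytest.approx(1.0, abs=1e-6)
            assert imp["oob_r2"] > 0.5
        assert wins == 5

    def test_noise_response_has_no_explanatory_power(self):
        imp = attribution.fit_importance(
            self.toy_samples(seed=3, signal=None), "NDVI",
            tree_grid=(100,), cv_folds=3, seed=3,
        ).iloc[0]
        assert imp["oob_r2"] <= 0.1

    def test_small_and_constant_strata_are_skipped(self, caplog):
        df = self.toy_samples(n=60, seed=1)
        small = df.iloc[:20].copy()
        small["stratum"] = "meadow_regrowing"
        flat = df.iloc[20:].copy()
        flat["stratum"] = "meadow_improving"
        flat["response_ndvi"] = 0.5
        out = attribution.fit_importance(
            pd.concat([df, small, flat], ignore_index=True), "NDVI",
            tree_grid=(50,), cv_folds=3, seed=0, min_stratum_size=50,
        )
        assert set(out["stratum"]) == {"steppe_improving"}

    def test_permutation_cross_check_agrees_on_the_dominant_driver(self):
        df = self.toy_samples(seed=2)
        imp = attribution.fit_importance(df, "NDVI", tree_grid=(50,),
                                         cv_folds=3, seed=2)
        perm = attribution.permutation_check(df, imp, "NDVI", seed=2).iloc[0]
        vals = {v: perm[v] for v in ("Pre", "Temp", "RH", "SPEI", "Graz", "Pop")}
        assert max(vals, key=vals.get) == "Temp"
        assert sum(vals.values()) == pytest.approx(1.0, abs=1e-9)

    def test_missing_predictor_columns_are_rejected(self):
        df = self.toy_samples().drop(columns=["Graz"])
        with pytest.raises(ValueError, match="missing predictors"):
            attribution.fit_importance(df, "NDVI", tree_grid=(50,))


class TestAggregateContributions:
    def test_equal_importances_split_two_thirds_to_climate(self):
        row = {"response": "NDVI", "stratum": "s", "n_samples": 100, "n_trees": 50,
               "oob_r2": 0.5, **{v: 1 / 6 for v in ("Pre", "Temp", "RH", "SPEI", "Graz", "Pop")}}
        out = attribution.aggregate_contributions(pd.DataFrame([row]))
        first = out.iloc[0]
        assert first["climate_share_pct"] == pytest.approx(100 * 4 / 6)
        assert first["human_share_pct"] == pytest.approx(100 * 2 / 6)

    def test_single_factor_concentration_and_random_vectors(self):
        rng = np.random.default_rng(4)
        rows = []
        w = rng.dirichlet(np.ones(6), size=3)
        names = ("Pre", "Temp", "RH", "SPEI", "Graz", "Pop")
        for k in range(3):
            rows.append({"response": "CV", "stratum": f"s{k}", "n_samples": 1,
                         "n_trees": 1, "oob_r2": 0.0,
                         **dict(zip(names, w[k]))})
        rows.append({"response": "CV", "stratum": "temp_only", "n_samples": 1,
                     "n_trees": 1, "oob_r2": 0.0,
                     **{v: (1.0 if v == "Temp" else 0.0) for v in names}})
        out = attribution.aggregate_contributions(pd.DataFrame(rows))
        per = out[out.stratum != "average"].set_index("stratum")
        assert per.loc["temp_only", "climate_share_pct"] == pytest.approx(100.0)
        for k in range(3):
            assert per.loc[f"s{k}", "climate_share_pct"] == pytest.approx(100 * w[k][:4].sum())
            assert per.loc[f"s{k}", "climate_share_pct"] + per.loc[f"s{k}", "human_share_pct"] \
                == pytest.approx(100.0)
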