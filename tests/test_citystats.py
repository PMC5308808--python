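"""City summaries, typology, Moran's I, and the regression models."""

import numpy as np
import pandas as pd
import pytest

from greenview.citystats import (
    MODEL_PREDICTORS,
    check_covariate_correlations,
    classify_cities,
    fit_by_level,
    fit_location_models,
    morans_i,
    summarize_city,
)
from greenview.synthetic import PanelSpec, make_city_panel


class TestSummarizeCity:
    def test_closed_form(self):
        assert summarize_city([0.2, 0.4]) == pytest.approx((0.3, 0.1))

    def test_single_site(self):
        assert summarize_city([0.25]) == (0.25, 0.0)

    def test_constant_city_zero_sd(self):
        assert summarize_city([0.3] * 7)[1] == 0.0

    def test_empty_city_rejected(self):
        with pytest.raises(ValueError):
            summarize_city([])


class TestClassifyCities:
    def _frame(self, pairs):
        return pd.DataFrame(pairs, columns=["mean_gvi", "std_gvi"])

    def test_against_reference_pair(self):
        # reference fixed by including counterweight cities around known means
        df = self._frame([(0.30, 0.10), (0.252, 0.156)])
        # reference pair = (0.276, 0.128): first city High avg, Low std
        labels = classify_cities(df)
        assert labels[0] == "HighAvgLowStd"
        assert labels[1] == "LowAvgHighStd"

    def test_city_exactly_at_reference_is_low_low(self):
        df = self._frame([(0.2, 0.1), (0.4, 0.3), (0.3, 0.2)])
        # city 2 sits exactly at the mean pair (0.3, 0.2): ties go Low/Low
        assert classify_cities(df)[2] == "LowAvgLowStd"

    def test_identical_cities_share_label(self):
        df = self._frame([(0.3, 0.1), (0.3, 0.1)])
        labels = classify_cities(df)
        assert labels[0] == labels[1] == "LowAvgLowStd"

    def test_labels_partition_cities(self, rng):
        df = self._frame(list(zip(rng.uniform(0.1, 0.5, 40), rng.uniform(0.05, 0.3, 40))))
        labels = classify_cities(df)
        assert labels.notna().all() and len(labels) == 40
        assert set(labels) <= {
            "HighAvgLowStd", "LowAvgLowStd", "HighAvgHighStd", "LowAvgHighStd",
        }


class TestMoransI:
    @staticmethod
    def _grid_points(n=8):
        xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
        return np.column_stack([xs.ravel(), ys.ravel()])

    def test_smooth_gradient_positive_and_significant(self, rng):
        pts = self._grid_points()
        vals = pts[:, 1] + rng.normal(0, 0.5, len(pts))
        res = morans_i(pts, vals, permutations=999, seed=0)
        assert res.I > 0
        assert res.z_norm > 2
        assert res.p_sim < 0.05

    def test_permuted_values_mostly_null(self, rng):
        pts = self._grid_points()
        vals = pts[:, 1].copy()
        inside = 0
        trials = 30
        for _ in range(trials):
            res = morans_i(pts, rng.permutation(vals))
            inside += abs(res.z_norm) < 2
        assert inside >= 0.9 * trials

    def test_checkerboard_negative(self):
        pts = self._grid_points()
        vals = (pts[:, 0] + pts[:, 1]) % 2  # alternation on the lattice
        res = morans_i(pts, vals, weights_spec={"kind": "knn", "k": 4})
        assert res.I < res.expected_i

    def test_matches_brute_force_double_loop(self, rng):
        """Cross-check against a from-scratch O(n^2) Moran's I."""
        pts = rng.uniform(0, 10, (25, 2))
        vals = rng.normal(0, 1, 25)
        k = 6
        res = morans_i(pts, vals, weights_spec={"kind": "knn", "k": k})
        n = len(vals)
        w = np.zeros((n, n))
        for i in range(n):
            d = np.hypot(*(pts - pts[i]).T)
            d[i] = np.inf
            for j in np.argsort(d)[:k]:
                w[i, j] = 1.0
        w = w / w.sum(axis=1, keepdims=True)
        z = vals - vals.mean()
        num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
        brute = n / w.sum() * num / (z @ z)
        assert res.I == pytest.approx(brute, abs=1e-12)

    def test_bounds_with_row_standardized_weights(self, rng):
        pts = rng.uniform(0, 10, (40, 2))
        for _ in range(5):
            res = morans_i(pts, rng.normal(0, 1, 40))
            assert -1.0 - 1e-9 <= res.I <= 1.0 + 1e-9

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            morans_i(self._grid_points(), np.ones(64))


@pytest.fixture(scope="module")
def panel():
    return make_city_panel(
        PanelSpec(
            n_cities=80,
            sites_per_city=250,
            coefficients={"CENTER": 0.05, "LENGTH": 0.11, "WEST": 0.14,
                          "ELEVATION": -0.15},
            noise_sd=1.0,
            seed=21,
        )
    )


class TestLocationModels:
    def test_nested_predictor_sets(self):
        assert set(MODEL_PREDICTORS[1]) < set(MODEL_PREDICTORS[2]) < set(MODEL_PREDICTORS[3])

    def test_recovery_within_ci(self, panel):
        res = fit_location_models(panel, 3)
        se = 1.0 / np.sqrt(len(panel))
        assert abs(res.coefficients["CENTER"] - 0.05) < 3 * se
        assert abs(res.coefficients["LENGTH"] - 0.11) < 3 * se

    def test_adj_r2_non_decreasing_across_nested_models(self, panel):
        r2 = [fit_location_models(panel, m).adj_r2 for m in (1, 2, 3)]
        assert r2[0] <= r2[1] + 1e-6 <= r2[2] + 2e-6

    def test_standardization_invariance(self, panel):
        rescaled = panel.copy()
        rescaled["LENGTH"] = rescaled["LENGTH"] * 1000.0 + 5.0
        a = fit_location_models(panel, 1)
        b = fit_location_models(rescaled, 1)
        assert a.coefficients["LENGTH"] == pytest.approx(b.coefficients["LENGTH"], abs=1e-12)

    def test_rank_deficiency_names_collinear_pair(self, panel):
        dup = panel.copy()
        dup["LENGTH"] = dup["CENTER"]
        with pytest.raises(ValueError, match="CENTER.*LENGTH"):
            fit_location_models(dup, 1)

    def test_null_response_type_i_error_rate(self, rng):
        hits = 0
        reps = 200
        for rep in range(reps):
            n = 60
            df = pd.DataFrame(
                {
                    "GVI": rng.normal(0, 1, n),
                    "CENTER": rng.normal(0, 1, n),
                    "LENGTH": rng.normal(0, 1, n),
                }
            )
            res = fit_location_models(df, 1)
            hits += int((res.pvalues < 0.05).any())
        # two independent predictors: P(any false positive) ~ 1-(0.95)^2 = 9.75%
        assert 0.04 < hits / reps < 0.17


class TestFitByLevel:
    def test_strong_effects_recovered_exactly(self):
        panel = make_city_panel(
            PanelSpec(
                n_cities=60,
                sites_per_city=400,
                coefficients={"LENGTH": 0.2, "WEST": 0.15},
                noise_sd=1.0,
                seed=8,
            )
        )
        res = fit_by_level(panel, 4)
        assert set(res.coefficients.index) == {"LENGTH", "WEST"}
        assert (res.pvalues <= 0.05).all()

    def test_null_panel_usually_empty(self):
        empties = 0
        for seed in range(20):
            panel = make_city_panel(
                PanelSpec(n_cities=40, sites_per_city=60, noise_sd=1.0, seed=seed)
            )
            res = fit_by_level(panel, 4)
            empties += int(len(res.coefficients) == 0)
        assert empties > 10  # intercept-only in the majority of seeds

    def test_constant_covariate_dropped_and_reported(self):
        panel = make_city_panel(
            PanelSpec(n_cities=40, sites_per_city=60,
                      coefficients={"LENGTH": 0.3}, seed=2)
        )
        sub = panel[panel["LEVEL_RAW"] == 4].copy()
        sub["WATER"] = 0.0
        res = fit_by_level(sub, 4)
        assert "WATER" in res.dropped

    def test_too_few_records_refused(self):
        panel = make_city_panel(PanelSpec(n_cities=5, sites_per_city=4, seed=0))
        with pytest.raises(ValueError, match="at least 30"):
            fit_by_level(panel.head(40), 1)

    def test_deterministic_for_identical_inputs(self):
        panel = make_city_panel(
            PanelSpec(n_cities=40, sites_per_city=100,
                      coefficients={"CENTER": 0.1, "ECONOMY": 0.1}, seed=4)
        )
        a = fit_by_level(panel, 4)
        b = fit_by_level(panel.copy(), 4)
        assert list(a.coefficients.index) == list(b.coefficients.index)


class TestCovariateCorrelations:
    def test_orthogonal_covariates_unflagged(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (500, 3)), columns=["CENTER", "LENGTH", "SIZE"])
        _, flags = check_covariate_correlations(df, ["CENTER", "LENGTH", "SIZE"])
        assert flags == []

    def test_duplicate_column_flagged_at_unity(self):
        df = pd.DataFrame({"CENTER": np.arange(50.0)})
        df["LENGTH"] = df["CENTER"]
        _, flags = check_covariate_correlations(df, ["CENTER", "LENGTH"])
        assert flags[0][:2] == ("CENTER", "LENGTH")
        assert flags[0][2] == pytest.approx(1.0)

    def test_constructed_correlation_reported(self, rng):
        n = 4000
        a = rng.normal(0, 1, n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(0, 1, n)
        df = pd.DataFrame({"CENTER": a, "LENGTH": b})
        _, flags = check_covariate_correlations(df, ["CENTER", "LENGTH"])
        assert len(flags) == 1
        assert flags[0][2] == pytest.approx(0.9, abs=0.02)
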