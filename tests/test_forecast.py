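import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloomclock import forecast as fc

PRINTED = (3.56, -0.59, -0.22, -3.70)  # (beta_g, beta_b, beta_gb, beta_0)


def normal_equations_ols(x_mat, y):
    """Independent brute-force OLS: solve X'X beta = X'y directly."""
    xtx = x_mat.T @ x_mat
    xty = x_mat.T @ y
    return np.linalg.solve(xtx, xty)


def series_from(dct_g, dct_b, days):
    return pd.DataFrame(
        {"dct_g": dct_g, "dct_b": dct_b, "days_to_flowering": days}
    )


def grid_series(coeffs, n=6):
    bg, bb, bgb, b0 = coeffs
    g, b = np.meshgrid(np.linspace(0, 8, n), np.linspace(0, 12, n))
    g, b = g.ravel(), b.ravel()
    return series_from(g, b, bg * g + bb * b + bgb * g * b + b0)


class TestDeltaCt:
    @pytest.mark.parametrize("target,control,expected", [(25, 20, 5), (20, 20, 0)])
    def test_definition(self, target, control, expected):
        assert fc.delta_ct(target, control) == expected

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(0, 60, allow_nan=False), st.floats(0, 60, allow_nan=False)
    )
    def test_antisymmetry(self, a, b):
        assert fc.delta_ct(a, b) == -fc.delta_ct(b, a)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            fc.delta_ct(np.nan, 20)


class TestBuildDeltaCtSeries:
    def _meta(self, sample_days):
        return pd.DataFrame(
            {"sample_id": list(sample_days), "day_offset": list(sample_days.values())}
        )

    def test_two_subtractions_and_sign_convention(self):
        ct = pd.DataFrame(
            {
                "sample_id": ["x"] * 3,
                "role": ["CBFb", "CBFg", "CBFr"],
                "ct": [28.0, 30.0, 22.0],
            }
        )
        series = fc.build_delta_ct_series(ct, self._meta({"x": -14}))
        row = series.iloc[0]
        assert (row["dct_b"], row["dct_g"]) == (6.0, 8.0)
        assert row["days_to_flowering"] == 14.0

    def test_missing_control_names_sample(self):
        ct = pd.DataFrame(
            {
                "sample_id": ["x", "x"],
                "role": ["CBFb", "CBFg"],
                "ct": [28.0, 30.0],
            }
        )
        with pytest.raises(ValueError, match="'x'.*CBFr"):
            fc.build_delta_ct_series(ct, self._meta({"x": 0}))

    def test_duplicate_record_rejected(self):
        ct = pd.DataFrame(
            {
                "sample_id": ["x"] * 4,
                "role": ["CBFb", "CBFb", "CBFg", "CBFr"],
                "ct": [28.0, 28.5, 30.0, 22.0],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            fc.build_delta_ct_series(ct, self._meta({"x": 0}))


class TestStageCurve:
    def test_noiseless_quadratic_vertex_recovered(self):
        d = np.arange(0, 37, dtype=float)
        y = -((d - 20.0) ** 2)
        curve = fc.fit_stage_curve(d, y, degree=2)
        np.testing.assert_allclose(curve.coefficients, [-400.0, 40.0, -1.0], atol=1e-8)
        assert curve.extremum_day == pytest.approx(20.0, abs=1e-9)

    def test_noiseless_cubic_interior_extremum(self):
        # derivative 3*(d-10)*(d-40): local max at 10 inside [0, 36]
        d = np.arange(0, 37, dtype=float)
        y = d**3 - 75.0 * d**2 + 1200.0 * d
        curve = fc.fit_stage_curve(d, y, degree=3)
        assert curve.extremum_day == pytest.approx(10.0, abs=1e-9)

    def test_cubic_with_two_interior_roots_picks_data_extreme(self):
        # derivative 3*(d-10)*(d-30): both roots inside [0, 36];
        # the minimum at d=30 is farther from the mean than the max at 10
        d = np.linspace(0, 36, 73)
        y = d**3 - 60.0 * d**2 + 900.0 * d - 3000.0
        curve = fc.fit_stage_curve(d, y, degree=3)
        extreme = y[np.argmax(np.abs(y - y.mean()))]
        at_ext = np.polynomial.polynomial.polyval(curve.extremum_day, curve.coefficients)
        assert at_ext == pytest.approx(extreme, rel=1e-6)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="degree\\+2"):
            fc.fit_stage_curve([0, 1, 2], [1.0, 2.0, 3.0], degree=3)

    def test_monotone_data_no_interior_extremum(self):
        d = np.arange(0, 20, dtype=float)
        curve = fc.fit_stage_curve(d, 2.0 * d + 1.0, degree=2)
        assert curve.extremum_day is None

    def test_degree_d_data_fit_exactly(self, rng):
        for degree in (2, 3):
            coef = rng.normal(size=degree + 1)
            d = np.linspace(0, 30, 40)
            y = np.polynomial.polynomial.polyval(d, coef)
            curve = fc.fit_stage_curve(d, y, degree=degree)
            np.testing.assert_allclose(curve.coefficients, coef, atol=1e-7)
            assert curve.rss == pytest.approx(0.0, abs=1e-12)


class TestForecastModel:
    def test_printed_coefficients_roundtrip(self):
        model = fc.fit_forecast_model(grid_series(PRINTED))
        np.testing.assert_allclose(model.coefficients(), PRINTED, atol=1e-6)

    def test_constant_days_degenerate_fit(self, rng):
        g = rng.uniform(0, 8, 30)
        b = rng.uniform(0, 12, 30)
        model = fc.fit_forecast_model(series_from(g, b, np.full(30, 7.0)))
        np.testing.assert_allclose(
            model.coefficients(), (0.0, 0.0, 0.0, 7.0), atol=1e-8
        )

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 40))
            g = rng.uniform(0, 10, n)
            b = rng.uniform(0, 10, n)
            y = rng.normal(0, 10, n)
            model = fc.fit_forecast_model(series_from(g, b, y))
            x_mat = np.column_stack([np.ones(n), g, b, g * b])
            beta = normal_equations_ols(x_mat, y)
            np.testing.assert_allclose(
                model.coefficients(), (beta[1], beta[2], beta[3], beta[0]), atol=1e-10
            )

    def test_collinear_column_named(self, rng):
        g = rng.uniform(0, 8, 20)
        model_in = series_from(g, np.full(20, 3.0), rng.normal(size=20))
        with pytest.raises(ValueError, match="dct_b"):
            fc.fit_forecast_model(model_in)

    def test_residual_orthogonality(self, rng):
        g = rng.uniform(0, 8, 50)
        b = rng.uniform(0, 12, 50)
        y = 3 * g - b + rng.normal(0, 2, 50)
        model = fc.fit_forecast_model(series_from(g, b, y))
        pred, _ = fc.predict_days(model, g, b)
        resid = y - pred
        x_mat = np.column_stack([np.ones(50), g, b, g * b])
        np.testing.assert_allclose(x_mat.T @ resid, 0.0, atol=1e-8)

    def test_noisy_recovery_within_monte_carlo_error(self):
        """Estimates across replicates center on the generating values."""
        rng = np.random.default_rng(2024)
        estimates = []
        for _ in range(100):
            base = grid_series(PRINTED, n=23)  # 529 points
            noisy = base.copy()
            noisy["days_to_flowering"] += rng.normal(0, 0.5, len(base))
            estimates.append(fc.fit_forecast_model(noisy).coefficients())
        est = np.array(estimates)
        mean = est.mean(axis=0)
        se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(np.abs(mean - np.array(PRINTED)) <= 3 * se + 1e-12)


class TestPredictAndEvaluate:
    @pytest.mark.parametrize(
        "dct_g,dct_b,expected,in_range",
        [
            (0.0, 0.0, -3.70, False),
            (5.0, 0.0, 14.10, True),
            (1.0, 1.0, -0.95, False),
        ],
    )
    def test_printed_formula_evaluations(self, dct_g, dct_b, expected, in_range):
        model = fc.ForecastModel(*PRINTED)
        days, ok = fc.predict_days(model, dct_g, dct_b)
        assert days == pytest.approx(expected, abs=1e-12)
        assert ok is in_range

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            fc.predict_days(fc.ForecastModel(*PRINTED), np.inf, 0.0)

    def test_perfect_prediction(self):
        obs = np.array([0.0, 5.0, 10.0, 20.0])
        r, rmse, n = fc.evaluate_predictions(obs, obs)
        assert (r, rmse, n) == (1.0, 0.0, 4)

    def test_window_restriction(self):
        obs = np.array([0.0, 10.0, 30.0])
        pred = np.array([1.0, 9.0, 31.0])
        _, _, n = fc.evaluate_predictions(obs, pred, restrict_to_range=True)
        assert n == 2

    def test_rmse_tracks_noise_level(self):
        rng = np.random.default_rng(55)
        obs = rng.uniform(0, 21, 50)
        pred = obs + rng.normal(0, 1.0, 50)
        _, rmse, n = fc.evaluate_predictions(obs, pred)
        assert n == 50 and 0.6 <= rmse <= 1.4

    def test_too_few_after_restriction_errors(self):
        with pytest.raises(ValueError, match=">= 2"):
            fc.evaluate_predictions(np.array([30.0, 40.0]), np.array([1.0, 2.0]))


class TestModelJson:
    def test_roundtrip(self, tmp_path):
        model = fc.ForecastModel(*PRINTED, fit_diagnostics={"n": 36, "rss": 0.0, "r": 1.0})
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = fc.ForecastModel.from_json(path)
        assert loaded.coefficients() == model.coefficients()
        assert loaded.validity_range == (0.0, 21.0)
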