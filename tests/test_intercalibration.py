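import numpy as np
import pytest
from scipy import sparse
from scipy.optimize import linprog

from nightglow.composites import RegionMask
from nightglow.errors import FitError, ValidationError
from nightglow.intercalibration import (
    CalibrationModel,
    MedianIntercalibrator,
    apply_calibration,
    calibrate_series,
    dual_satellite_check,
    eval_scaled_poly,
    fit_calibration,
    fit_median_polynomial,
    l1_objective,
    select_base_year,
    select_most_recent,
)
from nightglow.synth import GainCurve, SatelliteSpec, SceneSpec, make_benchmark

from conftest import make_composite

DN = np.arange(64, dtype=float)


def primal_l1_fit(source_dn, base_dn, degree=6):
    """Independent oracle: explicit primal L1 linear program over residual splits."""
    x = np.asarray(source_dn, float) / 63.0
    y = np.asarray(base_dn, float)
    n, p = x.size, degree + 1
    V = np.vander(x, p, increasing=True)
    A = sparse.hstack(
        [sparse.csc_matrix(V), sparse.identity(n, format="csc"), -sparse.identity(n, format="csc")]
    )
    c = np.concatenate([np.zeros(p), np.ones(2 * n)])
    res = linprog(c, A_eq=A, b_eq=y, bounds=[(None, None)] * p + [(0, None)] * (2 * n),
                  method="highs")
    assert res.status == 0
    return res.x[:p], res.fun


def full_window(shape=(64, 64)):
    return RegionMask("window", np.ones(shape, dtype=bool))


class TestMedianPolynomialFit:
    def test_identity_recovered_exactly(self, rng):
        x = rng.integers(0, 64, 4000)
        coeffs = fit_median_polynomial(x, x.astype(float))
        np.testing.assert_allclose(eval_scaled_poly(coeffs, DN), DN, atol=1e-6)

    def test_affine_map_recovered(self, rng):
        source = rng.integers(1, 61, 50_000)
        base = np.clip(0.8 * source + 5, 0, 63)
        coeffs = fit_median_polynomial(source, base)
        fitted = eval_scaled_poly(coeffs, np.arange(1, 61))
        np.testing.assert_allclose(fitted, 0.8 * np.arange(1, 61) + 5, atol=0.1)

    def test_objective_matches_independent_primal_lp(self, rng):
        x = rng.integers(0, 64, 3000)
        y = eval_scaled_poly(np.array([0, 40, 10, 0, 0, 0, 13.0]), x) + rng.normal(0, 0.5, x.size)
        coeffs = fit_median_polynomial(x, y)
        _, f_oracle = primal_l1_fit(x, y)
        f_impl = l1_objective(coeffs, x, y)
        assert abs(f_impl - f_oracle) <= 1e-6 * abs(f_oracle)

    def test_agrees_with_irls_route_on_clean_data(self, rng):
        x = rng.integers(0, 64, 3000)
        y = 0.9 * x + 2 + rng.normal(0, 0.4, x.size)
        c_lp = fit_median_polynomial(x, y, solver="lp")
        c_irls = fit_median_polynomial(x, y, solver="irls")
        np.testing.assert_allclose(
            eval_scaled_poly(c_lp, DN), eval_scaled_poly(c_irls, DN), atol=0.05
        )

    def test_median_robust_to_30pct_contamination(self, rng):
        x = rng.integers(0, 64, 20_000)
        clean = 0.9 * x + 2.0
        y = clean + rng.normal(0, 0.25, x.size)
        idx = rng.choice(x.size, size=6000, replace=False)
        y_contam = y.copy()
        y_contam[idx] = rng.uniform(200, 1000, idx.size)
        c_clean = fit_median_polynomial(x, y)
        c_contam = fit_median_polynomial(x, y_contam)
        dev = np.abs(eval_scaled_poly(c_clean, DN) - eval_scaled_poly(c_contam, DN))
        assert dev.max() < 0.5

    def test_too_few_distinct_levels(self):
        x = np.repeat(np.arange(5), 100)
        with pytest.raises(FitError, match="distinct"):
            fit_median_polynomial(x, x.astype(float))


class TestCalibrationModel:
    def test_seven_coefficients_for_degree_six(self):
        model = CalibrationModel.identity(2000, "F12")
        assert model.coefficients.shape == (7,)
        assert model.degree == 6

    def test_raw_basis_coefficients_match_scaled_evaluation(self, rng):
        cs = rng.normal(0, 5, 7)
        model = CalibrationModel(1994, 2000, "F12", cs, n_pixels=10)
        raw = sum(c * DN**k for k, c in enumerate(model.coefficients))
        np.testing.assert_allclose(raw, model.evaluate(DN), rtol=1e-9, atol=1e-9)


class TestApplyCalibration:
    def test_truncation_both_ends(self):
        # linear map 2·DN − 4: negative below DN 2, above 63 past DN 33.5
        cs = np.array([-4.0, 2 * 63.0, 0, 0, 0, 0, 0])
        model = CalibrationModel(1994, 2000, "F12", cs, n_pixels=10)
        comp = make_composite(np.arange(64, dtype=np.int16).reshape(8, 8))
        out = apply_calibration(comp, model)
        assert out.grid.min() == 0.0 and out.grid.max() == 63.0
        assert out.grid.flat[0] == 0.0  # polynomial value −4 stored as 0
        assert out.grid.flat[63] == 63.0  # polynomial value 122 stored as 63
        assert out.calibrated

    def test_identity_model_changes_nothing_but_dtype(self, rng):
        comp = make_composite(rng.integers(0, 64, (8, 8)))
        out = apply_calibration(comp, CalibrationModel.identity(2000, "F12"))
        np.testing.assert_allclose(out.grid, comp.grid, atol=1e-9)

    def test_mismatched_year_rejected(self, rng):
        comp = make_composite(rng.integers(0, 64, (8, 8)), year=2001)
        model = CalibrationModel(1994, 2000, "F12", np.eye(1, 7, 1).ravel() * 63, 10)
        with pytest.raises(ValidationError):
            apply_calibration(comp, model)


class TestBaseYearSelection:
    def _comp(self, frac_zero, frac_sat, year):
        n = 400
        vals = np.full(n, 30, dtype=np.int16)
        vals[: int(frac_zero * n)] = 0
        vals[int(frac_zero * n): int((frac_zero + frac_sat) * n)] = 63
        return make_composite(vals.reshape(20, 20), year=year)

    def test_highest_combined_fraction_wins(self):
        a = self._comp(0.30, 0.10, 1994)
        b = self._comp(0.20, 0.05, 1995)
        assert select_base_year([a, b], full_window((20, 20))) == 1994

    def test_tie_goes_to_earliest_year(self):
        a = self._comp(0.2, 0.1, 1994)
        b = self._comp(0.2, 0.1, 1993)
        assert select_base_year([a, b], full_window((20, 20))) == 1993

    def test_scores_match_pixel_counting_loop(self, rng):
        comps = [make_composite(rng.integers(0, 64, (20, 20)), year=y) for y in (1994, 1995, 1996)]
        from nightglow.intercalibration import base_year_scores

        for s, comp in zip(base_year_scores(comps, full_window((20, 20))), comps):
            nz = sum(1 for v in comp.grid.ravel() if v == 0)
            ns = sum(1 for v in comp.grid.ravel() if v == 63)
            assert s.frac_zero == pytest.approx(nz / 400)
            assert s.frac_sat == pytest.approx(ns / 400)


class TestSeriesCalibration:
    def test_shared_gain_no_noise_gives_identity_models(self, null_spec):
        series, _ = make_benchmark(null_spec)
        window = null_spec.window_mask()
        calibrated, models = calibrate_series(series, window)
        for model in models:
            np.testing.assert_allclose(model.evaluate(DN), DN, atol=1e-6)
        grids = np.stack([c.grid for c in calibrated])
        assert np.abs(grids - grids[0]).max() < 1e-6

    def test_explicit_base_year_respected(self, null_spec):
        series, _ = make_benchmark(null_spec)
        _, models = calibrate_series(series, null_spec.window_mask(), base_year=1996)
        assert all(m.base_year == 1996 for m in models)

    def test_no_step_across_satellite_transitions(self):
        sats = [
            SatelliteSpec("F10", 1994, 1999, GainCurve(75, 55)),
            SatelliteSpec("F12", 1998, 2003, GainCurve(90, 70)),
        ]
        spec = SceneSpec(shape=(128, 128), years=(1994, 2003), satellites=sats,
                         jitter_max=0, noise_sd=0.4, seed=21)
        series, truth = make_benchmark(spec)
        cal = MedianIntercalibrator()
        calibrated = cal.fit_transform(series, spec.window_mask())
        selected = sorted(select_most_recent(calibrated).values(), key=lambda c: c.year)
        unchanged = truth.unchanged_land_mask()
        means = []
        for comp in selected:
            sel = unchanged & comp.valid_mask & (comp.grid < 62.9)
            means.append(comp.grid[sel].mean())
        assert np.abs(np.diff(means)).max() < 1.0

    def test_dual_satellite_bias_reduced(self):
        sats = [
            SatelliteSpec("F10", 1994, 2001, GainCurve(75, 55)),
            SatelliteSpec("F12", 1994, 2001, GainCurve(90, 70)),
        ]
        spec = SceneSpec(shape=(96, 96), years=(1994, 2001), satellites=sats,
                         change_events=[], jitter_max=0, noise_sd=0.4, seed=8)
        series, _ = make_benchmark(spec)
        cal = MedianIntercalibrator()
        calibrated = cal.fit_transform(series, spec.window_mask())
        year = cal.base_year_
        raw = {c.satellite_id: c for c in series if c.year == year}
        calb = {c.satellite_id: c for c in calibrated if c.year == year}
        report = dual_satellite_check(calb["F10"], calb["F12"], raw["F10"], raw["F12"])
        assert abs(report.bias_after) < abs(report.bias_before)
        assert report.n_pixels > 0


class TestInvariants:
    def test_calibrated_outputs_stay_in_range(self, rng):
        cs = rng.normal(0, 30, 7)  # arbitrary wild polynomial
        model = CalibrationModel(1994, 2000, "F12", cs, n_pixels=10)
        comp = make_composite(rng.integers(0, 64, (16, 16)))
        out = apply_calibration(comp, model)
        assert out.grid.min() >= 0.0 and out.grid.max() <= 63.0

    def test_base_fit_against_itself_is_identity(self, small_spec):
        series, _ = make_benchmark(small_spec)
        window = small_spec.window_mask()
        base = series[0]
        model = fit_calibration(base, base, window)
        np.testing.assert_allclose(model.evaluate(DN), DN, atol=1e-6)
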