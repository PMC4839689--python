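"""Half-life fits, T50 interpolation, profiles, kinetics and comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import curve_fit

from cystforge.fixtures import make_assay
from cystforge.stability import (
    AssaySeries,
    compare,
    crossing_half_life,
    fit_half_life,
    fit_lineweaver_burk,
    interpolate_T50,
    normalize_profile,
)


class TestFitHalfLife:
    def test_exact_recovery_of_first_order_decay(self):
        series = make_assay("inactivation_time", {"t_half": 59.0})
        result = fit_half_life(series)
        assert result.t_half == pytest.approx(59.0, abs=0.01)
        assert result.fit_r2 == pytest.approx(1.0, abs=1e-9)
        assert result.t_half == pytest.approx(np.log(2) / result.k_inact, abs=1e-12)

    def test_noisy_recovery_within_5_percent(self):
        series = make_assay("inactivation_time", {"t_half": 59.0, "sigma": 0.02}, seed=17)
        result = fit_half_life(series)
        assert result.t_half == pytest.approx(59.0, rel=0.05)

    def test_constant_series_rejected(self):
        series = AssaySeries("inactivation_time", np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError, match="no inactivation"):
            fit_half_life(series)

    def test_zero_activity_points_dropped_with_warning(self):
        x = np.arange(0.0, 60.0, 10.0)
        y = np.exp(-x / 20.0)
        y[-1] = 0.0
        with pytest.warns(UserWarning):
            result = fit_half_life(AssaySeries("inactivation_time", x, y))
        assert result.t_half == pytest.approx(20.0 * np.log(2), rel=1e-6)

    @given(st.floats(1.0, 500.0))
    @settings(derandomize=True, max_examples=50)
    def test_exact_on_noiseless_exponentials(self, t_half):
        series = make_assay("inactivation_time", {"t_half": t_half})
        assert fit_half_life(series).t_half == pytest.approx(t_half, rel=1e-9)

    def test_crossing_estimator_agrees_for_clean_decay(self):
        series = make_assay("inactivation_time", {"t_half": 40.0})
        assert crossing_half_life(series) == pytest.approx(40.0, rel=0.02)


class TestInterpolateT50:
    def test_exact_point_at_50_percent(self):
        series = AssaySeries("thermal_T50", np.array([70.0, 76.0, 80.0]), np.array([0.9, 0.5, 0.1]))
        assert interpolate_T50(series) == pytest.approx(76.0)

    def test_linear_interpolation_between_brackets(self):
        series = AssaySeries("thermal_T50", np.array([70.0, 75.0, 80.0]), np.array([0.9, 0.6, 0.4]))
        assert interpolate_T50(series) == pytest.approx(77.5)

    def test_percent_scale_accepted(self):
        series = AssaySeries("thermal_T50", np.array([75.0, 80.0]), np.array([60.0, 40.0]))
        assert interpolate_T50(series) == pytest.approx(77.5)

    def test_no_crossing_rejected(self):
        series = AssaySeries("thermal_T50", np.array([40.0, 50.0]), np.array([0.9, 0.8]))
        with pytest.raises(ValueError):
            interpolate_T50(series)

    def test_non_monotone_warns_first_crossing_used(self):
        series = AssaySeries(
            "thermal_T50",
            np.array([60.0, 65.0, 70.0, 75.0]),
            np.array([0.8, 0.4, 0.6, 0.2]),
        )
        with pytest.warns(UserWarning):
            t50 = interpolate_T50(series)
        assert 60.0 < t50 < 65.0

    @given(st.floats(0.1, 100.0))
    @settings(derandomize=True, max_examples=30)
    def test_invariant_under_uniform_activity_rescaling(self, scale):
        # rescaling raw activities together with the untreated control
        # leaves the crossing temperature unchanged
        y = np.array([90.0, 60.0, 40.0, 10.0])
        x = np.array([65.0, 70.0, 75.0, 80.0])
        base = interpolate_T50(AssaySeries("thermal_T50", x, y), control=100.0)
        rescaled = interpolate_T50(
            AssaySeries("thermal_T50", x, y * scale), control=100.0 * scale
        )
        assert rescaled == pytest.approx(base, abs=1e-9)


class TestNormalizeProfile:
    def test_optimum_at_peak(self):
        series = AssaySeries(
            "profile_temperature", np.array([55.0, 60.0, 65.0]), np.array([50.0, 100.0, 80.0])
        )
        out = normalize_profile(series)
        assert out.optimum == 60.0
        assert not out.tied
        np.testing.assert_allclose(out.series.y, [50.0, 100.0, 80.0])

    def test_idempotent_on_normalized_series(self):
        series = AssaySeries("profile_pH", np.array([5.0, 6.0, 7.0]), np.array([40.0, 100.0, 70.0]))
        once = normalize_profile(series)
        twice = normalize_profile(once.series)
        np.testing.assert_allclose(once.series.y, twice.series.y)

    def test_tie_flagged_lower_x_wins(self):
        series = AssaySeries("profile_pH", np.array([6.0, 6.5, 7.0]), np.array([80.0, 80.0, 10.0]))
        out = normalize_profile(series)
        assert out.optimum == 6.0
        assert out.tied

    def test_all_zero_rejected(self):
        series = AssaySeries("profile_pH", np.array([6.0, 7.0]), np.zeros(2))
        with pytest.raises(ValueError):
            normalize_profile(series)


class TestLineweaverBurk:
    def test_recovers_generating_km(self):
        series = make_assay("kinetics_substrate", {"Km": 277.8, "Vmax": 5.0})
        result = fit_lineweaver_burk(series)
        assert result.Km == pytest.approx(277.8, rel=1e-3)
        assert result.Vmax == pytest.approx(5.0, rel=1e-3)

    def test_rate_doubling_doubles_vmax_only(self):
        series = make_assay("kinetics_substrate", {"Km": 200.0, "Vmax": 2.0})
        doubled = AssaySeries("kinetics_substrate", series.x, series.y * 2)
        a = fit_lineweaver_burk(series)
        b = fit_lineweaver_burk(doubled)
        assert b.Vmax == pytest.approx(2 * a.Vmax, rel=1e-9)
        assert b.Km == pytest.approx(a.Km, rel=1e-9)

    def test_agrees_with_nonlinear_least_squares_oracle(self):
        series = make_assay(
            "kinetics_substrate", {"Km": 150.0, "Vmax": 3.0, "S": [50.0, 150.0, 600.0]}
        )
        lb = fit_lineweaver_burk(series)
        popt, _ = curve_fit(
            lambda s, vmax, km: vmax * s / (km + s), series.x, series.y, p0=(1.0, 100.0)
        )
        assert lb.Km == pytest.approx(popt[1], abs=1e-6)
        assert lb.Vmax == pytest.approx(popt[0], abs=1e-6)

    def test_kcat_and_specificity_constant(self):
        series = make_assay("kinetics_substrate", {"Km": 277.8, "Vmax": 5.0})
        r = fit_lineweaver_burk(series, enzyme_conc=0.027)
        assert r.kcat == pytest.approx(5.0 / 0.027, rel=1e-3)
        assert r.kcat_over_Km == pytest.approx(r.kcat / (r.Km / 1000.0), rel=1e-9)

    def test_non_saturable_data_rejected(self):
        # rates proportional to S: 1/v vs 1/S has zero intercept
        s = np.array([10.0, 20.0, 40.0])
        series = AssaySeries("kinetics_substrate", s, 0.1 * s)
        with pytest.raises(ValueError, match="non-saturable"):
            fit_lineweaver_burk(series)


class TestCompare:
    def test_half_life_percent_change(self):
        c = compare("WT", 59.0, "double mutant", 87.5, mode="percent")
        assert c.value == 48.3

    def test_melting_temperature_difference(self):
        c = compare("WT", 50.8, "double mutant", 54.9, mode="difference")
        assert c.value == pytest.approx(4.1, abs=1e-9)

    def test_identity_is_zero(self):
        assert compare("a", 3.3, "b", 3.3, mode="percent").value == 0.0
        assert compare("a", 3.3, "b", 3.3, mode="difference").value == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            compare("a", 0.0, "b", 1.0, mode="percent")

    @given(st.floats(1.0, 1e4), st.floats(1.0, 1e4))
    @settings(derandomize=True, max_examples=100)
    def test_forward_and_reverse_percent_are_reciprocal(self, a, b):
        p_ab = compare("a", a, "b", b, mode="percent").value
        p_ba = compare("b", b, "a", a, mode="percent").value
        # each percent is rounded to 1 decimal, so the product deviates
        # from 1 by at most ~0.0005 * (r + 1/r)
        r = b / a
        tol = 6e-4 * (r + 1.0 / r) + 1e-6
        assert (1 + p_ab / 100.0) * (1 + p_ba / 100.0) == pytest.approx(1.0, abs=tol)
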