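"""DSS-stage tests: categorization, duration covariates, surface, contours."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from neozy.sporulation_dss import (
    categorize,
    extract_durations,
    fit_surface,
    iso_contour,
    predict_probability,
    sporulation_advice,
)
from neozy.synthetic_data import SemiFieldGenConfig, simulate_semifield
from neozy.types import SurfaceParams, Thresholds, WeatherSeries, WeeklyTrial


def make_window(rh, temp, start="2011-01-01 00:00", window_id="w"):
    ts = pd.date_range(start, periods=24, freq="h")
    rh = np.full(24, rh, float) if np.isscalar(rh) else np.asarray(rh, float)
    temp = np.full(24, temp, float) if np.isscalar(temp) else np.asarray(temp, float)
    return WeatherSeries(window_id, ts, temp, rh)


class TestCategorize:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, "zero"), (1, "low"), (500, "low"), (501, "high"), (10_000, "high")],
    )
    def test_scale_boundaries(self, count, expected):
        assert categorize(count) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            categorize(-1)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_categories_are_exhaustive_and_consistent(self, n):
        cat = categorize(n)
        assert cat == ("zero" if n == 0 else "low" if n <= 500 else "high")


class TestExtractDurations:
    def test_all_exceed(self):
        assert extract_durations(make_window(100.0, 30.0)) == (24, 24)

    def test_threshold_is_strict(self):
        h_rh, _ = extract_durations(make_window(90.0, 25.0))
        assert h_rh == 0  # RH exactly 90 does not count as "higher than 90"

    def test_hand_counted_evening_humidity_block(self):
        # RH > 90 for the six hours 19:00-00:59 within a 15:00-start window
        ts = pd.date_range("2011-01-01 15:00", periods=24, freq="h")
        rh = np.where((ts.hour >= 19) | (ts.hour == 0), 95.0, 80.0)
        w = WeatherSeries("evening", ts, np.full(24, 20.0), rh)
        h_rh, h_temp = extract_durations(w)
        assert h_rh == 6
        assert h_temp == 0

    def test_gap_is_reported(self):
        ts = pd.date_range("2011-01-01", periods=24, freq="h").delete(13)
        ts = ts.append(pd.DatetimeIndex([ts[-1] + pd.Timedelta(hours=1)]))
        w = WeatherSeries("gappy", ts, np.full(24, 20.0), np.full(24, 50.0))
        with pytest.raises(ValueError, match="gap"):
            extract_durations(w)

    def test_wrong_window_length_rejected(self):
        ts = pd.date_range("2011-01-01", periods=23, freq="h")
        w = WeatherSeries("short", ts, np.full(23, 20.0), np.full(23, 50.0))
        with pytest.raises(ValueError, match="24 hourly"):
            extract_durations(w)


class TestFitSurface:
    def test_sequential_ladder_df_on_28_weeks(self, semifield_data):
        _, trials = semifield_data
        assert len(trials) == 28
        sf = fit_surface(trials)
        labels = [t.label for t in sf.anova]
        assert labels == ["h_temp", "h_rh", "h_rh:h_temp"]
        assert [t.df_den for t in sf.anova] == [26, 25, 24]
        assert all(t.df_num == 1 for t in sf.anova)
        assert sf.glm.df_resid == 24

    def test_interaction_test_near_nominal_under_additive_truth(self):
        additive = SurfaceParams(beta0=-4.0, beta_rh=0.25, beta_temp=0.25,
                                 beta_int=0.0)
        rejections = 0
        n_rep = 500
        for seed in range(n_rep):
            _, trials = simulate_semifield(
                SemiFieldGenConfig(surface=additive, seed=seed)
            )
            sf = fit_surface(trials)
            rejections += sf.anova[2].p_value < 0.05
        assert rejections / n_rep <= 0.10

    def test_coefficient_recovery_within_three_standard_errors(self, surface):
        hits = total = 0
        for seed in range(200):
            _, trials = simulate_semifield(SemiFieldGenConfig(seed=seed))
            sf = fit_surface(trials)
            se = sf.glm.std_errors()
            truth = surface.as_array()
            for est, s, tv in zip(sf.glm.coef, se, truth):
                total += 1
                hits += abs(est - tv) <= 3 * s
        assert hits / total >= 0.95

    def test_no_covariate_variation_rejected(self):
        trials = [WeeklyTrial(f"w{i}", 6, 10, 10, 5) for i in range(8)]
        with pytest.raises(ValueError, match="variation"):
            fit_surface(trials)


class TestPredictProbability:
    def test_printed_anchor_probabilities(self, surface):
        assert predict_probability(surface, 6, 10) == pytest.approx(0.90, abs=1e-10)
        assert predict_probability(surface, 15, 6) == pytest.approx(0.90, abs=1e-10)
        assert predict_probability(surface, 0, 0) == pytest.approx(0.01, abs=1e-10)

    def test_matches_direct_formula(self, surface, rng):
        for _ in range(10):
            hr, ht = rng.uniform(0, 24, 2)
            eta = (surface.beta0 + surface.beta_rh * hr
                   + surface.beta_temp * ht + surface.beta_int * hr * ht)
            assert predict_probability(surface, hr, ht) == pytest.approx(
                float(expit(eta)), abs=1e-12
            )


class TestIsoContour:
    def test_printed_contour_points(self, surface):
        at10 = iso_contour(surface, 0.9, "h_temp", 10.0)
        assert at10.feasible and at10.value == pytest.approx(6.0, abs=1e-9)
        at6 = iso_contour(surface, 0.9, "h_temp", 6.0)
        assert at6.feasible and at6.value == pytest.approx(15.0, abs=1e-9)

    def test_additive_surface_closed_form(self):
        p = SurfaceParams(beta0=-4.0, beta_rh=0.2, beta_temp=0.3, beta_int=0.0)
        sol = iso_contour(p, 0.5, "h_temp", 5.0)
        assert sol.value == pytest.approx((0.0 + 4.0 - 1.5) / 0.2, abs=1e-12)

    def test_contour_consistency_roundtrip(self, surface):
        for p in (0.1, 0.5, 0.9):
            for v in (2.0, 6.0, 10.0, 14.0):
                sol = iso_contour(surface, p, "h_temp", v)
                if sol.feasible:
                    assert predict_probability(surface, sol.value, v) == pytest.approx(
                        p, abs=1e-9
                    )

    def test_non_increasing_surface_is_infeasible_not_an_exception(self):
        p = SurfaceParams(beta0=0.0, beta_rh=-0.1, beta_temp=0.1, beta_int=0.0)
        sol = iso_contour(p, 0.9, "h_temp", 5.0)
        assert not sol.feasible
        assert sol.reason == "non-increasing surface"
        assert np.isnan(sol.root)

    def test_out_of_range_root_carried(self, surface):
        # at a warm fixed axis the 0.5 contour sits below 0 hours of RH
        sol = iso_contour(surface, 0.5, "h_temp", 15.0)
        assert not sol.feasible
        assert np.isfinite(sol.root)

    def test_degenerate_probability_rejected(self, surface):
        with pytest.raises(ValueError, match="in \\(0, 1\\)"):
            iso_contour(surface, 1.0, "h_temp", 10.0)


class TestSurfaceShape:
    def test_probability_monotone_in_warm_hours(self, surface):
        grid = np.linspace(0, 24, 25)
        for hr in grid:
            probs = [predict_probability(surface, hr, ht) for ht in grid]
            assert np.all(np.diff(probs) >= -1e-12)

    def test_probability_nearly_monotone_in_humid_hours(self, surface):
        # the negative interaction allows a <1e-3 dip at the 0.999 plateau
        grid = np.linspace(0, 24, 25)
        for ht in grid:
            probs = [predict_probability(surface, hr, ht) for hr in grid]
            assert np.all(np.diff(probs) >= -1e-3)


class TestSporulationAdvice:
    def test_extreme_windows_match_anchors(self, surface):
        wet = make_window(100.0, 30.0, window_id="wet")
        dry = make_window(50.0, 10.0, window_id="dry")
        advice = sporulation_advice([wet, dry], surface, p_star=0.9)
        assert advice[0].probability == pytest.approx(0.999, abs=1e-9)
        assert advice[0].favorable
        assert advice[1].probability == pytest.approx(0.01, abs=1e-9)
        assert not advice[1].favorable

    def test_flags_equal_direct_threshold_comparison(self, surface, rng):
        windows = [
            make_window(
                rng.uniform(80, 100, 24), rng.uniform(10, 30, 24),
                window_id=f"w{i}",
            )
            for i in range(20)
        ]
        advice = sporulation_advice(windows, surface, p_star=0.5)
        for a, w in zip(advice, windows):
            h_rh, h_temp = extract_durations(w)
            p = predict_probability(surface, h_rh, h_temp)
            assert a.favorable == (p >= 0.5)
            assert a.probability == pytest.approx(p, abs=1e-12)
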