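import datetime as dt

import numpy as np
import pandas as pd
import pytest

from hrmonitor import (
    BaselineStats,
    ChangeClass,
    MethodConfig,
    baseline_stats,
    compare_methods,
    default_config,
    flag_threshold,
    flag_zscore,
    swc_from_sd,
    trend_slope,
)

D0 = dt.date(2024, 1, 1)


def day(i):
    return D0 + dt.timedelta(days=i)


def series(values, step_days=1):
    idx = pd.DatetimeIndex([pd.Timestamp(day(i * step_days)) for i in range(len(values))])
    return pd.Series([float(v) for v in values], index=idx)


class TestBaselineStats:
    def test_spec_example(self):
        s = series([150, 152, 148, 150])
        st = baseline_stats(s, (day(0), day(3)))
        assert st.mean == pytest.approx(150.0)
        assert st.sd == pytest.approx(1.6329931618, abs=1e-9)
        assert st.n == 4

    def test_single_value_errors(self):
        with pytest.raises(ValueError):
            baseline_stats(series([150]), (day(0), day(0)))

    def test_identical_values_sd_zero(self):
        st = baseline_stats(series([150, 150, 150]), (day(0), day(2)))
        assert st.sd == 0.0

    def test_window_restricts(self):
        s = series([150, 150, 999])
        st = baseline_stats(s, (day(0), day(1)))
        assert st.mean == pytest.approx(150.0)


class TestSwcFromSd:
    def test_half_sd(self):
        st = BaselineStats(mean=60, sd=4.0, n=10, window=(day(0), day(13)))
        assert swc_from_sd(st) == pytest.approx(2.0)

    def test_degenerate_zero(self):
        st = BaselineStats(mean=60, sd=0.0, n=10, window=(day(0), day(13)))
        assert swc_from_sd(st) == 0.0

    def test_multiplier_one(self):
        st = BaselineStats(mean=60, sd=2.0, n=10, window=(day(0), day(13)))
        assert swc_from_sd(st, multiplier=1.0) == pytest.approx(2.0)


BASE150 = BaselineStats(mean=150.0, sd=2.0, n=14, window=(day(0), day(13)))


class TestFlagThreshold:
    def test_swc_percent(self):
        f = flag_threshold(148.0, BASE150, MethodConfig(method="swc", swc_pct=1.0))
        assert f.meaningful
        assert f.change_class is ChangeClass.DECREASED
        assert f.delta_pct == pytest.approx(-2.0 / 150.0 * 100.0)

    def test_conjunction_passes_swc_fails_te(self):
        f = flag_threshold(148.0, BASE150, MethodConfig(method="swc_and_te"))
        assert not f.meaningful
        assert f.change_class is ChangeClass.TRIVIAL

    def test_value_equal_baseline_trivial_all_methods(self):
        for method in ("swc", "te", "swc_and_te"):
            f = flag_threshold(150.0, BASE150, MethodConfig(method=method))
            assert not f.meaningful
            assert f.change_class is ChangeClass.TRIVIAL

    def test_strict_inequality_at_swc_boundary(self):
        # exactly 1%: NOT meaningful (strict >)
        f = flag_threshold(151.5, BASE150, MethodConfig(method="swc", swc_pct=1.0))
        assert not f.meaningful
        f = flag_threshold(151.5 + 1e-6, BASE150, MethodConfig(method="swc"))
        assert f.meaningful

    def test_strict_inequality_at_te_boundary(self):
        f = flag_threshold(154.5, BASE150, MethodConfig(method="te", te_pct=3.0))
        assert not f.meaningful
        f = flag_threshold(154.5 + 1e-6, BASE150, MethodConfig(method="te"))
        assert f.meaningful

    def test_sd_mode(self):
        cfg = MethodConfig(method="swc", swc_mode="sd", sd_multiplier=0.5)
        assert not flag_threshold(151.0, BASE150, cfg).meaningful  # |1| == 0.5*2
        assert flag_threshold(151.0 + 1e-9, BASE150, cfg).meaningful

    def test_zero_mean_percent_errors(self):
        st = BaselineStats(mean=0.0, sd=1.0, n=5, window=(day(0), day(4)))
        with pytest.raises(ValueError):
            flag_threshold(1.0, st, MethodConfig(method="swc"))

    def test_monotonicity_single_threshold(self):
        cfg = MethodConfig(method="swc")
        was_meaningful = False
        for delta in np.linspace(0, 10, 101):
            f = flag_threshold(150.0 + delta, BASE150, cfg)
            assert f.meaningful or not was_meaningful
            was_meaningful = f.meaningful


SPEC_SERIES = [60, 62, 58, 60, 63, 57, 65]


class TestFlagZscore:
    def test_spec_retrospective_example(self):
        s = series(SPEC_SERIES)
        f = flag_zscore(s, day(6), MethodConfig(method="z_retrospective"))
        vals = np.array(SPEC_SERIES, dtype=float)
        expected = (65 - vals.mean()) / vals.std(ddof=1)
        assert f.z == pytest.approx(expected, abs=1e-9)
        assert f.z == pytest.approx(1.525, abs=0.01)
        assert f.meaningful
        assert f.change_class is ChangeClass.INCREASED

    def test_rolling_insufficient_data(self):
        s = series(SPEC_SERIES)
        cfg = MethodConfig(method="z_rolling", min_n_rolling=4)
        f = flag_zscore(s, day(2), cfg, mode="rolling")
        assert f.z is None
        assert not f.meaningful
        assert f.change_class is ChangeClass.TRIVIAL

    def test_rolling_uses_only_past_data(self):
        s = series(SPEC_SERIES)
        cfg = MethodConfig(method="z_rolling")
        f = flag_zscore(s, day(4), cfg, mode="rolling")
        vals = np.array(SPEC_SERIES[:5], dtype=float)
        assert f.z == pytest.approx((63 - vals.mean()) / vals.std(ddof=1), abs=1e-9)

    def test_rolling_exclude_current_config(self):
        s = series(SPEC_SERIES)
        cfg = MethodConfig(method="z_rolling", rolling_includes_current=False)
        f = flag_zscore(s, day(4), cfg, mode="rolling")
        vals = np.array(SPEC_SERIES[:4], dtype=float)
        assert f.z == pytest.approx((63 - vals.mean()) / vals.std(ddof=1), abs=1e-9)

    def test_retrospective_equals_rolling_at_final_index(self):
        rng = np.random.default_rng(11)
        s = series(rng.normal(60, 3, size=30))
        cfg = MethodConfig(method="z_rolling")
        retro = flag_zscore(s, day(29), cfg, mode="retrospective")
        roll = flag_zscore(s, day(29), cfg, mode="rolling")
        assert roll.z == pytest.approx(retro.z, abs=1e-12)

    def test_constant_series_errors(self):
        s = series([60] * 7)
        with pytest.raises(ValueError):
            flag_zscore(s, day(6), MethodConfig(method="z_retrospective"))

    def test_missing_date_errors(self):
        with pytest.raises(ValueError):
            flag_zscore(series(SPEC_SERIES), day(99), MethodConfig(method="z_rolling"))


class TestTrendSlope:
    def test_exact_line(self):
        # +1 per week over 8 weekly points
        s = series(range(8), step_days=7)
        res = trend_slope(s, swc_band=0.5)
        assert res.slope_per_week == pytest.approx(1.0, abs=1e-12)
        assert res.change_class is ChangeClass.INCREASED

    def test_flat_series(self):
        s = series([5] * 6, step_days=7)
        res = trend_slope(s)
        assert res.slope_per_week == pytest.approx(0.0)
        assert res.change_class is ChangeClass.TRIVIAL

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        y = 150 + 0.3 * np.arange(20) + rng.normal(0, 1, 20)
        s = series(y, step_days=3)
        t_weeks = np.arange(20) * 3 / 7.0
        fit = sm.OLS(y, sm.add_constant(t_weeks)).fit()
        assert trend_slope(s).slope_per_week == pytest.approx(
            fit.params[1], abs=1e-9
        )

    def test_band_gates_sign(self):
        s = series(np.arange(6) * 0.1, step_days=7)  # total change 0.5
        assert trend_slope(s, swc_band=1.0).change_class is ChangeClass.TRIVIAL
        assert trend_slope(s, swc_band=0.4).change_class is ChangeClass.INCREASED

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            trend_slope(series([1, 2], step_days=7))


class TestCompareMethods:
    def test_all_quiet_agreement_one(self):
        vals = [150.0, 150.2, 149.9, 150.1] + [150.3, 149.8, 150.0, 150.2]
        s = series(vals)
        cfgs = [MethodConfig(method="swc"), MethodConfig(method="te")]
        _, agreement = compare_methods(s, (day(0), day(3)), cfgs)
        assert agreement[("swc", "te")] == 1.0

    def test_two_percent_step_splits_swc_and_te(self):
        vals = [150.0] * 3 + [150.1] + [153.0] * 4  # +2%: beats SWC 1%, not TE 3%
        s = series(vals)
        cfgs = [MethodConfig(method="swc"), MethodConfig(method="te")]
        matrix, agreement = compare_methods(s, (day(0), day(3)), cfgs)
        assert agreement[("swc", "te")] < 1.0
        last = matrix.iloc[-1]
        assert last["swc"].meaningful and not last["te"].meaningful

    def test_duplicate_method_agrees_with_itself(self):
        s = series([150, 151, 149, 150, 153, 148])
        cfgs = [MethodConfig(method="swc"), MethodConfig(method="swc")]
        matrix, agreement = compare_methods(s, (day(0), day(3)), cfgs)
        assert set(matrix.columns) == {"swc", "swc#1"}
        assert agreement[("swc", "swc#1")] == 1.0

    def test_conjunction_is_intersection(self):
        rng = np.random.default_rng(2)
        s = series(150 + rng.normal(0, 4, size=40))
        cfgs = [
            MethodConfig(method="swc"),
            MethodConfig(method="te"),
            MethodConfig(method="swc_and_te"),
        ]
        matrix, _ = compare_methods(s, (day(0), day(13)), cfgs)
        for _, row in matrix.iterrows():
            assert row["swc_and_te"].meaningful == (
                row["swc"].meaningful and row["te"].meaningful
            )

    def test_needs_two_methods(self):
        with pytest.raises(ValueError):
            compare_methods(series([1, 2, 3]), (day(0), day(2)), [MethodConfig()])


class TestDefaults:
    def test_channel_defaults(self):
        assert default_config("HRex").swc_pct == 1.0
        assert default_config("HRex").te_pct == 3.0
        assert default_config("HRR").swc_pct == 7.0
        assert default_config("HRrest").swc_mode == "sd"
        assert default_config("LnRMSSD").sd_multiplier == 0.5
        assert default_config("HRex").z_threshold == 1.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MethodConfig(method="bogus")
        with pytest.raises(ValueError):
            MethodConfig(swc_pct=0.0)
        with pytest.raises(ValueError):
            MethodConfig(min_n_rolling=1)
        with pytest.raises(ValueError):
            MethodConfig(swc_mode="absolute")
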