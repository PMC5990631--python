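import dataclasses
import datetime as dt
import math

import numpy as np
import pytest

from hrmonitor import (
    Channel,
    Intensity,
    Phase,
    ScheduleDay,
    SessionSpec,
    SimParams,
    acute_recovery_hours,
    build_schedule,
    default_params,
    ground_truth,
    simulate,
)

D0 = dt.date(2024, 1, 1)  # a Monday


def noise_free(template="microcycle_4_2", **overrides):
    return dataclasses.replace(
        default_params(template), noise_cv=0.0, rpe_noise_sd=0.0, **overrides
    )


class TestSchedules:
    def test_microcycle_counts(self):
        # 4 weeks -> 16 training days, 8 rest days, 8 test occasions
        sched = build_schedule("microcycle_4_2", n_weeks=4)
        assert len(sched.days) == 28
        training = [d for d in sched.days if d.sessions]
        rest = [d for d in sched.days if not d.sessions and not d.is_test]
        tests = [d for d in sched.days if d.is_test]
        assert len(training) == 16
        assert len(rest) == 8
        assert len(tests) == 8

    def test_microcycle_weekday_structure(self):
        sched = build_schedule("microcycle_4_2", n_weeks=2)
        for d in sched.days:
            wd = d.date.weekday()
            if wd in (0, 4):
                assert d.is_test
            if wd in (4, 5, 6):
                assert d.load_au == 0.0
            if wd in (0, 1, 2, 3):
                assert d.load_au > 0.0

    def test_season_break_weeks_have_zero_load(self):
        sched = build_schedule("season_fig5", n_weeks=30)
        break_days = [
            d for d in sched.days if sched.calendar.phase_of(d.date) is Phase.BREAK
        ]
        assert len(break_days) == 14
        assert all(d.load_au == 0.0 for d in break_days)
        assert sum(d.is_test for d in break_days) == 2

    def test_season_phases_cover_whole_span(self):
        sched = build_schedule("season_fig5", n_weeks=30)
        assert len(sched.days) == 210
        assert all(sched.calendar.phase_of(d.date) is not None for d in sched.days)
        assert sched.calendar.phase_of(D0) is Phase.PREPARATION
        assert sched.calendar.phase_of(sched.days[-1].date) is Phase.OFF_SEASON
        assert len(sched.calendar.game_days) > 0

    def test_same_seed_identical(self):
        a = build_schedule("season_fig5", n_weeks=20, seed=3)
        b = build_schedule("season_fig5", n_weeks=20, seed=3)
        assert a == b

    def test_custom_template(self):
        days = [
            ScheduleDay(D0, (SessionSpec(Intensity.HIGH, 60, 600),), is_test=True)
        ]
        sched = build_schedule("custom", custom_days=days)
        assert sched.days == tuple(days)
        with pytest.raises(ValueError):
            build_schedule("custom")

    def test_validation(self):
        with pytest.raises(ValueError):
            build_schedule("unknown_template")
        with pytest.raises(ValueError):
            build_schedule("microcycle_4_2", start=dt.date(2024, 1, 2))  # Tuesday
        with pytest.raises(ValueError):
            build_schedule("season_fig5", n_weeks=10)


class TestSimulateFixedPoints:
    def test_zero_load_schedule_constant_at_bases(self):
        days = [
            ScheduleDay(D0 + dt.timedelta(days=i), (), is_test=True) for i in range(14)
        ]
        sched = build_schedule("custom", custom_days=days)
        params = noise_free()
        log, simdays = simulate(sched, params)
        assert all(d.ground_truth == "fresh" for d in simdays)
        for ch, base in [
            (Channel.HREX, params.hrex_base),
            (Channel.HRR, params.hrr_base),
            (Channel.HRREST, params.hrrest_base),
            (Channel.LNRMSSD, params.lnrmssd_base),
            (Channel.RPE, params.rpe_base),
        ]:
            vals = log.channel_series(ch).values
            assert len(vals) == 14
            assert np.allclose(vals, base)

    def test_determinism_identical_seed(self):
        sched = build_schedule("microcycle_4_2", n_weeks=6)
        p = dataclasses.replace(default_params("microcycle_4_2"), seed=9)
        log1, days1 = simulate(sched, p)
        log2, days2 = simulate(sched, p)
        assert days1 == days2
        assert log1.to_frame().equals(log2.to_frame())

    def test_different_seeds_differ(self):
        sched = build_schedule("microcycle_4_2", n_weeks=4)
        log1, _ = simulate(sched, dataclasses.replace(default_params(), seed=1))
        log2, _ = simulate(sched, dataclasses.replace(default_params(), seed=2))
        assert not log1.to_frame().equals(log2.to_frame())


class TestDynamics:
    def test_fitness_recurrence_matches_oracle(self):
        sched = build_schedule("microcycle_4_2", n_weeks=4)
        p = noise_free()
        _, days = simulate(sched, p)
        # independent step-by-step recurrence
        f = p.f_init
        rest = 0
        for i, d in enumerate(days):
            if i > 0:
                prev = days[i - 1].load_au
                if prev > 0:
                    a = math.exp(-1.0 / p.tau_fitness)
                    f = a * f + (1 - a) * prev / p.load_ref
                    rest = 0
                else:
                    rest += 1
                    tau = p.tau_detraining if rest >= p.detrain_after_rest_days else p.tau_fitness
                    f *= math.exp(-1.0 / tau)
            assert d.fitness == pytest.approx(f, abs=1e-12)

    def test_friday_hrex_below_monday_every_week(self):
        sched = build_schedule("microcycle_4_2", n_weeks=12)
        log, _ = simulate(sched, noise_free())
        hrex = log.channel_series(Channel.HREX)
        mondays = hrex[hrex.index.dayofweek == 0]
        fridays = hrex[hrex.index.dayofweek == 4]
        assert len(mondays) == len(fridays) == 12
        assert (fridays.values < mondays.values).all()

    def test_season_mean_hrex_decreases_as_fitness_grows(self):
        sched = build_schedule("microcycle_4_2", n_weeks=12)
        log, days = simulate(sched, noise_free())
        hrex = log.channel_series(Channel.HREX)
        weekly = hrex.groupby(hrex.index.isocalendar().week.values).mean()
        fitness = [d.fitness for d in days]
        assert fitness[-1] > fitness[0]
        assert weekly.iloc[-1] < weekly.iloc[0]
        # weekly mean decreases monotonically after the first week
        assert (np.diff(weekly.values[1:]) < 1e-9).all()

    def test_table1_response_directions(self):
        # one high session on an otherwise empty schedule: next morning and
        # next test show the acute signature (HRex down is confounded by the
        # absence of fitness change here, so A dominates all channels)
        days = [
            ScheduleDay(D0, (), is_test=True),
            ScheduleDay(
                D0 + dt.timedelta(days=1),
                (SessionSpec(Intensity.HIGH, 110, 900),),
                is_test=False,
            ),
            ScheduleDay(D0 + dt.timedelta(days=2), (), is_test=True),
        ]
        sched = build_schedule("custom", custom_days=days)
        log, simdays = simulate(sched, noise_free(f_init=0.0))
        pre, post = simdays[0], simdays[2]
        assert post.acute > pre.acute
        assert post.observables["HRex"] < pre.observables["HRex"]  # suppressed
        assert post.observables["RPE"] > pre.observables["RPE"]  # elevated
        assert post.observables["HRR"] < pre.observables["HRR"]  # blunted
        assert post.observables["HRrest"] > pre.observables["HRrest"]  # elevated
        assert post.observables["LnRMSSD"] < pre.observables["LnRMSSD"]  # reduced

    def test_acute_recovery_bracket(self):
        hours = acute_recovery_hours(Intensity.HIGH, noise_free())
        assert hours >= 48
        # intensity ordering: harder sessions take longer to wash out
        low = acute_recovery_hours(Intensity.LOW, noise_free())
        thr = acute_recovery_hours(Intensity.THRESHOLD, noise_free())
        assert low < thr < hours

    def test_rpe_is_half_point_quantized_and_bounded(self):
        sched = build_schedule("microcycle_4_2", n_weeks=8)
        log, _ = simulate(sched, dataclasses.replace(default_params(), seed=5))
        rpe = log.channel_series(Channel.RPE).values
        assert ((rpe * 2) == np.round(rpe * 2)).all()
        assert (rpe >= 0).all() and (rpe <= 10).all()


class TestGroundTruth:
    def test_low_acute_all_fresh(self):
        days = [
            ScheduleDay(
                D0 + dt.timedelta(days=i),
                (SessionSpec(Intensity.LOW, 30, 150),),
            )
            for i in range(21)
        ]
        _, simdays = simulate(build_schedule("custom", custom_days=days), noise_free())
        assert all(d.ground_truth == "fresh" for d in simdays)

    def test_overload_block_gives_contiguous_overreached_span(self):
        _, simdays = simulate(
            build_schedule("season_fig5", n_weeks=30), noise_free("season_fig5")
        )
        labels = [d.ground_truth for d in simdays]
        assert "overreached" in labels
        first = labels.index("overreached")
        last = len(labels) - 1 - labels[::-1].index("overreached")
        assert all(l == "overreached" for l in labels[first : last + 1])
        # the span lies inside the preseason overload block (weeks 6-8)
        assert simdays[first].date >= D0 + dt.timedelta(weeks=5)
        assert simdays[last].date < D0 + dt.timedelta(weeks=9)

    def test_post_break_detrained(self):
        sched = build_schedule("season_fig5", n_weeks=30)
        _, simdays = simulate(sched, noise_free("season_fig5"))
        by_date = {d.date: d for d in simdays}
        # 15 zero-load days into the break: fitness collapsed, label detrained
        resumption_monday = D0 + dt.timedelta(weeks=18)
        assert by_date[resumption_monday].ground_truth == "detrained"

    def test_ground_truth_function_matches_stored_labels(self):
        sched = build_schedule("microcycle_4_2", n_weeks=6)
        p = noise_free()
        _, simdays = simulate(sched, p)
        assert ground_truth(simdays, p) == [d.ground_truth for d in simdays]


class TestParams:
    def test_default_params_per_template(self):
        assert default_params("microcycle_4_2").f_init == 0.0
        assert default_params("season_fig5").f_init == pytest.approx(0.6)
        assert default_params(None).f_init == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            SimParams(tau_fitness=0.0)
        with pytest.raises(ValueError):
            SimParams(noise_cv=-0.1)
        with pytest.raises(ValueError):
            SimParams(rpe_base=12.0)
        with pytest.raises(ValueError):
            SimParams(hrex_base=400.0)
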