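"""Synthetic athlete seasons with fitness-fatigue dynamics and ground truth.

The generator produces the data every other module is tested against:
training schedules, latent fitness/acute-perturbation states, noisy daily
observables, and per-day ground-truth labels.

Model
-----
Two latent states drive all observables:

* ``F`` — a slow *fitness* state: an exponentially weighted trace of the
  daily session-RPE load (normalized by a reference daily load), time
  constant ``tau_fitness`` (30 d).  Under sustained complete rest (three or
  more consecutive zero-load days) fitness decays with the much shorter
  ``tau_detraining`` (8 d): early detraining is rapid (plasma-volume loss,
  reduced blood volume), which is what makes a two-week mid-season shutdown
  visible against a season baseline.
* ``A`` — a fast *acute autonomic perturbation* state: a sum of session
  impulses decaying with an intensity-dependent hourly time constant
  (low 8 h, threshold 14 h, high 20 h), chosen so that ~95 % recovery
  (3 tau) lands at ~24 / ~42 / ~60 h — inside the reported 24 h /
  24-48 h / >=48 h cardiac-autonomic recovery brackets.

Observables (test-day exercise channels at 17:00, resting channels at
07:00, session impulses at 18:00):

* ``HRex  = hrex_base  * (1 - c_f*F - c_a*A) * (1 + eps)`` — both fitness
  and acute load *lower* submaximal exercise HR (the day after a hard day,
  HRex is reduced — which is exactly why HRex alone cannot separate
  adaptation from fatigue).
* ``RPE   = clip(rpe_base - d_f*F + d_a*A + eta, 0, 10)``, rounded to 0.5.
* ``HRrest = hrrest_base * (1 + e_a*A_high - e_f*F) * (1 + eps)`` — resting
  HR is raised only by *high-intensity* acute load.
* ``LnRMSSD = lnrmssd_base * (1 + g_f*F - g_a*A_high) * (1 + eps)``.
* ``HRR  = hrr_base * (1 + f_f*F - f_a*A) * (1 + eps)``.

``eps`` is multiplicative Gaussian noise with CV ``noise_cv`` (HR channels
scale with level); ``eta`` is additive Gaussian noise on the bounded
ordinal RPE scale.  All randomness flows from the single ``seed``.

Ground-truth labels per day (latents at 17:00): *fatigued* when
``A >= fatigue_threshold``; *overreached* when ``A`` has stayed at or above
``overreach_threshold`` for 7 consecutive days; *detrained* when fitness
has dropped below 90 % of its trailing-season peak after >=14 days of
recovery-context (near-zero load) days; *fresh* otherwise.
"""

from __future__ import annotations

import datetime as dt
import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import AthleteLog, Channel, DailyRecord, Phase, PhaseCalendar

__all__ = [
    "Intensity",
    "SessionSpec",
    "ScheduleDay",
    "Schedule",
    "SimParams",
    "SimDay",
    "default_params",
    "build_schedule",
    "simulate",
    "ground_truth",
    "acute_recovery_hours",
]


class Intensity(str, enum.Enum):
    LOW = "low"
    THRESHOLD = "threshold"
    HIGH = "high"


@dataclass(frozen=True)
class SessionSpec:
    intensity: Intensity
    duration_min: float
    load_au: float


@dataclass(frozen=True)
class ScheduleDay:
    date: dt.date
    sessions: tuple[SessionSpec, ...] = ()
    is_test: bool = False
    is_game: bool = False

    @property
    def load_au(self) -> float:
        return sum(s.load_au for s in self.sessions)


@dataclass(frozen=True)
class Schedule:
    template: str
    days: tuple[ScheduleDay, ...]
    calendar: PhaseCalendar = field(default_factory=PhaseCalendar)


@dataclass(frozen=True)
class SimParams:
    """All simulator constants; every field is a documented convention."""

    # observable baselines (the latent-free operating point, F = A = 0)
    hrex_base: float = 165.0  # bpm
    hrr_base: float = 50.0  # bpm recovered in 60 s
    hrrest_base: float = 55.0  # bpm
    lnrmssd_base: float = 4.0  # log-ms
    rpe_base: float = 7.0  # 0-10

    # dynamics
    tau_fitness: float = 30.0  # days
    tau_detraining: float = 8.0  # days, after sustained complete rest
    detrain_after_rest_days: int = 3  # consecutive zero-load days before fast decay
    tau_acute: dict[Intensity, float] = field(
        default_factory=lambda: {
            Intensity.LOW: 8.0,
            Intensity.THRESHOLD: 14.0,
            Intensity.HIGH: 20.0,
        }
    )  # hours
    load_ref: float = 600.0  # AU; a typical full training day
    f_init: float = 0.0  # initial fitness state (season scenarios start fitter)

    # gains (fraction of base per unit latent state)
    c_f: float = 0.06  # HRex suppression per unit fitness
    c_a: float = 0.077  # HRex suppression per unit acute perturbation
    d_f: float = 4.5  # RPE units per unit fitness
    d_a: float = 4.0  # RPE units per unit acute perturbation
    e_f: float = 0.05  # HRrest reduction per unit fitness
    e_a: float = 0.05  # HRrest elevation per unit high-intensity A
    g_f: float = 0.05  # Ln rMSSD elevation per unit fitness
    g_a: float = 0.08  # Ln rMSSD suppression per unit high-intensity A
    f_f: float = 0.15  # HRR elevation per unit fitness
    f_a: float = 0.10  # HRR suppression per unit acute perturbation

    # observation noise
    noise_cv: float = 0.02  # multiplicative CV on HR channels
    rpe_noise_sd: float = 0.5  # additive SD on RPE (rounded to 0.5)

    # ground-truth thresholds
    fatigue_threshold: float = 0.35  # a1: A at/above => fatigued
    overreach_threshold: float = 0.6  # a2: A sustained 7 d => overreached

    seed: int = 0

    # times of day (hours)
    morning_hour: int = 7
    test_hour: int = 17
    session_hour: int = 18

    def __post_init__(self) -> None:
        if self.tau_fitness <= 0 or self.tau_detraining <= 0:
            raise ValueError("time constants must be positive")
        if any(v <= 0 for v in self.tau_acute.values()):
            raise ValueError("acute time constants must be positive")
        if self.noise_cv < 0 or self.rpe_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        for name, lo, hi in (
            ("hrex_base", 30, 230),
            ("hrrest_base", 30, 230),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside physiologic {lo}-{hi} bpm")
        if not (0 <= self.rpe_base <= 10):
            raise ValueError("rpe_base outside the 0-10 scale")


def default_params(template: str | None = None, seed: int = 0) -> SimParams:
    """Scenario defaults.

    The season scenario starts with residual fitness (``f_init = 0.6``):
    players enter preseason off individual off-season programs, not fully
    detrained, and the mid-season shutdown is judged against that level.
    All other scenarios start from the neutral operating point.
    """
    p = SimParams(seed=seed)
    if template == "season_fig5":
        p = replace(p, f_init=0.6)
    return p


# ---------------------------------------------------------------------------
# Schedules


def _week(start: dt.date, spec: list[tuple[int, tuple | None, bool, bool]]):
    """Helper: spec rows are (weekday_offset, session-or-None, is_test, is_game)."""
    days = []
    by_off: dict[int, list] = {}
    for off, sess, test, game in spec:
        by_off.setdefault(off, []).append((sess, test, game))
    for off in range(7):
        rows = by_off.get(off, [(None, False, False)])
        sessions = tuple(
            SessionSpec(Intensity(i), dur, au) for (s, _, _) in rows if s for (i, dur, au) in [s]
        )
        days.append(
            ScheduleDay(
                date=start + dt.timedelta(days=off),
                sessions=sessions,
                is_test=any(t for (_, t, _) in rows),
                is_game=any(g for (_, _, g) in rows),
            )
        )
    return days


def _scaled(sessions: list[tuple[str, float, float]], scale: float):
    return [(i, d, round(au * scale)) for i, d, au in sessions]


def build_schedule(
    template: str,
    n_weeks: int = 12,
    seed: int = 0,
    start: dt.date = dt.date(2024, 1, 1),  # a Monday
    custom_days: list[ScheduleDay] | None = None,
) -> Schedule:
    """Build a training/testing schedule from a named template.

    microcycle_4_2
        The repeating weekly block of a preparatory period: Mon-Thu
        training (mixed intensities), Fri a test-only day, Sat-Sun complete
        rest; submaximal tests on Monday (after three days of pronounced
        recovery) and Friday (after four consecutive training days).
    season_fig5
        A full season: an 8-week preseason ramp whose final three weeks are
        a daily-training overload block, a steady in-season phase with a
        Saturday game and the weekly test two days post game-day (Monday),
        a 2-week mid-season break with zero scheduled load, a second
        in-season half, and a closing off-season; weekly tests throughout.
        Requires ``n_weeks >= 18`` (8 preseason + 2 break + 4 off-season
        plus in-season halves).
    custom
        Explicit ``custom_days``.

    Templates are deterministic; ``seed`` is accepted for interface
    symmetry with :func:`simulate` and reproducibility bookkeeping.
    """
    if start.weekday() != 0:
        raise ValueError("schedules start on a Monday")
    if template == "custom":
        if custom_days is None:
            raise ValueError("custom template needs custom_days")
        return Schedule("custom", tuple(custom_days))
    if template == "microcycle_4_2":
        if n_weeks < 1:
            raise ValueError("n_weeks must be >= 1")
        days: list[ScheduleDay] = []
        for w in range(n_weeks):
            monday = start + dt.timedelta(weeks=w)
            days += _week(
                monday,
                [
                    (0, ("threshold", 100, 600), True, False),
                    (1, ("high", 110, 900), False, False),
                    (2, ("threshold", 75, 450), False, False),
                    (3, ("high", 110, 900), False, False),
                    (4, None, True, False),  # Friday: test only, no session
                ],
            )
        cal = PhaseCalendar(
            [(start, start + dt.timedelta(weeks=n_weeks, days=-1), Phase.PREPARATION)]
        )
        return Schedule("microcycle_4_2", tuple(days), cal)
    if template == "season_fig5":
        if n_weeks < 18:
            raise ValueError("season template needs n_weeks >= 18")
        half1 = (n_weeks - 14 + 1) // 2
        half2 = n_weeks - 14 - half1
        days = []
        w = 0
        # preseason ramp: 5 progressively loaded standard weeks ...
        base_week = [
            ("low", 40, 200),
            ("threshold", 100, 600),
            ("threshold", 100, 600),
            ("high", 95, 750),
            ("low", 40, 200),
        ]
        for scale in (0.8, 0.9, 1.0, 1.1, 1.2):
            monday = start + dt.timedelta(weeks=w)
            scaled = _scaled(base_week, scale)
            days += _week(
                monday,
                [
                    (0, scaled[0], True, False),
                    (1, scaled[1], False, False),
                    (2, scaled[2], False, False),
                    (3, scaled[3], False, False),
                    (4, scaled[4], False, False),
                ],
            )
            w += 1
        # ... then a 3-week daily-training overload block
        for _ in range(3):
            monday = start + dt.timedelta(weeks=w)
            days += _week(
                monday,
                [(off, ("high", 110, 900), off == 0, False) for off in range(7)],
            )
            w += 1
        in_week = [
            ("low", 40, 200),  # Mon: test + light
            ("threshold", 75, 450),
            ("threshold", 75, 450),
            ("high", 75, 600),
            ("low", 30, 150),
        ]

        def in_season_week(monday: dt.date):
            return _week(
                monday,
                [
                    (0, in_week[0], True, False),
                    (1, in_week[1], False, False),
                    (2, in_week[2], False, False),
                    (3, in_week[3], False, False),
                    (4, in_week[4], False, False),
                    (5, ("high", 90, 800), False, True),  # Saturday game
                ],
            )

        for _ in range(half1):
            days += in_season_week(start + dt.timedelta(weeks=w))
            w += 1
        break_start_week = w
        for _ in range(2):  # mid-season break: tests continue, zero load
            monday = start + dt.timedelta(weeks=w)
            days += _week(monday, [(0, None, True, False)])
            w += 1
        for _ in range(half2):
            days += in_season_week(start + dt.timedelta(weeks=w))
            w += 1
        off_start_week = w
        for _ in range(4):  # off-season: weekly monitoring only
            monday = start + dt.timedelta(weeks=w)
            days += _week(monday, [(0, None, True, False)])
            w += 1
        d0 = start
        cal = PhaseCalendar(
            [
                (d0, d0 + dt.timedelta(weeks=8, days=-1), Phase.PREPARATION),
                (
                    d0 + dt.timedelta(weeks=8),
                    d0 + dt.timedelta(weeks=break_start_week, days=-1),
                    Phase.IN_SEASON,
                ),
                (
                    d0 + dt.timedelta(weeks=break_start_week),
                    d0 + dt.timedelta(weeks=break_start_week + 2, days=-1),
                    Phase.BREAK,
                ),
                (
                    d0 + dt.timedelta(weeks=break_start_week + 2),
                    d0 + dt.timedelta(weeks=off_start_week, days=-1),
                    Phase.IN_SEASON,
                ),
                (
                    d0 + dt.timedelta(weeks=off_start_week),
                    d0 + dt.timedelta(weeks=w, days=-1),
                    Phase.OFF_SEASON,
                ),
            ],
            game_days=[d.date for d in days if d.is_game],
        )
        return Schedule("season_fig5", tuple(days), cal)
    raise ValueError(f"unknown template {template!r}")


# ---------------------------------------------------------------------------
# Simulation


@dataclass(frozen=True)
class SimDay:
    """Latent state, emissions and ground-truth label of one simulated day."""

    date: dt.date
    load_au: float
    fitness: float  # F at day start
    acute: float  # total A at the test hour
    acute_high: float  # high-intensity A component at the morning hour
    observables: dict[str, float]
    ground_truth: str  # fresh | fatigued | overreached | detrained


class _AcuteState:
    """Per-intensity-class acute impulses with exact exponential decay."""

    def __init__(self, taus: dict[Intensity, float]):
        self.taus = taus
        self.comp = {c: 0.0 for c in taus}
        self.hour = 0.0

    def advance(self, hour: float) -> None:
        dh = hour - self.hour
        if dh < 0:
            raise ValueError("time runs forward only")
        for c, tau in self.taus.items():
            self.comp[c] *= math.exp(-dh / tau)
        self.hour = hour

    def impulse(self, intensity: Intensity, weight: float) -> None:
        self.comp[intensity] += weight

    @property
    def total(self) -> float:
        return sum(self.comp.values())


def simulate(
    schedule: Schedule, params: SimParams
) -> tuple[AthleteLog, list[SimDay]]:
    """Run the fitness-fatigue model over a schedule.

    Returns the observable :class:`AthleteLog` (what a practitioner would
    see) and the latent :class:`SimDay` series (what actually happened),
    including ground-truth labels.  Identical seed and parameters give
    bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    acute = _AcuteState(params.tau_acute)
    f = params.f_init
    consec_rest = 0
    records: list[DailyRecord] = []
    latents: list[tuple[dt.date, float, float, float, float, dict]] = []
    athlete = "sim"

    def noisy(base: float) -> float:
        if params.noise_cv == 0:
            return base
        return base * (1.0 + rng.normal(0.0, params.noise_cv))

    for i, day in enumerate(schedule.days):
        h0 = 24.0 * i
        obs: dict[str, float] = {}
        # fitness update from the previous day's load
        if i > 0:
            prev_load = schedule.days[i - 1].load_au
            if prev_load > 0:
                alpha = math.exp(-1.0 / params.tau_fitness)
                f = alpha * f + (1 - alpha) * prev_load / params.load_ref
                consec_rest = 0
            else:
                consec_rest += 1
                tau = (
                    params.tau_detraining
                    if consec_rest >= params.detrain_after_rest_days
                    else params.tau_fitness
                )
                f = math.exp(-1.0 / tau) * f

        # morning resting channels (daily)
        acute.advance(h0 + params.morning_hour)
        a_high_morning = acute.comp[Intensity.HIGH]
        hrrest = noisy(
            params.hrrest_base * (1 + params.e_a * a_high_morning - params.e_f * f)
        )
        lnrmssd = noisy(
            params.lnrmssd_base * (1 + params.g_f * f - params.g_a * a_high_morning)
        )
        obs["HRrest"] = hrrest
        obs["LnRMSSD"] = lnrmssd
        records.append(DailyRecord(day.date, athlete, Channel.HRREST, hrrest))
        records.append(DailyRecord(day.date, athlete, Channel.LNRMSSD, lnrmssd))

        # test-hour exercise channels
        acute.advance(h0 + params.test_hour)
        a_test = acute.total
        if day.is_test:
            hrex = noisy(
                params.hrex_base * (1 - params.c_f * f - params.c_a * a_test)
            )
            hrr = noisy(
                params.hrr_base * (1 + params.f_f * f - params.f_a * a_test)
            )
            rpe = params.rpe_base - params.d_f * f + params.d_a * a_test
            if params.rpe_noise_sd > 0:
                rpe += rng.normal(0.0, params.rpe_noise_sd)
            rpe = min(10.0, max(0.0, rpe))
            rpe = round(rpe * 2.0) / 2.0
            obs["HRex"] = hrex
            obs["HRR"] = hrr
            obs["RPE"] = rpe
            records.append(DailyRecord(day.date, athlete, Channel.HREX, hrex))
            records.append(DailyRecord(day.date, athlete, Channel.HRR, hrr))
            records.append(DailyRecord(day.date, athlete, Channel.RPE, rpe))

        # evening sessions: acute impulses + load record
        acute.advance(h0 + params.session_hour)
        for sess in day.sessions:
            acute.impulse(sess.intensity, sess.load_au / params.load_ref)
        if day.sessions:
            records.append(
                DailyRecord(
                    day.date, athlete, Channel.SESSION_LOAD, day.load_au
                )
            )
            records.append(
                DailyRecord(
                    day.date,
                    athlete,
                    Channel.DURATION_MIN,
                    sum(s.duration_min for s in day.sessions),
                )
            )
        latents.append((day.date, day.load_au, f, a_test, a_high_morning, obs))

    labels = _label(latents, params)
    simdays = [
        SimDay(
            date=d,
            load_au=load,
            fitness=f_,
            acute=a_,
            acute_high=ah,
            observables=o,
            ground_truth=lab,
        )
        for (d, load, f_, a_, ah, o), lab in zip(latents, labels)
    ]
    log = AthleteLog(records, calendar=schedule.calendar)
    return log, simdays


def _label(
    latents: list[tuple[dt.date, float, float, float, float, dict]],
    params: SimParams,
) -> list[str]:
    loads = np.array([row[1] for row in latents])
    fs = np.array([row[2] for row in latents])
    a_s = np.array([row[3] for row in latents])
    labels: list[str] = []
    f_peak = 0.0
    for i in range(len(latents)):
        f_peak = max(f_peak, fs[i])
        overreached = i >= 6 and bool(np.all(a_s[i - 6 : i + 1] >= params.overreach_threshold))
        fatigued = a_s[i] >= params.fatigue_threshold
        detrained = False
        if i >= 14:
            recent = loads[i - 13 : i + 1].sum()
            season_daily = loads[: i + 1].mean()
            if (
                season_daily > 0
                and recent <= 0.1 * 14 * season_daily
                and fs[i] < 0.9 * f_peak
            ):
                detrained = True
        if overreached:
            labels.append("overreached")
        elif fatigued:
            labels.append("fatigued")
        elif detrained:
            labels.append("detrained")
        else:
            labels.append("fresh")
    return labels


def acute_recovery_hours(
    intensity: Intensity | str = Intensity.HIGH,
    params: SimParams | None = None,
    fraction: float = 0.05,
    max_hours: int = 168,
) -> int:
    """Hours after a single session until A first falls below ``fraction`` of peak.

    Runs the acute-perturbation state of a noise-free simulation with one
    session of the given intensity on an otherwise empty schedule, sampling
    hourly.  For the default high-intensity dynamics this is the model's
    cardiac-autonomic recovery horizon.
    """
    params = params or SimParams()
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    state = _AcuteState(params.tau_acute)
    state.impulse(Intensity(intensity), 1.0)
    peak = state.total
    for hour in range(1, max_hours + 1):
        state.advance(float(hour))
        if state.total < fraction * peak:
            return hour
    raise ValueError(f"perturbation did not recover within {max_hours} h")


def ground_truth(simdays: list[SimDay], params: SimParams | None = None) -> list[str]:
    """Recompute the label series from stored latents (pure function)."""
    params = params or SimParams()
    latents = [
        (d.date, d.load_au, d.fitness, d.acute, d.acute_high, d.observables)
        for d in simdays
    ]
    return _label(latents, params)
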