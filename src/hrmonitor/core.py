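"""Domain types, calendar handling, and the rolling-window engine.

Everything downstream (HRV metrics, load accumulation, change detection,
the decision engine) operates on the small vocabulary defined here: an
``RRSeries`` of beat-to-beat intervals, a per-second ``HRTrace`` from a
submaximal test, and an ``AthleteLog`` of calendar-indexed daily values
(resting HR, Ln rMSSD, exercise HR, HR recovery, RPE, session load).

All dates are plain calendar days (no time zones); monitoring operates at
daily resolution.  Rolling windows are trailing — a window "ending" at a
date covers ``[date - width + 1, date]`` — because monitoring decisions may
only use data available at the time of the decision.
"""

from __future__ import annotations

import datetime as dt
import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Position",
    "RecordingContext",
    "Channel",
    "Phase",
    "ChangeClass",
    "RRSeries",
    "HRTrace",
    "DailyRecord",
    "PhaseCalendar",
    "AthleteLog",
    "rolling_window",
    "validate_log",
]


class Position(str, enum.Enum):
    """Body position during a resting R-R recording."""

    SUPINE = "supine"
    SEATED = "seated"
    STANDING = "standing"


class RecordingContext(str, enum.Enum):
    """Situational context of a resting recording."""

    REST_WAKING = "rest_waking"
    PRE_TRAINING = "pre_training"
    OTHER = "other"


class Channel(str, enum.Enum):
    """Monitoring channels stored in an :class:`AthleteLog`."""

    HRREST = "HRrest"
    LNRMSSD = "LnRMSSD"
    HREX = "HRex"
    HRR = "HRR"
    RPE = "RPE"
    SESSION_LOAD = "session_load"
    DURATION_MIN = "duration_min"


class Phase(str, enum.Enum):
    PREPARATION = "preparation"
    IN_SEASON = "in_season"
    BREAK = "break"
    OFF_SEASON = "off_season"


class ChangeClass(str, enum.Enum):
    """Tri-state direction of an observed change."""

    DECREASED = "decreased"
    TRIVIAL = "trivial"
    INCREASED = "increased"


@dataclass(frozen=True)
class RRSeries:
    """An ordered series of beat-to-beat R-R intervals, in milliseconds.

    Parameters
    ----------
    intervals
        Strictly positive R-R durations (ms), in recording order.
    start_time
        Wall-clock start of the recording.
    position, context
        Recording posture and situation; both are always set because
        resting HRV values are only comparable within a standardized
        position/context.
    """

    intervals: tuple[float, ...]
    start_time: dt.datetime = dt.datetime(2000, 1, 1, 7, 0)
    position: Position = Position.SEATED
    context: RecordingContext = RecordingContext.REST_WAKING

    def __init__(
        self,
        intervals: Iterable[float],
        start_time: dt.datetime = dt.datetime(2000, 1, 1, 7, 0),
        position: Position = Position.SEATED,
        context: RecordingContext = RecordingContext.REST_WAKING,
    ) -> None:
        vals = tuple(float(v) for v in intervals)
        if any(v <= 0 for v in vals):
            raise ValueError("R-R intervals must be strictly positive (ms)")
        object.__setattr__(self, "intervals", vals)
        object.__setattr__(self, "start_time", start_time)
        object.__setattr__(self, "position", Position(position))
        object.__setattr__(self, "context", RecordingContext(context))

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def mean_rr(self) -> float:
        if not self.intervals:
            raise ValueError("empty R-R series has no mean")
        return float(np.mean(self.intervals))


HR_MIN, HR_MAX = 30.0, 230.0
CESSATION_MARKER = "exercise_cessation"


@dataclass(frozen=True)
class HRTrace:
    """Per-second HR samples from a (sub)maximal test plus named markers.

    ``samples`` is an ordered sequence of ``(time_s, hr_bpm)`` pairs at a
    nominal 1 Hz (gaps allowed); ``markers`` maps names such as stage
    boundaries or ``"exercise_cessation"`` to times in seconds.
    """

    samples: tuple[tuple[float, float], ...]
    markers: dict[str, float] = field(default_factory=dict)

    def __init__(
        self,
        samples: Iterable[tuple[float, float]],
        markers: dict[str, float] | None = None,
    ) -> None:
        pairs = tuple((float(t), float(h)) for t, h in samples)
        times = [t for t, _ in pairs]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        for t, h in pairs:
            if not (HR_MIN <= h <= HR_MAX):
                raise ValueError(
                    f"HR sample {h} bpm at t={t}s outside plausible range "
                    f"[{HR_MIN}, {HR_MAX}]"
                )
        markers = dict(markers or {})
        if CESSATION_MARKER in markers and pairs:
            c = markers[CESSATION_MARKER]
            if not (times[0] <= c <= times[-1]):
                raise ValueError("cessation marker outside sampled range")
        object.__setattr__(self, "samples", pairs)
        object.__setattr__(self, "markers", markers)

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.samples])

    @property
    def hr(self) -> np.ndarray:
        return np.array([h for _, h in self.samples])

    @property
    def cessation(self) -> float:
        try:
            return self.markers[CESSATION_MARKER]
        except KeyError:
            raise ValueError("trace has no exercise_cessation marker") from None


@dataclass(frozen=True)
class DailyRecord:
    """One (athlete, date, channel, value) observation."""

    date: dt.date
    athlete_id: str
    channel: Channel
    value: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel", Channel(self.channel))
        object.__setattr__(self, "value", float(self.value))


@dataclass(frozen=True)
class PhaseCalendar:
    """Ordered, non-overlapping date ranges labelled with a training phase.

    ``phases`` maps ``(start, end)`` inclusive ranges to a :class:`Phase`;
    ``game_days`` is a set of match dates.  A date falling in no range maps
    to ``None`` ("unlabeled").
    """

    phases: tuple[tuple[dt.date, dt.date, Phase], ...] = ()
    game_days: frozenset[dt.date] = frozenset()

    def __init__(
        self,
        phases: Iterable[tuple[dt.date, dt.date, Phase | str]] = (),
        game_days: Iterable[dt.date] = (),
    ) -> None:
        rows = sorted(
            ((s, e, Phase(p)) for s, e, p in phases), key=lambda r: r[0]
        )
        for (s, e, _) in rows:
            if e < s:
                raise ValueError(f"phase range {s}..{e} ends before it starts")
        for (_, e1, _), (s2, _, _) in zip(rows, rows[1:]):
            if s2 <= e1:
                raise ValueError("phase ranges overlap")
        object.__setattr__(self, "phases", tuple(rows))
        object.__setattr__(self, "game_days", frozenset(game_days))

    def phase_of(self, date: dt.date) -> Phase | None:
        for s, e, p in self.phases:
            if s <= date <= e:
                return p
        return None


class AthleteLog:
    """Calendar-indexed multichannel record for one or more athletes.

    Multiple same-day recordings of a channel are aggregated by mean at
    construction so that each (athlete, date, channel) cell holds exactly
    one value — one decision input per day.
    """

    def __init__(
        self,
        records: Iterable[DailyRecord],
        calendar: PhaseCalendar | None = None,
        aggregate: str = "mean",
    ) -> None:
        recs = sorted(records, key=lambda r: (r.athlete_id, r.date, r.channel.value))
        if aggregate == "mean":
            agg: dict[tuple[str, dt.date, Channel], list[float]] = {}
            for r in recs:
                agg.setdefault((r.athlete_id, r.date, r.channel), []).append(r.value)
            recs = [
                DailyRecord(d, a, c, float(np.mean(vs)))
                for (a, d, c), vs in sorted(agg.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value))
            ]
        elif aggregate == "error":
            seen: set[tuple[str, dt.date, Channel]] = set()
            for r in recs:
                key = (r.athlete_id, r.date, r.channel)
                if key in seen:
                    raise ValueError(
                        f"duplicate record for athlete={r.athlete_id} "
                        f"date={r.date} channel={r.channel.value}"
                    )
                seen.add(key)
        else:
            raise ValueError(f"unknown aggregation {aggregate!r}")
        self.records: list[DailyRecord] = recs
        self.calendar = calendar or PhaseCalendar()

    def __len__(self) -> int:
        return len(self.records)

    @property
    def athletes(self) -> list[str]:
        return sorted({r.athlete_id for r in self.records})

    def channel_series(
        self,
        channel: Channel | str,
        athlete_id: str | None = None,
        start: dt.date | None = None,
        end: dt.date | None = None,
    ) -> pd.Series:
        """Values of one channel as a date-indexed Series (possibly empty).

        Queries are total: a date with no observation is simply absent from
        the index.  Restricting by ``athlete_id`` is required when the log
        holds more than one athlete.
        """
        channel = Channel(channel)
        if athlete_id is None:
            ids = self.athletes
            if len(ids) > 1:
                raise ValueError("log holds multiple athletes; pass athlete_id")
            athlete_id = ids[0] if ids else ""
        rows = [
            (r.date, r.value)
            for r in self.records
            if r.channel is channel
            and r.athlete_id == athlete_id
            and (start is None or r.date >= start)
            and (end is None or r.date <= end)
        ]
        idx = pd.DatetimeIndex([d for d, _ in rows])
        return pd.Series([v for _, v in rows], index=idx, dtype=float, name=channel.value)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [r.date for r in self.records],
                "athlete_id": [r.athlete_id for r in self.records],
                "channel": [r.channel.value for r in self.records],
                "value": [r.value for r in self.records],
            }
        )

    @property
    def start_date(self) -> dt.date:
        if not self.records:
            raise ValueError("empty log")
        return min(r.date for r in self.records)

    @property
    def end_date(self) -> dt.date:
        if not self.records:
            raise ValueError("empty log")
        return max(r.date for r in self.records)


# ---------------------------------------------------------------------------
# Rolling-window engine


def rolling_window(
    series: pd.Series | Sequence[tuple[dt.date, float]],
    width_days: int,
    min_obs: int,
    stat: str = "mean",
) -> pd.Series:
    """Trailing-window statistic over a date-indexed series.

    At each observation date the statistic is computed over the values whose
    dates fall in the trailing window ``[date - width_days + 1, date]``
    (closed on both ends).  The result is NaN ("absent") wherever fewer than
    ``min_obs`` valid values fall in the window — e.g. weekly averages of
    resting HRV are only considered valid with >=3-4 measurements per week.

    ``stat`` is one of ``"mean"``, ``"sd"`` (sample SD) or ``"cv"`` (sample
    SD / mean x 100, in percent).
    """
    if width_days < 1:
        raise ValueError("width_days must be >= 1")
    if min_obs < 1:
        raise ValueError("min_obs must be >= 1")
    if min_obs > width_days:
        raise ValueError("min_obs cannot exceed width_days")
    if not isinstance(series, pd.Series):
        series = pd.Series(
            [v for _, v in series],
            index=pd.DatetimeIndex([pd.Timestamp(d) for d, _ in series]),
            dtype=float,
        )
    series = series.sort_index()
    roll = series.rolling(f"{width_days}D", min_periods=min_obs)
    if stat == "mean":
        return roll.mean()
    if stat == "sd":
        return roll.std(ddof=1)
    if stat == "cv":
        m = roll.mean()
        s = roll.std(ddof=1)
        return s / m * 100.0
    raise ValueError(f"unknown stat {stat!r}")


def validate_log(log: AthleteLog) -> list[str]:
    """Check all log invariants; returns a (possibly empty) list of violations.

    Total function: never raises for a structurally constructed log.  Each
    violation names the offending record and the rule it breaks.
    """
    violations: list[str] = []
    seen: set[tuple[str, dt.date, Channel]] = set()
    for r in log.records:
        key = (r.athlete_id, r.date, r.channel)
        if key in seen:
            violations.append(
                f"{r.athlete_id} {r.date} {r.channel.value}: duplicate "
                "(athlete, date, channel) after aggregation"
            )
        seen.add(key)
        if r.channel is Channel.RPE and not (0.0 <= r.value <= 10.0):
            violations.append(
                f"{r.athlete_id} {r.date} RPE={r.value}: outside the 0-10 "
                "session-RPE scale"
            )
        if r.channel in (Channel.DURATION_MIN, Channel.SESSION_LOAD) and r.value < 0:
            violations.append(
                f"{r.athlete_id} {r.date} {r.channel.value}={r.value}: "
                "durations and loads must be >= 0"
            )
        if not math.isfinite(r.value):
            violations.append(
                f"{r.athlete_id} {r.date} {r.channel.value}: non-finite value"
            )
    return violations
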