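"""Session-RPE training load, acute/chronic accumulation, and context.

Internal training load is quantified as session-RPE load: RPE on the 0-10
scale times session duration in minutes, in arbitrary units (AU).  Loads
are accumulated over a trailing *acute* window (1 week) and a *chronic*
window (4 weeks); the chronic accumulation is expressed per week so that a
steady training routine yields an acute:chronic workload ratio (ACWR) of
exactly 1.  An exponentially-weighted variant (EWMA, decay 2/(N+1)) is
provided alongside the plain rolling windows.

The ratio also operationalizes the decision-relevant *context*: training
periods are constant or increasing loads (ACWR around or above 1), recovery
is a load reduction or rest (ACWR below a threshold, default 0.8, or zero
acute load).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AthleteLog, Channel

__all__ = [
    "LoadSummary",
    "session_load",
    "daily_load_series",
    "acute_chronic",
    "classify_context",
    "DEFAULT_REDUCTION_THRESHOLD",
    "MIN_CHRONIC_DAYS",
]

#: ACWR below this => the athlete is in a recovery context.
DEFAULT_REDUCTION_THRESHOLD = 0.8

#: The ACWR is reported as absent until the chronic window holds at least
#: this many days of data, to avoid early-season ratio spikes.
MIN_CHRONIC_DAYS = 21


@dataclass(frozen=True)
class LoadSummary:
    """Acute and chronic load state at one date."""

    date: dt.date
    acute_load: float  # AU over the trailing acute window
    chronic_weekly_load: float  # AU per week over the chronic window
    acwr: float | None  # absent while the chronic window is too short/empty
    method: str  # "rolling" | "ewma"


def session_load(rpe: float, duration_min: float) -> float:
    """Session-RPE training load: RPE (0-10) x duration (min), in AU."""
    if not (0.0 <= rpe <= 10.0):
        raise ValueError(f"RPE {rpe} outside the 0-10 scale")
    if duration_min < 0:
        raise ValueError("duration must be >= 0")
    return rpe * duration_min


def daily_load_series(log: AthleteLog, athlete_id: str | None = None) -> pd.Series:
    """Dense daily AU series from a log's session_load channel.

    Days without a record count as 0 AU — rest is information, not missing
    data, because the context definition hinges on load reductions.
    """
    s = log.channel_series(Channel.SESSION_LOAD, athlete_id)
    if s.empty:
        return s
    # The dense range covers the whole monitoring log, not just the span of
    # session records: trailing rest weeks (e.g. an off-season with resting
    # measurements only) are zero-load days, not the end of the data.
    start = min(s.index.min(), pd.Timestamp(log.start_date))
    end = max(s.index.max(), pd.Timestamp(log.end_date))
    full = pd.date_range(start, end, freq="D")
    return s.reindex(full, fill_value=0.0)


def acute_chronic(
    log: AthleteLog,
    acute_days: int = 7,
    chronic_days: int = 28,
    method: str = "rolling",
    athlete_id: str | None = None,
) -> list[LoadSummary]:
    """Acute load, chronic weekly load and ACWR for every day of the log.

    rolling
        acute = trailing ``acute_days`` sum; chronic weekly load = trailing
        ``chronic_days`` sum scaled to one week; ACWR = acute / chronic.
    ewma
        per-day exponentially smoothed load with decay ``2/(N+1)`` for each
        window length, both expressed per week, and their ratio.

    The ACWR is ``None`` until ``MIN_CHRONIC_DAYS`` days of data exist or
    when the chronic load is zero.
    """
    if acute_days < 1 or chronic_days < 1:
        raise ValueError("windows must be positive")
    if chronic_days < acute_days:
        raise ValueError("chronic window must be >= acute window")
    if method not in ("rolling", "ewma"):
        raise ValueError(f"unknown method {method!r}")

    daily = daily_load_series(log, athlete_id)
    if daily.empty:
        return []

    if method == "rolling":
        acute = daily.rolling(f"{acute_days}D", min_periods=1).sum()
        chronic_weekly = (
            daily.rolling(f"{chronic_days}D", min_periods=1).sum()
            * 7.0
            / chronic_days
        )
    else:
        acute_daily = daily.ewm(alpha=2.0 / (acute_days + 1), adjust=False).mean()
        chronic_daily = daily.ewm(alpha=2.0 / (chronic_days + 1), adjust=False).mean()
        acute = acute_daily * 7.0
        chronic_weekly = chronic_daily * 7.0

    out: list[LoadSummary] = []
    start = daily.index[0]
    for ts in daily.index:
        days_of_data = (ts - start).days + 1
        a = float(acute.loc[ts])
        c = float(chronic_weekly.loc[ts])
        ratio: float | None
        if days_of_data < MIN_CHRONIC_DAYS or c == 0.0:
            ratio = None
        else:
            ratio = a / c
        out.append(
            LoadSummary(
                date=ts.date(),
                acute_load=a,
                chronic_weekly_load=c,
                acwr=ratio,
                method=method,
            )
        )
    return out


def classify_context(
    summaries: list[LoadSummary],
    date: dt.date,
    reduction_threshold: float = DEFAULT_REDUCTION_THRESHOLD,
) -> str:
    """``"recovery"`` or ``"training"`` at a date.

    Recovery iff the ACWR falls strictly below ``reduction_threshold`` or
    the acute load is zero; a constant load (ACWR around 1) is training.
    While the ACWR is still undefined, the absolute acute load decides
    (zero => recovery).
    """
    by_date = {s.date: s for s in summaries}
    try:
        s = by_date[date]
    except KeyError:
        raise ValueError(f"no load summary at {date}") from None
    if s.acute_load == 0.0:
        return "recovery"
    if s.acwr is None:
        return "training"
    return "recovery" if s.acwr < reduction_threshold else "training"
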