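"""Heuristic contextual decision layer for HR monitoring.

The engine is a fast-and-frugal rule set: search rules (which markers to
look at — exercise HR and RPE from the weekly submaximal run), stopping
rules (stop once context, horizon and the two marker directions are known)
and decision rules (a fixed lookup table over context x horizon x ΔHRex x
ΔRPE).  The same observed change means different things in different
contexts: a reduced HRex with elevated RPE after consecutive training days
is acute fatigue, while the same long-term pattern under sustained high
loads points to overreaching; an increased HRex with elevated RPE after
weeks of rest is detraining, not freshness.

Only the table cells that the underlying evidence actually resolves carry
a named status; every other combination deliberately returns ``ambiguous``
with a ``review_context`` recommendation rather than guessing.  The one
extrapolated cell is training/short-term (HRex up, RPE up) -> a sickness /
non-training-stress warning.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .change import BASELINE_WEEKS, ChangeFlag
from .core import AthleteLog, Channel, ChangeClass
from .load import (
    DEFAULT_REDUCTION_THRESHOLD,
    LoadSummary,
    acute_chronic,
    classify_context,
    daily_load_series,
)

__all__ = [
    "ContextState",
    "StatusDecision",
    "EngineConfig",
    "classify_status",
    "vote_markers",
    "marker_ratio",
    "evaluate_log",
    "decision_table",
]

Horizon = str  # "short_term" | "long_term"

STATUS_RECOMMENDATION: dict[str, str] = {
    "normal": "continue",
    "coping": "maintain_high_load",
    "acute_fatigue": "reduce_load",
    "incomplete_recovery": "facilitate_recovery",
    "recovered": "resume_training",
    "positive_adaptation": "continue",
    "overreaching": "sustained_load_reduction",
    "detraining": "intensify_training",
    "warning_review": "review_context",
    "ambiguous": "review_context",
}

_D, _T, _I = ChangeClass.DECREASED, ChangeClass.TRIVIAL, ChangeClass.INCREASED

#: The decision table.  Keys: (context, horizon, ΔHRex class, ΔRPE class).
#: Unlisted combinations resolve to "ambiguous".
_TABLE: dict[tuple[str, str, ChangeClass, ChangeClass], str] = {
    # short-term changes while training: accumulated load
    ("training", "short_term", _D, _I): "acute_fatigue",
    ("training", "short_term", _D, _T): "coping",
    ("training", "short_term", _D, _D): "coping",
    ("training", "short_term", _I, _I): "warning_review",  # extrapolated
    # short-term changes after relief: recovery state
    ("recovery", "short_term", _I, _D): "recovered",
    ("recovery", "short_term", _I, _T): "recovered",
    ("recovery", "short_term", _T, _I): "incomplete_recovery",
    ("recovery", "short_term", _I, _I): "incomplete_recovery",
    # long-term changes under sustained training
    ("training", "long_term", _D, _T): "positive_adaptation",
    ("training", "long_term", _D, _D): "positive_adaptation",
    ("training", "long_term", _D, _I): "overreaching",
    # long-term changes under sustained relief
    ("recovery", "long_term", _I, _I): "detraining",
}


@dataclass(frozen=True)
class ContextState:
    """Decision context at one date: training vs recovery, and horizon."""

    context: str  # "training" | "recovery"
    horizon: Horizon  # "short_term" | "long_term"
    date: dt.date

    def __post_init__(self) -> None:
        if self.context not in ("training", "recovery"):
            raise ValueError(f"unknown context {self.context!r}")
        if self.horizon not in ("short_term", "long_term"):
            raise ValueError(f"unknown horizon {self.horizon!r}")


@dataclass(frozen=True)
class StatusDecision:
    """Engine output: status, recommendation, and the rule trace behind it."""

    date: dt.date
    horizon: Horizon
    context: str
    status: str
    recommendation: str
    trace: tuple[tuple[str, str, str], ...]  # (rule, input, verdict)


def classify_status(
    ctx: ContextState, hrex: ChangeClass, rpe: ChangeClass
) -> StatusDecision:
    """Look up (context, horizon, ΔHRex, ΔRPE) in the decision table.

    Total and deterministic over the full 2 x 2 x 3 x 3 domain; every
    decision carries the trace of the rules that produced it.
    """
    hrex = ChangeClass(hrex)
    rpe = ChangeClass(rpe)
    if hrex is _T and rpe is _T:
        status = "normal"
    else:
        status = _TABLE.get((ctx.context, ctx.horizon, hrex, rpe), "ambiguous")
    trace = (
        ("context", f"date={ctx.date}", ctx.context),
        ("horizon", "", ctx.horizon),
        ("hrex_change", "", hrex.value),
        ("rpe_change", "", rpe.value),
        (
            "decision_table",
            f"({ctx.context}, {ctx.horizon}, {hrex.value}, {rpe.value})",
            status,
        ),
    )
    return StatusDecision(
        date=ctx.date,
        horizon=ctx.horizon,
        context=ctx.context,
        status=status,
        recommendation=STATUS_RECOMMENDATION[status],
        trace=trace,
    )


def decision_table() -> pd.DataFrame:
    """The full 36-cell decision table as a human-readable DataFrame."""
    rows = []
    for context in ("training", "recovery"):
        for horizon in ("short_term", "long_term"):
            for hrex in (_D, _T, _I):
                for rpe in (_D, _T, _I):
                    d = classify_status(
                        ContextState(context, horizon, dt.date(2000, 1, 1)),
                        hrex,
                        rpe,
                    )
                    rows.append(
                        {
                            "context": context,
                            "horizon": horizon,
                            "hrex": hrex.value,
                            "rpe": rpe.value,
                            "status": d.status,
                            "recommendation": d.recommendation,
                        }
                    )
    return pd.DataFrame(rows)


def vote_markers(flags: Iterable[ChangeFlag], k: int) -> bool:
    """k-of-n marker rule: true iff at least ``k`` flags are meaningful."""
    flags = list(flags)
    if not (1 <= k <= len(flags)):
        raise ValueError(f"k={k} out of range for {len(flags)} markers")
    return sum(f.meaningful for f in flags) >= k


def marker_ratio(numerator: float, denominator: float) -> float:
    """Continuous marker combination, e.g. HRex/RPE or Ln rMSSD/R-R."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return numerator / denominator


# ---------------------------------------------------------------------------
# Log-level evaluation pipeline


@dataclass(frozen=True)
class EngineConfig:
    """Thresholds and comparators for evaluating a monitoring log.

    ``hrex_swc_pct``: percent band for HRex change classification (both
    horizons).  ``rpe_delta``: the minimal RPE change on the 0-10 scale
    treated as a real shift (the smallest whole-scale increment, compared
    non-strictly).  Short-term context is judged from the load of the
    ``short_context_days`` preceding days against the chronic daily mean;
    long-term context from the acute:chronic workload ratio.
    """

    hrex_swc_pct: float = 1.0
    rpe_delta: float = 1.0
    baseline_weeks: int = BASELINE_WEEKS
    reduction_threshold: float = DEFAULT_REDUCTION_THRESHOLD
    short_context_days: int = 2
    acute_days: int = 7
    chronic_days: int = 28


def _classify_pct(value: float, reference: float, band_pct: float) -> ChangeClass:
    if reference == 0:
        raise ValueError("reference value 0: percent change undefined")
    pct = (value - reference) / reference * 100.0
    if pct > band_pct:
        return ChangeClass.INCREASED
    if pct < -band_pct:
        return ChangeClass.DECREASED
    return ChangeClass.TRIVIAL


def _classify_abs(value: float, reference: float, band: float) -> ChangeClass:
    delta = value - reference
    if delta >= band:
        return ChangeClass.INCREASED
    if delta <= -band:
        return ChangeClass.DECREASED
    return ChangeClass.TRIVIAL


def _short_context(
    daily_load: pd.Series, date: pd.Timestamp, cfg: EngineConfig
) -> str:
    """Training vs recovery over the last few days (for short-term reads).

    Recovery iff the load of the ``short_context_days`` days preceding the
    test day is zero or reduced below ``reduction_threshold`` times the
    athlete's chronic daily mean over those days.
    """
    nd = cfg.short_context_days
    window = daily_load.loc[
        date - pd.Timedelta(days=nd) : date - pd.Timedelta(days=1)
    ]
    recent = float(window.sum())
    if recent == 0.0:
        return "recovery"
    hist = daily_load.loc[: date - pd.Timedelta(days=1)]
    hist = hist.iloc[-cfg.chronic_days :]
    chronic_daily = float(hist.mean()) if len(hist) else 0.0
    if chronic_daily > 0 and recent < cfg.reduction_threshold * nd * chronic_daily:
        return "recovery"
    return "training"


def evaluate_log(
    log: AthleteLog,
    cfg: EngineConfig | None = None,
    athlete_id: str | None = None,
) -> list[StatusDecision]:
    """Run the full decision pipeline over every test occasion of a log.

    Per test date (a date carrying an HRex value): classify the context
    from the training loads, classify the short-term change (vs the
    previous test occasion) and the long-term change (vs the baseline:
    mean over the first ``baseline_weeks`` weeks of the log) for HRex and
    RPE, and emit one :class:`StatusDecision` per horizon, each with its
    rule trace.
    """
    cfg = cfg or EngineConfig()
    if len(log) == 0:
        raise ValueError("empty log")
    hrex = log.channel_series(Channel.HREX, athlete_id).dropna()
    rpe = log.channel_series(Channel.RPE, athlete_id).dropna()
    if hrex.empty or rpe.empty:
        raise ValueError("log must contain HRex and RPE channels")

    start = pd.Timestamp(log.start_date)
    base_end = start + pd.Timedelta(days=7 * cfg.baseline_weeks - 1)
    hrex_base = hrex.loc[start:base_end]
    rpe_base = rpe.loc[hrex.loc[start:base_end].index.intersection(rpe.index)]
    if len(hrex_base) < 2:
        raise ValueError(
            f"baseline window {start.date()}..{base_end.date()} holds "
            f"{len(hrex_base)} HRex values; need >= 2"
        )
    hrex_ref = float(hrex_base.mean())
    rpe_ref = float(rpe_base.mean())

    daily_load = daily_load_series(log, athlete_id)
    summaries: list[LoadSummary] = (
        acute_chronic(
            log, cfg.acute_days, cfg.chronic_days, "rolling", athlete_id
        )
        if not daily_load.empty
        else []
    )
    by_date = {s.date: s for s in summaries}

    decisions: list[StatusDecision] = []
    prev_test: pd.Timestamp | None = None
    for ts in hrex.index:
        date = ts.date()
        if ts not in rpe.index:
            prev_test = ts
            continue
        # long-term: level vs season baseline, context from the ACWR
        if date in by_date:
            long_ctx = classify_context(summaries, date, cfg.reduction_threshold)
        else:
            long_ctx = "training"
        long_hrex = _classify_pct(float(hrex.loc[ts]), hrex_ref, cfg.hrex_swc_pct)
        long_rpe = _classify_abs(float(rpe.loc[ts]), rpe_ref, cfg.rpe_delta)
        decisions.append(
            classify_status(
                ContextState(long_ctx, "long_term", date), long_hrex, long_rpe
            )
        )
        # short-term: vs the previous test occasion, context from recent days
        if prev_test is not None and prev_test in rpe.index:
            short_ctx = (
                _short_context(daily_load, ts, cfg)
                if not daily_load.empty
                else "training"
            )
            s_hrex = _classify_pct(
                float(hrex.loc[ts]), float(hrex.loc[prev_test]), cfg.hrex_swc_pct
            )
            s_rpe = _classify_abs(
                float(rpe.loc[ts]), float(rpe.loc[prev_test]), cfg.rpe_delta
            )
            decisions.append(
                classify_status(
                    ContextState(short_ctx, "short_term", date), s_hrex, s_rpe
                )
            )
        prev_test = ts
    return decisions
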