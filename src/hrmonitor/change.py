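"""Meaningful-change detection for individual monitoring series.

Whether an observed change in a monitoring marker matters can be judged
against several partially conflicting yardsticks, and the methods genuinely
disagree on real series — which is why they are implemented side by side:

* **SWC** — smallest worthwhile change, the smallest practically relevant
  change: 1 % of baseline for exercise HR, 7 % for HR recovery, or a
  fraction (default 0.5) of the baseline SD for resting HR/Ln rMSSD.
* **TE** — typical (test-retest) error, the noise floor: 3 % by default.
* **SWC+TE** — a change must clear both bands.
* **Z-scores** — within-athlete distributional flags, |z| > 1, computed
  either retrospectively (mean/SD of the entire series) or on a rolling,
  additive basis using only the data available at each point in time.

All thresholds are strict inequalities ("larger than" the band); a change
exactly on a boundary is trivial.  Baselines default to the average of the
first 4 weeks of the preparation period and stay fixed unless re-baselined
explicitly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ChangeClass, Channel

__all__ = [
    "BaselineStats",
    "MethodConfig",
    "ChangeFlag",
    "TrendResult",
    "baseline_stats",
    "swc_from_sd",
    "flag_threshold",
    "flag_zscore",
    "trend_slope",
    "compare_methods",
    "default_config",
    "BASELINE_WEEKS",
]

#: Baseline window length: first 4 weeks of the preparation period.
BASELINE_WEEKS = 4

THRESHOLD_METHODS = ("swc", "te", "swc_and_te")
Z_METHODS = ("z_retrospective", "z_rolling")


@dataclass(frozen=True)
class BaselineStats:
    """Sample mean/SD of a channel over a (baseline) window."""

    mean: float
    sd: float
    n: int
    window: tuple[dt.date, dt.date]


@dataclass(frozen=True)
class MethodConfig:
    """Configuration of one meaningful-change method.

    ``swc_mode`` selects how the SWC band is formed: ``"percent"`` of the
    baseline mean (exercise channels: 1 % HRex, 7 % HRR) or ``"sd"``, a
    multiple of the baseline SD (resting channels: 0.5 x SD).
    """

    method: str = "swc"
    swc_pct: float = 1.0
    te_pct: float = 3.0
    sd_multiplier: float = 0.5
    swc_mode: str = "percent"
    z_threshold: float = 1.0
    min_n_rolling: int = 4
    rolling_includes_current: bool = True

    def __post_init__(self) -> None:
        if self.method not in THRESHOLD_METHODS + Z_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.swc_mode not in ("percent", "sd"):
            raise ValueError(f"unknown swc_mode {self.swc_mode!r}")
        for name in ("swc_pct", "te_pct", "sd_multiplier", "z_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_n_rolling < 2:
            raise ValueError("min_n_rolling must be >= 2 (SD needs 2 points)")


def default_config(channel: Channel | str, method: str = "swc") -> MethodConfig:
    """Paper-anchored per-channel defaults.

    HRex: SWC 1 % / TE 3 %; HRR: SWC 7 %; resting channels (HRrest,
    Ln rMSSD): SD-based SWC with multiplier 0.5.
    """
    channel = Channel(channel)
    if channel is Channel.HRR:
        return MethodConfig(method=method, swc_pct=7.0)
    if channel in (Channel.HRREST, Channel.LNRMSSD):
        return MethodConfig(method=method, swc_mode="sd")
    return MethodConfig(method=method)


@dataclass(frozen=True)
class ChangeFlag:
    """Per-date, per-method verdict on an observed value."""

    date: dt.date | None
    method: str
    delta: float
    delta_pct: float | None
    z: float | None
    change_class: ChangeClass
    meaningful: bool


@dataclass(frozen=True)
class TrendResult:
    slope_per_week: float
    change_class: ChangeClass


def baseline_stats(
    series: pd.Series, window: tuple[dt.date, dt.date]
) -> BaselineStats:
    """Sample mean and SD (n-1) over the values inside ``window`` (inclusive)."""
    start, end = window
    vals = series.loc[pd.Timestamp(start) : pd.Timestamp(end)].dropna()
    if len(vals) < 2:
        raise ValueError(
            f"baseline window {start}..{end} holds {len(vals)} values; need >= 2"
        )
    return BaselineStats(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        n=int(len(vals)),
        window=(start, end),
    )


def swc_from_sd(stats: BaselineStats, multiplier: float = 0.5) -> float:
    """SD-based smallest worthwhile change: ``multiplier x baseline SD``.

    With SD 0 the band degenerates to 0 and every nonzero change is
    meaningful.
    """
    if stats.sd < 0:
        raise ValueError("sd must be >= 0")
    return multiplier * stats.sd


def _direction(delta: float, meaningful: bool) -> ChangeClass:
    if not meaningful or delta == 0:
        return ChangeClass.TRIVIAL
    return ChangeClass.INCREASED if delta > 0 else ChangeClass.DECREASED


def flag_threshold(
    value: float,
    stats: BaselineStats,
    cfg: MethodConfig,
    date: dt.date | None = None,
) -> ChangeFlag:
    """SWC / TE / SWC+TE verdict of ``value`` against a baseline.

    The change is meaningful when it strictly exceeds the SWC band, the TE
    band, or both, depending on ``cfg.method``.
    """
    if cfg.method not in THRESHOLD_METHODS:
        raise ValueError(f"{cfg.method!r} is not a threshold method")
    delta = value - stats.mean
    if cfg.swc_mode == "percent" or cfg.method in ("te", "swc_and_te"):
        if stats.mean == 0:
            raise ValueError("percent thresholds undefined: baseline mean is 0")
    delta_pct = delta / stats.mean * 100.0 if stats.mean != 0 else None

    def beats_swc() -> bool:
        if cfg.swc_mode == "percent":
            return abs(delta_pct) > cfg.swc_pct  # type: ignore[arg-type]
        return abs(delta) > swc_from_sd(stats, cfg.sd_multiplier)

    def beats_te() -> bool:
        return abs(delta_pct) > cfg.te_pct  # type: ignore[arg-type]

    if cfg.method == "swc":
        meaningful = beats_swc()
    elif cfg.method == "te":
        meaningful = beats_te()
    else:
        meaningful = beats_swc() and beats_te()
    return ChangeFlag(
        date=date,
        method=cfg.method,
        delta=delta,
        delta_pct=delta_pct,
        z=None,
        change_class=_direction(delta, meaningful),
        meaningful=meaningful,
    )


def flag_zscore(
    series: pd.Series,
    date: dt.date,
    cfg: MethodConfig,
    mode: str = "retrospective",
) -> ChangeFlag:
    """Within-athlete distributional (Z-score) verdict at ``date``.

    retrospective
        z is computed against the mean/SD of the *entire* series — the
        after-the-fact analysis once data collection is complete.
    rolling
        z uses only the values observed up to (and, by default, including)
        ``date`` — the data actually available at that point in time.
        Below ``cfg.min_n_rolling`` observations the verdict is trivial
        with no z value, since a small-n SD is unstable.
    """
    if mode not in ("retrospective", "rolling"):
        raise ValueError(f"unknown mode {mode!r}")
    ts = pd.Timestamp(date)
    if ts not in series.index:
        raise ValueError(f"no observation at {date}")
    value = float(series.loc[ts])

    if mode == "retrospective":
        ref = series.dropna()
    else:
        ref = series.loc[: ts].dropna()
        if not cfg.rolling_includes_current:
            ref = ref.drop(ts, errors="ignore")
        if len(ref) < cfg.min_n_rolling:
            return ChangeFlag(
                date=date,
                method="z_rolling",
                delta=float("nan"),
                delta_pct=None,
                z=None,
                change_class=ChangeClass.TRIVIAL,
                meaningful=False,
            )
    mean = float(ref.mean())
    sd = float(ref.std(ddof=1))
    if sd == 0.0:
        raise ValueError("z-score undefined: reference SD is 0")
    z = (value - mean) / sd
    meaningful = abs(z) > cfg.z_threshold
    return ChangeFlag(
        date=date,
        method=f"z_{mode}",
        delta=value - mean,
        delta_pct=None,
        z=z,
        change_class=_direction(value - mean, meaningful),
        meaningful=meaningful,
    )


def trend_slope(
    series: pd.Series,
    window: tuple[dt.date, dt.date] | None = None,
    swc_band: float = 0.0,
) -> TrendResult:
    """OLS slope of value on time, in channel units per week.

    The sign class compares the total modelled change over the window
    (``|slope| x window length``) against ``swc_band`` (channel units):
    below the band the trend is trivial.
    """
    if window is not None:
        start, end = window
        series = series.loc[pd.Timestamp(start) : pd.Timestamp(end)]
    series = series.dropna()
    if len(series) < 3:
        raise ValueError("trend needs at least 3 points")
    t_weeks = (series.index - series.index[0]).days.to_numpy(dtype=float) / 7.0
    if np.ptp(t_weeks) == 0:
        raise ValueError("zero time variance")
    y = series.to_numpy(dtype=float)
    tc = t_weeks - t_weeks.mean()
    slope = float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))
    span_weeks = float(np.ptp(t_weeks))
    total = abs(slope) * span_weeks
    meaningful = total > swc_band
    return TrendResult(
        slope_per_week=slope, change_class=_direction(slope, meaningful)
    )


def compare_methods(
    series: pd.Series,
    baseline_window: tuple[dt.date, dt.date],
    cfgs: Sequence[MethodConfig],
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Flag every date with every method and measure pairwise agreement.

    Returns a (date x method) DataFrame of :class:`ChangeFlag` objects and,
    for every method pair, the fraction of dates with identical
    (meaningful, direction) verdicts — the quantitative face of the
    disagreement between analysis concepts.
    """
    if len(cfgs) < 2:
        raise ValueError("need at least 2 method configurations")
    stats = baseline_stats(series, baseline_window)
    cols: dict[str, list[ChangeFlag]] = {}
    names: list[str] = []
    for i, cfg in enumerate(cfgs):
        name = cfg.method if cfg.method not in names else f"{cfg.method}#{i}"
        names.append(name)
        flags: list[ChangeFlag] = []
        for ts in series.index:
            d = ts.date()
            if cfg.method in THRESHOLD_METHODS:
                flags.append(
                    flag_threshold(float(series.loc[ts]), stats, cfg, date=d)
                )
            else:
                mode = "retrospective" if cfg.method == "z_retrospective" else "rolling"
                flags.append(flag_zscore(series, d, cfg, mode=mode))
        cols[name] = flags
    matrix = pd.DataFrame(cols, index=series.index)
    agreement: dict[tuple[str, str], float] = {}
    for a, b in combinations(names, 2):
        same = [
            fa.meaningful == fb.meaningful and fa.change_class == fb.change_class
            for fa, fb in zip(matrix[a], matrix[b])
        ]
        agreement[(a, b)] = float(np.mean(same))
    return matrix, agreement
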