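"""Resting HR/HRV metrics from R-R interval series.

The workhorse vagal index is rMSSD (root mean square of successive R-R
differences) and its natural logarithm, Ln rMSSD — the time-domain measure
of choice for day-to-day field monitoring because it is more reliable and
less breathing-dependent than spectral indices.  Because HRV shrinks again
at very low resting heart rates (parasympathetic "saturation" at the
acetylcholine-receptor level), Ln rMSSD is also normalized by the
prevailing R-R interval; a concurrent drop in HR, HRV and the HRV/R-R
ratio flags saturation rather than vagal withdrawal.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass

import numpy as np

from .core import ChangeClass, RRSeries

__all__ = [
    "RestingSummary",
    "clean_rr",
    "rmssd",
    "ln_rmssd",
    "lnrmssd_rr_ratio",
    "classify_saturation",
    "resting_summary",
]

#: Default relative artifact threshold: an interval deviating by more than
#: this fraction from the median of its accepted neighbours is rejected.
DEFAULT_ARTIFACT_THRESHOLD = 0.3

#: Number of accepted neighbouring intervals whose median anchors the filter.
_NEIGHBOURS = 5


@dataclass(frozen=True)
class RestingSummary:
    """Summary metrics of one resting R-R recording."""

    mean_rr: float  # ms
    mean_hr: float  # bpm; always 60000 / mean_rr
    rmssd: float  # ms
    ln_rmssd: float | None  # log-ms; None when rmssd == 0
    lnrmssd_rr_ratio: float | None  # log-ms per second of mean R-R
    n_beats: int
    artifact_fraction: float


def clean_rr(
    series: RRSeries, rel_threshold: float = DEFAULT_ARTIFACT_THRESHOLD
) -> tuple[RRSeries, float]:
    """Remove artifactual intervals (missed/extra beats) from an R-R series.

    An interval is rejected when it deviates by more than ``rel_threshold``
    (a fraction, e.g. 0.3) from the median of its up-to-5 nearest *accepted*
    neighbours.  Rejection passes repeat until no interval moves, so the
    filter is idempotent: cleaning a cleaned series removes nothing.

    Returns the cleaned series and the fraction of intervals removed.
    """
    if not (0.0 < rel_threshold < 1.0):
        raise ValueError("rel_threshold must lie in (0, 1)")
    n = len(series)
    if n < 3:
        raise ValueError("need at least 3 intervals to artifact-filter")

    vals = list(series.intervals)
    accepted = list(range(n))
    while True:
        rejected: list[int] = []
        for pos, i in enumerate(accepted):
            neigh = _nearest(accepted, pos, _NEIGHBOURS)
            med = statistics.median(vals[j] for j in neigh)
            if abs(vals[i] - med) / med > rel_threshold:
                rejected.append(i)
        if not rejected:
            break
        accepted = [i for i in accepted if i not in set(rejected)]
        if len(accepted) < 2:
            break
    cleaned = RRSeries(
        [vals[i] for i in accepted],
        start_time=series.start_time,
        position=series.position,
        context=series.context,
    )
    return cleaned, (n - len(accepted)) / n


def _nearest(accepted: list[int], pos: int, k: int) -> list[int]:
    """Indices of up to ``k`` accepted intervals nearest to ``accepted[pos]``."""
    out: list[int] = []
    lo, hi = pos - 1, pos + 1
    while len(out) < k and (lo >= 0 or hi < len(accepted)):
        if lo >= 0:
            out.append(accepted[lo])
            lo -= 1
        if len(out) < k and hi < len(accepted):
            out.append(accepted[hi])
            hi += 1
    return out


def rmssd(series: RRSeries) -> float:
    """Square root of the mean squared successive R-R differences, in ms."""
    if len(series) < 2:
        raise ValueError("rMSSD needs at least 2 intervals")
    x = np.asarray(series.intervals, dtype=float)
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def ln_rmssd(series: RRSeries) -> float:
    """Natural logarithm of rMSSD (log-ms).

    Undefined (raises) when rMSSD is exactly zero, i.e. a metronomically
    constant series.
    """
    r = rmssd(series)
    if r <= 0.0:
        raise ValueError("Ln rMSSD undefined: rMSSD is zero")
    return math.log(r)


def lnrmssd_rr_ratio(series: RRSeries) -> float:
    """Ln rMSSD normalized by the prevailing R-R interval.

    The denominator is the mean R-R expressed in *seconds*, which keeps the
    ratio on the same numeric scale as Ln rMSSD itself (a documented
    convention; any monotone-equivalent normalization would do).
    """
    ln = ln_rmssd(series)
    mean_rr_s = series.mean_rr / 1000.0
    if mean_rr_s <= 0:
        raise ValueError("mean R-R must be positive")
    return ln / mean_rr_s


def classify_saturation(
    trend_hr: ChangeClass,
    trend_lnrmssd: ChangeClass,
    trend_ratio: ChangeClass,
) -> str:
    """Distinguish parasympathetic saturation from true vagal withdrawal.

    Saturation is flagged only by the concurrent triple decrease of HR,
    Ln rMSSD and the Ln rMSSD/R-R ratio.  A fall in Ln rMSSD while HR is
    stable or rising is ordinary vagal withdrawal (``no_saturation``); any
    other pattern is ``indeterminate``.
    """
    trend_hr = ChangeClass(trend_hr)
    trend_lnrmssd = ChangeClass(trend_lnrmssd)
    trend_ratio = ChangeClass(trend_ratio)
    dec = ChangeClass.DECREASED
    if trend_hr is dec and trend_lnrmssd is dec and trend_ratio is dec:
        return "saturation"
    if trend_lnrmssd is dec and trend_hr in (ChangeClass.INCREASED, ChangeClass.TRIVIAL):
        return "no_saturation"
    return "indeterminate"


def resting_summary(
    series: RRSeries,
    rel_threshold: float = DEFAULT_ARTIFACT_THRESHOLD,
    clean: bool = True,
) -> RestingSummary:
    """Artifact-filter a recording and compute all resting metrics.

    Ultra-short recordings (~60 s) are accepted as-is; ``n_beats`` records
    how much data the summary rests on.
    """
    frac = 0.0
    if clean:
        series, frac = clean_rr(series, rel_threshold)
    mean_rr = series.mean_rr
    r = rmssd(series)
    ln = math.log(r) if r > 0 else None
    ratio = ln / (mean_rr / 1000.0) if ln is not None else None
    return RestingSummary(
        mean_rr=mean_rr,
        mean_hr=60000.0 / mean_rr,
        rmssd=r,
        ln_rmssd=ln,
        lnrmssd_rr_ratio=ratio,
        n_beats=len(series),
        artifact_fraction=frac,
    )
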