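"""Exercise and post-exercise HR metrics from submaximal test traces.

A standardized submaximal shuttle run (the default protocol: ~1, 1 and
3 min at 9.0, 10.5 and 12.0 km/h on a 28 m shuttle, then 1 min of passive
recovery) yields two longitudinal markers:

* **HRex** — exercise HR averaged over the final 30-60 s of the run, a
  fitness-oriented marker (lower at fixed external load = fitter).
* **HRR** — HR recovery, the drop from exercise cessation to a fixed delay
  (60 s), with short smoothing windows (5-15 s) at both anchor points to
  reduce measurement error.

Smoothing windows *end at* their anchor times (causality at cessation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import HRTrace

__all__ = [
    "ProtocolDef",
    "TestResult",
    "DEFAULT_PROTOCOL",
    "extract_hrex",
    "extract_hrr",
    "hr_zones",
    "evaluate_test",
]


@dataclass(frozen=True)
class ProtocolDef:
    """A graded submaximal run protocol: stages, recovery, shuttle length."""

    stages: tuple[tuple[float, float], ...]  # (duration_s, speed_kmh)
    recovery_s: float = 60.0
    shuttle_length_m: float = 28.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d, _ in self.stages):
            raise ValueError("stage durations must be positive")
        if self.recovery_s < 0:
            raise ValueError("recovery_s must be >= 0")

    @property
    def total_duration_s(self) -> float:
        return sum(d for d, _ in self.stages)


#: The shuttle-run protocol used throughout: 1 + 1 + 3 min at
#: 9.0 / 10.5 / 12.0 km/h, 28 m shuttles, 1 min passive recovery.
DEFAULT_PROTOCOL = ProtocolDef(
    stages=((60.0, 9.0), (60.0, 10.5), (180.0, 12.0)),
    recovery_s=60.0,
    shuttle_length_m=28.0,
)


@dataclass(frozen=True)
class TestResult:
    """Extracted markers of one submaximal test occasion."""

    hrex: float
    hrr60: float | None
    hr_at_cessation: float | None
    pct_hrmax: float | None = None
    quality_flags: tuple[str, ...] = field(default_factory=tuple)


def _window_mean(
    trace: HRTrace, start: float, end: float, closed: str = "right"
) -> tuple[float, int]:
    """Mean HR over a time window; returns (mean, n_samples)."""
    t = trace.times
    h = trace.hr
    if closed == "right":  # (start, end]
        mask = (t > start) & (t <= end)
    else:  # [start, end)
        mask = (t >= start) & (t < end)
    n = int(mask.sum())
    return (float(h[mask].mean()) if n else float("nan")), n


def extract_hrex(
    trace: HRTrace,
    protocol: ProtocolDef = DEFAULT_PROTOCOL,
    window_s: float = 60.0,
    min_coverage: float = 0.8,
) -> float:
    """Mean HR over the final ``window_s`` seconds of the last stage.

    The window is ``[cessation - window_s, cessation)``; at a nominal 1 Hz
    at least ``min_coverage`` (default 80%) of the expected samples must be
    present, otherwise the test occasion is rejected.
    """
    if not (30.0 <= window_s <= 60.0):
        raise ValueError("window_s must lie in [30, 60] s")
    cess = trace.cessation
    mean, n = _window_mean(trace, cess - window_s, cess, closed="left")
    if n < min_coverage * window_s:
        raise ValueError(
            f"insufficient coverage in HRex window: {n} samples over "
            f"{window_s:.0f} s (need >= {min_coverage:.0%})"
        )
    return mean


def extract_hrr(
    trace: HRTrace,
    delay_s: float = 60.0,
    smooth_s: float = 5.0,
) -> float:
    """HR recovery: smoothed HR at cessation minus smoothed HR ``delay_s`` later.

    Both anchor values are means over a ``smooth_s`` window (5-15 s) *ending*
    at the anchor; positive values mean the HR recovered.
    """
    if not (5.0 <= smooth_s <= 15.0):
        raise ValueError("smooth_s must lie in [5, 15] s")
    cess = trace.cessation
    if trace.times[-1] < cess + delay_s:
        raise ValueError(
            f"trace ends {trace.times[-1] - cess:.0f} s after cessation; "
            f"need >= {delay_s:.0f} s of recovery"
        )
    hr_cess, n0 = _window_mean(trace, cess - smooth_s, cess, closed="right")
    hr_post, n1 = _window_mean(
        trace, cess + delay_s - smooth_s, cess + delay_s, closed="right"
    )
    if n0 == 0 or n1 == 0:
        raise ValueError("no samples in an HRR smoothing window")
    return hr_cess - hr_post


def hr_zones(hr: float, hrmax: float) -> str:
    """10 %-wide %HRmax zone label for an HR value.

    Zones are lower-closed half-open bands from 50 %HRmax upward
    ([50-60), ..., [90-100] with the top zone closed), so every percentage
    in (0, 100] maps to exactly one label; ``"below"``/``"above"`` catch the
    remainder.
    """
    if hrmax <= 0:
        raise ValueError("hrmax must be positive")
    pct = hr / hrmax * 100.0
    if pct < 50.0:
        return "below"
    if pct > 100.0:
        return "above"
    if pct == 100.0:
        return "90-100%"
    lo = 10 * int(pct // 10)
    return f"{lo}-{lo + 10}%"


def evaluate_test(
    trace: HRTrace,
    protocol: ProtocolDef = DEFAULT_PROTOCOL,
    hrmax: float | None = None,
    window_s: float = 60.0,
    smooth_s: float = 5.0,
) -> TestResult:
    """Extract HRex (and HRR when the recovery period was recorded)."""
    flags: list[str] = []
    hrex = extract_hrex(trace, protocol, window_s=window_s)
    hrr = hr_cess = None
    try:
        cess = trace.cessation
        hr_cess, _ = _window_mean(trace, cess - smooth_s, cess, closed="right")
        hrr = extract_hrr(trace, delay_s=protocol.recovery_s, smooth_s=smooth_s)
    except ValueError as exc:
        flags.append(f"no_hrr: {exc}")
    pct = None
    if hrmax is not None:
        pct = hrex / hrmax * 100.0
        if not (0.0 < pct <= 120.0):
            raise ValueError(f"pct_hrmax {pct:.1f} outside (0, 120]")
    return TestResult(
        hrex=hrex,
        hrr60=hrr,
        hr_at_cessation=hr_cess,
        pct_hrmax=pct,
        quality_flags=tuple(flags),
    )
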