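"""File formats: monitoring CSV, R-R text, HR-trace CSV, YAML run config.

All readers are strict and fail with the offending line number — silent
coercion of malformed monitoring data would defeat the point of
longitudinal comparison.  All writers produce files the corresponding
reader round-trips exactly (up to float formatting).
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from pathlib import Path

import pydantic
import yaml

from .core import (
    CESSATION_MARKER,
    AthleteLog,
    Channel,
    DailyRecord,
    HRTrace,
    Phase,
    PhaseCalendar,
    RRSeries,
)

__all__ = [
    "read_monitoring_csv",
    "write_monitoring_csv",
    "read_rr_txt",
    "write_rr_txt",
    "read_trace_csv",
    "write_trace_csv",
    "read_phase_calendar",
    "write_phase_calendar",
    "RunConfig",
    "load_config",
    "save_config",
]

_MONITOR_COLS = ["date", "athlete_id", "channel", "value"]


def _parse_date(text: str, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text.strip())
    except ValueError as exc:
        raise ValueError(f"{where}: bad date {text!r} (want YYYY-MM-DD)") from exc


def _parse_float(text: str, where: str) -> float:
    try:
        v = float(text)
    except ValueError as exc:
        raise ValueError(f"{where}: bad number {text!r}") from exc
    if not math.isfinite(v):
        raise ValueError(f"{where}: non-finite value {text!r}")
    return v


def read_monitoring_csv(path: str | Path, calendar: PhaseCalendar | None = None) -> AthleteLog:
    """Read a long-format monitoring CSV (date, athlete_id, channel, value).

    Every malformed cell is reported with its file line number; a file with
    a header but no data rows is an error ("no records"), because an empty
    log is far more likely a pipeline failure than a real empty season.
    """
    path = Path(path)
    records: list[DailyRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _MONITOR_COLS:
            raise ValueError(
                f"{path}: header must be {','.join(_MONITOR_COLS)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            where = f"{path}:{reader.line_num}"
            if any(row.get(c) in (None, "") for c in _MONITOR_COLS):
                raise ValueError(f"{where}: missing field(s)")
            date = _parse_date(row["date"], where)
            value = _parse_float(row["value"], where)
            try:
                channel = Channel(row["channel"].strip())
            except ValueError:
                raise ValueError(
                    f"{where}: unknown channel {row['channel']!r} "
                    f"(known: {', '.join(c.value for c in Channel)})"
                ) from None
            if channel is Channel.RPE and not (0.0 <= value <= 10.0):
                raise ValueError(f"{where}: RPE {value} outside the 0-10 scale")
            records.append(DailyRecord(date, row["athlete_id"].strip(), channel, value))
    if not records:
        raise ValueError(f"{path}: no records")
    return AthleteLog(records, calendar=calendar)


def write_monitoring_csv(log: AthleteLog, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MONITOR_COLS)
        for r in log.records:
            writer.writerow(
                [r.date.isoformat(), r.athlete_id, r.channel.value, repr(r.value)]
            )


def read_rr_txt(path: str | Path, **kwargs) -> RRSeries:
    """One R-R interval (ms) per line; blank lines and ``#`` comments skipped."""
    path = Path(path)
    intervals: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        v = _parse_float(text, f"{path}:{lineno}")
        if v <= 0:
            raise ValueError(f"{path}:{lineno}: R-R interval must be positive")
        intervals.append(v)
    if not intervals:
        raise ValueError(f"{path}: no intervals")
    return RRSeries(intervals, **kwargs)


def write_rr_txt(series: RRSeries, path: str | Path) -> None:
    Path(path).write_text("".join(f"{v!r}\n" for v in series.intervals))


def read_trace_csv(path: str | Path) -> HRTrace:
    """Per-second HR trace CSV: ``time_s,hr`` rows.

    Markers (e.g. exercise cessation) are carried as comment lines of the
    form ``# marker <name> <time_s>`` before the header.
    """
    path = Path(path)
    markers: dict[str, float] = {}
    samples: list[tuple[float, float]] = []
    header_seen = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        text = line.strip()
        where = f"{path}:{lineno}"
        if not text:
            continue
        if text.startswith("#"):
            parts = text[1:].split()
            if parts and parts[0] == "marker":
                if len(parts) != 3:
                    raise ValueError(f"{where}: marker lines are '# marker <name> <time_s>'")
                markers[parts[1]] = _parse_float(parts[2], where)
            continue
        if not header_seen:
            if [c.strip() for c in text.split(",")] != ["time_s", "hr"]:
                raise ValueError(f"{where}: header must be time_s,hr")
            header_seen = True
            continue
        cells = text.split(",")
        if len(cells) != 2:
            raise ValueError(f"{where}: expected 2 columns")
        samples.append(
            (_parse_float(cells[0], where), _parse_float(cells[1], where))
        )
    if not samples:
        raise ValueError(f"{path}: no samples")
    return HRTrace(samples, markers)


def write_trace_csv(trace: HRTrace, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# marker {k} {v!r}" for k, v in sorted(trace.markers.items())]
    lines.append("time_s,hr")
    lines += [f"{t!r},{h!r}" for t, h in trace.samples]
    path.write_text("\n".join(lines) + "\n")


def read_phase_calendar(path: str | Path) -> PhaseCalendar:
    """Phase calendar CSV: ``start,end,phase`` inclusive ranges.

    Rows whose phase is ``game`` mark match days (start must equal end).
    """
    path = Path(path)
    phases: list[tuple[dt.date, dt.date, Phase]] = []
    games: list[dt.date] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != [
            "start",
            "end",
            "phase",
        ]:
            raise ValueError(f"{path}: header must be start,end,phase")
        for row in reader:
            where = f"{path}:{reader.line_num}"
            start = _parse_date(row["start"], where)
            end = _parse_date(row["end"], where)
            label = row["phase"].strip()
            if label == "game":
                if start != end:
                    raise ValueError(f"{where}: game rows must have start == end")
                games.append(start)
                continue
            try:
                phases.append((start, end, Phase(label)))
            except ValueError:
                raise ValueError(
                    f"{where}: unknown phase {label!r} "
                    f"(known: game, {', '.join(p.value for p in Phase)})"
                ) from None
    return PhaseCalendar(phases, games)


def write_phase_calendar(calendar: PhaseCalendar, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start", "end", "phase"])
        for s, e, p in calendar.phases:
            writer.writerow([s.isoformat(), e.isoformat(), p.value])
        for g in sorted(calendar.game_days):
            writer.writerow([g.isoformat(), g.isoformat(), "game"])


class RunConfig(pydantic.BaseModel):
    """Validated run configuration (YAML-serializable).

    Unknown keys are rejected (a typo in a config must fail loudly, not
    silently fall back to a default).
    """

    model_config = pydantic.ConfigDict(extra="forbid")

    template: str = "microcycle_4_2"
    n_weeks: int = pydantic.Field(default=12, ge=1)
    seed: int = 0
    noise_cv: float | None = pydantic.Field(default=None, ge=0)
    rpe_noise_sd: float | None = pydantic.Field(default=None, ge=0)
    f_init: float | None = None
    hrex_swc_pct: float = pydantic.Field(default=1.0, gt=0)
    rpe_delta: float = pydantic.Field(default=1.0, gt=0)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    try:
        return RunConfig(**raw)
    except pydantic.ValidationError as exc:
        raise ValueError(f"{path}: invalid config:\n{exc}") from None


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
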