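"""Simplified Mobility Score (SMoS) computation.

The SMoS is a composite 0-100 mobility score built from two objective gait
metrics with equal weight:

* walking speed (WS), in m/s, scored linearly up to a cap of 1.35 m/s — the
  speed associated with complete functional independence — worth up to 50
  points;
* daily step count (DSC), in steps/day, scored linearly up to a cap of
  10,000 steps/day — the conventional "active individual" threshold — worth
  up to 50 points.

Each component is ``50 * min(value / cap, 1)`` and the total is their sum,
so 0 means nil mobility and 100 excellent mobility. This module also derives
walking speed from a timed walk and aggregates a dated step time series into
a mean daily step count.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from datetime import date

from .errors import (
    InvalidMeasurementError,
    InvalidWalkError,
    LowCoverageWarning,
    MissingMetricError,
    NoDataError,
    NonStandardDistanceWarning,
)

#: Walking-speed cap in m/s; at or above it the WS component scores 50 points.
WS_CAP_MPS = 1.35
#: Daily-step-count cap; at or above it the DSC component scores 50 points.
DSC_CAP_STEPS = 10_000.0
#: Maximum points per component.
COMPONENT_MAX = 50.0
#: Standard timed-walk course lengths in metres.
STANDARD_WALK_DISTANCES_M = (30.0, 60.0, 120.0, 200.0)
#: Default aggregation window for the step time series ("last month").
DEFAULT_WINDOW_DAYS = 30
#: Fewer tracked days than this in the window triggers a low-coverage flag.
DEFAULT_MIN_COVERAGE_DAYS = 7


def _require_valid(value: float | None, name: str) -> float:
    if value is None:
        raise MissingMetricError(f"{name} is missing")
    value = float(value)
    if not math.isfinite(value):
        raise InvalidMeasurementError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise InvalidMeasurementError(f"{name} must be non-negative, got {value!r}")
    return value


@dataclass(frozen=True)
class GaitMeasurement:
    """One patient's raw gait metrics.

    Either field may be ``None`` (missing); :func:`compute_smos` requires
    both. Present values must be finite and non-negative.
    """

    walking_speed: float | None = None  # m/s
    daily_step_count: float | None = None  # steps/day, fractional allowed

    def __post_init__(self) -> None:
        if self.walking_speed is not None:
            _require_valid(self.walking_speed, "walking_speed")
        if self.daily_step_count is not None:
            _require_valid(self.daily_step_count, "daily_step_count")


@dataclass(frozen=True)
class TimedWalk:
    """A single timed walk over a measured course."""

    distance_m: float
    duration_s: float

    def __post_init__(self) -> None:
        for name, value in (("distance_m", self.distance_m), ("duration_s", self.duration_s)):
            if not math.isfinite(value) or value <= 0:
                raise InvalidWalkError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class SMoSResult:
    """Component points and total score; ``total == ws_points + dsc_points``."""

    ws_points: float
    dsc_points: float
    total: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ws_points <= COMPONENT_MAX):
            raise ValueError(f"ws_points out of [0, 50]: {self.ws_points}")
        if not (0.0 <= self.dsc_points <= COMPONENT_MAX):
            raise ValueError(f"dsc_points out of [0, 50]: {self.dsc_points}")
        if self.total != self.ws_points + self.dsc_points:
            raise ValueError("total must equal ws_points + dsc_points exactly")


@dataclass(frozen=True)
class StepTimeseries:
    """Dated daily step totals with strictly increasing dates."""

    entries: tuple[tuple[date, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        prev: date | None = None
        for d, steps in self.entries:
            if prev is not None and d <= prev:
                raise ValueError(f"dates must be strictly increasing (at {d})")
            prev = d
            if not math.isfinite(steps) or steps < 0:
                raise ValueError(f"step total on {d} must be non-negative and finite")

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_csv(cls, path) -> "StepTimeseries":
        """Read a two-column CSV with header ``date,steps`` (ISO dates)."""
        rows: list[tuple[date, float]] = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"date", "steps"} <= set(reader.fieldnames):
                raise NoDataError(f"{path}: expected header with 'date' and 'steps' columns")
            for row in reader:
                rows.append((date.fromisoformat(row["date"].strip()), float(row["steps"])))
        return cls(entries=tuple(rows))


@dataclass(frozen=True)
class MeanStepsResult:
    """Mean daily steps over the aggregation window."""

    mean: float
    days_used: int
    low_coverage: bool = False

    def __float__(self) -> float:
        return self.mean


def score_walking_speed(v: float | None, *, cap: float = WS_CAP_MPS) -> float:
    """WS component points: ``50 * min(v / cap, 1)``, continuous and non-decreasing."""
    v = _require_valid(v, "walking_speed")
    return COMPONENT_MAX * min(v / cap, 1.0)


def score_daily_step_count(dsc: float | None, *, cap: float = DSC_CAP_STEPS) -> float:
    """DSC component points: ``50 * min(dsc / cap, 1)``, continuous and non-decreasing."""
    dsc = _require_valid(dsc, "daily_step_count")
    return COMPONENT_MAX * min(dsc / cap, 1.0)


def compute_smos(
    m: GaitMeasurement,
    *,
    ws_cap: float = WS_CAP_MPS,
    dsc_cap: float = DSC_CAP_STEPS,
) -> SMoSResult:
    """Total SMoS for one patient.

    Both metrics must be present; a patient with only one metric gets no
    score (the component scorers remain callable individually, but a partial
    total is never emitted as an SMoS).
    """
    if m.walking_speed is None:
        raise MissingMetricError("cannot compute SMoS: walking_speed is missing")
    if m.daily_step_count is None:
        raise MissingMetricError("cannot compute SMoS: daily_step_count is missing")
    ws = score_walking_speed(m.walking_speed, cap=ws_cap)
    dsc = score_daily_step_count(m.daily_step_count, cap=dsc_cap)
    return SMoSResult(ws_points=ws, dsc_points=dsc, total=ws + dsc)


def walking_speed_from_timed_walk(walk: TimedWalk) -> float:
    """Walking speed in m/s from a timed walk (distance / duration).

    Warns (``NonStandardDistanceWarning``) when the course length is not one
    of the standard self-selected distances (30, 60, 120, 200 m).
    """
    if not any(math.isclose(walk.distance_m, d) for d in STANDARD_WALK_DISTANCES_M):
        warnings.warn(
            f"timed-walk distance {walk.distance_m} m is not a standard course "
            f"length {STANDARD_WALK_DISTANCES_M}",
            NonStandardDistanceWarning,
            stacklevel=2,
        )
    return walk.distance_m / walk.duration_s


def mean_daily_steps(
    ts: StepTimeseries,
    window_days: int = DEFAULT_WINDOW_DAYS,
    *,
    min_coverage_days: int = DEFAULT_MIN_COVERAGE_DAYS,
) -> MeanStepsResult:
    """Mean daily step count over the most recent ``window_days`` tracked days.

    The window is the last ``window_days`` *dated entries*: days with no
    entry are excluded rather than imputed as zero, since non-wear days say
    nothing about activity. A result covering fewer than
    ``min_coverage_days`` days is flagged (and warned) as low coverage.
    """
    if window_days < 1:
        raise ValueError(f"window_days must be >= 1, got {window_days}")
    if len(ts) == 0:
        raise NoDataError("step time series is empty")
    window = ts.entries[-window_days:]
    days_used = len(window)
    mean = sum(steps for _, steps in window) / days_used
    low = days_used < min_coverage_days
    if low:
        warnings.warn(
            f"only {days_used} tracked day(s) in window (minimum {min_coverage_days})",
            LowCoverageWarning,
            stacklevel=2,
        )
    return MeanStepsResult(mean=mean, days_used=days_used, low_coverage=low)
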