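"""Domain types, file readers/writers and configuration.

Conventions
-----------
* Time is stored in seconds as floating point.  CSV input may carry
  milliseconds; readers accept a ``time_unit`` argument to convert.
* The pitch-rate sign convention is: positive = shank rotating in the
  direction of forward progression (swing).  With the default
  ``event_polarity="negative"`` the toe-off (TO) and initial-contact (IC)
  events are negative troughs and mid-swing (MSW) is the positive peak
  during forward locomotion.
* All intervals are half-open ``[start, end)`` when assigning samples to
  track segments, so no sample is counted twice at a boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GyroSeries",
    "AthleteConfig",
    "DetectorConfig",
    "StepRecord",
    "TrackSegment",
    "SessionResult",
    "read_gyro_csv",
    "write_gyro_csv",
    "write_steps_csv",
    "read_steps_csv",
    "build_default_circuit",
    "load_athlete_config",
    "load_detector_config",
]

#: floating point format that round-trips IEEE doubles through text
_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GyroSeries:
    """A time-stamped shank pitch angular-velocity stream.

    Parameters
    ----------
    timestamps
        Sample times in seconds, strictly increasing.
    pitch_rate
        Angular velocity about the sagittal-plane pitch axis, rad/s.
    sample_rate_nominal
        Nominal sampling frequency in Hz (default 200).
    rates_xyz
        Optional ``(n, 3)`` array with the full three-axis rates.
    warnings
        Accumulated data-quality messages (dropped rows, jitter, ...).
    """

    timestamps: np.ndarray
    pitch_rate: np.ndarray
    sample_rate_nominal: float = 200.0
    rates_xyz: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.pitch_rate = np.asarray(self.pitch_rate, dtype=float)
        if self.timestamps.shape != self.pitch_rate.shape:
            raise ValueError("timestamps and pitch_rate must have equal length")
        if not np.all(np.isfinite(self.timestamps)):
            raise ValueError("non-finite timestamps")
        if not np.all(np.isfinite(self.pitch_rate)):
            raise ValueError("non-finite pitch_rate values")
        if self.timestamps.size >= 2:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0))
                raise ValueError(
                    f"timestamps not strictly increasing at index {bad + 1}"
                )
            med = float(np.median(dt))
            nominal = 1.0 / self.sample_rate_nominal
            if abs(med - nominal) > 0.20 * nominal:
                self.warnings.append(
                    f"median sampling interval {med:.6g}s deviates more than "
                    f"20% from nominal {nominal:.6g}s"
                )

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def require_processable(self) -> None:
        """Raise unless the series may enter a processing operation."""
        if len(self) < 2:
            raise ValueError("series must contain at least 2 samples")


@dataclass(frozen=True)
class AthleteConfig:
    """Per-athlete configuration: identifier and leg length (metres)."""

    athlete_id: str
    leg_length: float

    def __post_init__(self) -> None:
        if not (0.2 < self.leg_length < 1.5):
            raise ValueError(
                f"leg_length must lie in (0.2, 1.5) m, got {self.leg_length}"
            )


@dataclass(frozen=True)
class DetectorConfig:
    """All step-detector thresholds and filter settings.

    ``magnitude_threshold`` (rad/s) gates the TO and IC extrema,
    ``refractory`` (s) is the post-step lockout before a new TO search,
    and the flight-time window bounds ``t_IC - t_TO``.
    """

    magnitude_threshold: float = 1.0
    refractory: float = 0.250
    flight_time_min: float = 0.080
    flight_time_max: float = 1.500
    event_polarity: str = "negative"  # TO/IC troughs negative, MSW positive
    hysteresis: float = 0.1
    filter_order: int = 2
    filter_cutoff: float = 5.0
    integration: str = "rectangular"  # or "trapezoid"

    def __post_init__(self) -> None:
        if self.magnitude_threshold <= 0:
            raise ValueError("magnitude_threshold must be > 0")
        if not (0 < self.flight_time_min < self.flight_time_max):
            raise ValueError("need 0 < flight_time_min < flight_time_max")
        if self.refractory <= 0:
            raise ValueError("refractory must be > 0")
        if self.event_polarity not in ("negative", "positive"):
            raise ValueError("event_polarity must be 'negative' or 'positive'")
        if self.hysteresis < 0:
            raise ValueError("hysteresis must be >= 0")
        if self.integration not in ("rectangular", "trapezoid"):
            raise ValueError("integration must be 'rectangular' or 'trapezoid'")

    @property
    def event_sign(self) -> int:
        """Sign of the TO/IC extrema during forward locomotion."""
        return -1 if self.event_polarity == "negative" else +1


@dataclass(frozen=True)
class StepRecord:
    """One detected step.

    ``theta`` is the signed net angular displacement (rad) selected between
    the positive and negative accumulations over the TO->IC window;
    ``distance`` is the chord-model metric distance (m).
    """

    t_TO: float
    t_MSW: float
    t_IC: float
    theta: float
    distance: float
    direction: str  # "forward" | "backward"

    def __post_init__(self) -> None:
        if not (self.t_TO < self.t_MSW < self.t_IC):
            raise ValueError("step events must satisfy t_TO < t_MSW < t_IC")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")

    @property
    def flight_time(self) -> float:
        return self.t_IC - self.t_TO


@dataclass(frozen=True)
class TrackSegment:
    """One labelled segment of the test circuit."""

    pace: str
    reference_distance: float
    time_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.pace not in PACES:
            raise ValueError(f"unknown pace {self.pace!r}; expected one of {PACES}")
        if self.reference_distance <= 0:
            raise ValueError("reference_distance must be positive")

    def contains(self, t: float) -> bool:
        """Half-open membership test [start, end)."""
        if self.time_window is None:
            return False
        return self.time_window[0] <= t < self.time_window[1]


PACES = ("walking", "jogging", "sprinting", "run_CoD", "ball_dribbling", "backward")


@dataclass
class SegmentTotals:
    segment: TrackSegment
    lap: int
    step_count: int
    distance: float


@dataclass
class SessionResult:
    """Batch detection output: all steps plus per-segment totals."""

    steps: list[StepRecord]
    per_segment: list[SegmentTotals] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def total_steps(self) -> int:
        return len(self.steps)

    @property
    def total_distance(self) -> float:
        return float(sum(s.distance for s in self.steps))


# ---------------------------------------------------------------------------
# the default test circuit
# ---------------------------------------------------------------------------

#: (pace, reference distance in metres) in circuit order
_DEFAULT_CIRCUIT = (
    ("jogging", 25.0),
    ("run_CoD", 42.3),
    ("backward", 16.0),
    ("ball_dribbling", 42.3),
    ("walking", 26.0),
    ("sprinting", 50.0),
)


def build_default_circuit() -> list[TrackSegment]:
    """Return the six-segment default circuit (total 201.6 m)."""
    return [TrackSegment(pace=p, reference_distance=d) for p, d in _DEFAULT_CIRCUIT]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_gyro_csv(
    path: str | Path,
    sample_rate_nominal: float = 200.0,
    time_unit: str = "s",
) -> GyroSeries:
    """Read a gyro CSV with columns ``t,gyro_pitch[,gx,gy,gz]``.

    Rows containing non-finite values are dropped; their (0-based data)
    row numbers are reported in ``GyroSeries.warnings``.
    """
    if time_unit not in ("s", "ms"):
        raise ValueError("time_unit must be 's' or 'ms'")
    df = pd.read_csv(path)
    missing = {"t", "gyro_pitch"} - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    cols = ["t", "gyro_pitch"]
    has_xyz = {"gx", "gy", "gz"} <= set(df.columns)
    if has_xyz:
        cols += ["gx", "gy", "gz"]
    data = df[cols].to_numpy(dtype=float)
    finite = np.all(np.isfinite(data), axis=1)
    warnings: list[str] = []
    if not np.all(finite):
        dropped = np.flatnonzero(~finite)
        warnings.append(
            f"dropped {dropped.size} row(s) with non-finite values: "
            f"{dropped.tolist()}"
        )
        data = data[finite]
    if data.shape[0] < 2:
        raise ValueError("gyro CSV must contain at least 2 valid rows")
    t = data[:, 0] * (1e-3 if time_unit == "ms" else 1.0)
    series = GyroSeries(
        timestamps=t,
        pitch_rate=data[:, 1],
        sample_rate_nominal=sample_rate_nominal,
        rates_xyz=data[:, 2:5] if has_xyz else None,
    )
    series.warnings = warnings + series.warnings
    return series


def write_gyro_csv(series: GyroSeries, path: str | Path) -> None:
    """Write a GyroSeries back to the ``t,gyro_pitch[,gx,gy,gz]`` schema."""
    frame = {"t": series.timestamps, "gyro_pitch": series.pitch_rate}
    if series.rates_xyz is not None:
        frame["gx"] = series.rates_xyz[:, 0]
        frame["gy"] = series.rates_xyz[:, 1]
        frame["gz"] = series.rates_xyz[:, 2]
    pd.DataFrame(frame).to_csv(path, index=False, float_format=_FLOAT_FMT)


_STEP_COLUMNS = ["t_to", "t_msw", "t_ic", "theta_rad", "distance_m", "direction"]


def write_steps_csv(steps: Sequence[StepRecord], path: str | Path) -> None:
    """Write one row per step; numeric columns round-trip to 1e-9."""
    rows = [
        (s.t_TO, s.t_MSW, s.t_IC, s.theta, s.distance, s.direction) for s in steps
    ]
    pd.DataFrame(rows, columns=_STEP_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_steps_csv(path: str | Path) -> list[StepRecord]:
    df = pd.read_csv(path)
    missing = set(_STEP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing step columns: {sorted(missing)}")
    return [
        StepRecord(
            t_TO=float(r.t_to),
            t_MSW=float(r.t_msw),
            t_IC=float(r.t_ic),
            theta=float(r.theta_rad),
            distance=float(r.distance_m),
            direction=str(r.direction),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# JSON configuration
# ---------------------------------------------------------------------------

def _load_json_strict(path: str | Path, allowed: Iterable[str], kind: str) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{kind} config must be a JSON object")
    unknown = set(doc) - set(allowed)
    if unknown:
        raise ValueError(f"unknown {kind} config keys: {sorted(unknown)}")
    return doc


def load_athlete_config(path: str | Path) -> AthleteConfig:
    doc = _load_json_strict(path, ("athlete_id", "leg_length"), "athlete")
    try:
        return AthleteConfig(
            athlete_id=str(doc["athlete_id"]), leg_length=float(doc["leg_length"])
        )
    except KeyError as exc:
        raise ValueError(f"athlete config missing key {exc}") from exc


def load_detector_config(path: str | Path) -> DetectorConfig:
    names = [f.name for f in fields(DetectorConfig)]
    doc = _load_json_strict(path, names, "detector")
    return DetectorConfig(**doc)
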