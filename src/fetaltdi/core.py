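"""Shared domain types and readers/writers for trace tables and result files.

Conventions used throughout the package:

* Time is in seconds from trace start, samples are 0-based and uniformly
  spaced, so sample ``i`` sits at ``time_start + i / sampling_rate``.
* Velocity is in cm/s with the canonical polarity: positive during
  ventricular ejection (motion toward the apex/transducer), so the systolic
  peak is positive and the two diastolic peaks are negative.  An ``invert``
  flag on the analysis configuration accommodates the opposite probe
  orientation.
* A cardiac cycle starts at the onset of atrial contraction and is split
  into six half-open phases ``[onset, next onset)``; their durations sum to
  the cycle length exactly by construction.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "WALLS",
    "FAILURE_REASONS",
    "DEFAULT_PHASE_FRACTIONS",
    "TraceFormatError",
    "TooFewRowsError",
    "NonMonotoneTimeError",
    "NonUniformSamplingError",
    "ROISpec",
    "GestationalAgeGroup",
    "GA_I",
    "GA_II",
    "GA_III",
    "GA_GROUPS",
    "ga_group_for",
    "VelocityTrace",
    "AccelerationTrace",
    "PhaseSegmentation",
    "PeakVelocities",
    "IntervalSet",
    "AnalysisResult",
    "read_trace_table",
    "write_trace_table",
    "write_result",
    "read_result",
]

#: Ordered names of the six cardiac-cycle phases, cycle starts at atrial
#: contraction.
PHASES = (
    "atrial_contraction",
    "pre_ejection",
    "ejection",
    "post_ejection",
    "rapid_filling",
    "slow_filling",
)

WALLS = ("septum", "left_wall", "right_wall", "other")

FAILURE_REASONS = (
    "no_periodicity",
    "insufficient_shifts",
    "template_mismatch",
    "degenerate_input",
)

#: Default share of the cycle occupied by each phase (model convention, used
#: both by the synthetic generator and as template priors for event
#: assignment; configurable in both places).  The pre-/post-ejection phases
#: are kept wide enough (~13 ms at fetal rates) that their boundary events
#: stay resolvable at ~190 Hz after smoothing.
DEFAULT_PHASE_FRACTIONS = (0.15, 0.07, 0.33, 0.07, 0.23, 0.15)


class TraceFormatError(ValueError):
    """Base class for malformed trace-table input."""


class TooFewRowsError(TraceFormatError):
    """Trace table has fewer than two rows."""


class NonMonotoneTimeError(TraceFormatError):
    """Time column is not strictly increasing."""


class NonUniformSamplingError(TraceFormatError):
    """Timestamps deviate from a uniform grid beyond tolerance."""


@dataclass(frozen=True)
class ROISpec:
    """Region-of-interest geometry: ``height_mm`` runs along the wall (the
    spatially averaged direction), ``width_mm`` runs across the wall and is
    metadata only for the 1-D velocity field.  ``center_offset_mm`` is the
    distance of the ROI center below the AV-plane."""

    height_mm: float
    width_mm: float
    center_offset_mm: float

    def __post_init__(self) -> None:
        if not (self.height_mm > 0):
            raise ValueError("ROI height must be > 0")
        if not (self.width_mm > 0):
            raise ValueError("ROI width must be > 0")
        if self.center_offset_mm < self.height_mm / 2 - 1e-12:
            raise ValueError(
                "ROI must lie fully below the AV-plane "
                "(center_offset_mm >= height_mm / 2)"
            )

    @classmethod
    def at_av_plane(cls, height_mm: float, width_mm: float) -> "ROISpec":
        """ROI whose top edge sits exactly at the AV-plane."""
        return cls(height_mm, width_mm, height_mm / 2.0)


@dataclass(frozen=True)
class GestationalAgeGroup:
    name: str
    week_range: tuple[int, int]

    def __contains__(self, weeks: float) -> bool:
        lo, hi = self.week_range
        return lo <= weeks <= hi


GA_I = GestationalAgeGroup("GA_I", (18, 24))
GA_II = GestationalAgeGroup("GA_II", (25, 32))
GA_III = GestationalAgeGroup("GA_III", (33, 41))
GA_GROUPS = (GA_I, GA_II, GA_III)


def ga_group_for(weeks: float) -> GestationalAgeGroup:
    """Map gestational age in weeks to its group; boundaries are inclusive,
    the 24-25 and 32-33 gaps resolve to the younger group."""
    if weeks < 18 or weeks > 41:
        raise ValueError(f"gestational age {weeks} outside supported 18-41 weeks")
    for grp in GA_GROUPS:
        if weeks <= grp.week_range[1]:
            return grp
    raise AssertionError("unreachable")


def _as_sample_array(samples) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1:
        raise ValueError("samples must be 1-D")
    if arr.size < 2:
        raise ValueError("trace needs at least 2 samples")
    if not np.all(np.isfinite(arr)):
        raise ValueError("samples must all be finite")
    return arr


@dataclass(eq=False)
class VelocityTrace:
    """Uniformly sampled myocardial longitudinal velocity (cm/s) for one
    wall/ROI."""

    label: str
    sampling_rate: float
    samples: np.ndarray
    time_start: float = 0.0
    roi: Optional[ROISpec] = None

    def __post_init__(self) -> None:
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be > 0")
        self.samples = _as_sample_array(self.samples)

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.time_start + np.arange(self.n) / self.sampling_rate

    @property
    def duration(self) -> float:
        return (self.n - 1) / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "VelocityTrace":
        """Copy of this trace with new sample values on the same grid."""
        return replace(self, samples=np.asarray(samples, dtype=float))

    def index_at(self, time: float) -> int:
        """Nearest sample index for a time, clipped to the valid range."""
        i = int(round((time - self.time_start) * self.sampling_rate))
        return min(max(i, 0), self.n - 1)


@dataclass(eq=False)
class AccelerationTrace:
    """Myocardial acceleration (cm/s^2) on the same grid as its source
    velocity trace."""

    label: str
    sampling_rate: float
    samples: np.ndarray
    source_trace_label: str
    time_start: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be > 0")
        self.samples = _as_sample_array(self.samples)

    n = VelocityTrace.n
    dt = VelocityTrace.dt
    times = VelocityTrace.times
    duration = VelocityTrace.duration
    index_at = VelocityTrace.index_at


@dataclass(frozen=True)
class PhaseSegmentation:
    """Six ordered phase-onset times of one cardiac cycle.

    ``boundaries[k]`` is the onset of ``PHASES[k]``; ``cycle_end`` is the
    next atrial-contraction onset so the six half-open phase durations sum
    exactly to the cycle length.  ``shift_indices`` records the sample
    indices of the acceleration shifts that produced each boundary.
    """

    cycle_start: float
    boundaries: tuple[float, ...]
    cycle_end: float
    shift_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "shift_indices", tuple(int(i) for i in self.shift_indices))
        if len(b) != 6:
            raise ValueError("exactly six phase boundaries required")
        if b[0] != self.cycle_start:
            raise ValueError("boundaries[0] must equal cycle_start")
        if any(b[i + 1] <= b[i] for i in range(5)):
            raise ValueError("boundaries must be strictly increasing")
        if not (self.cycle_end > b[5]):
            raise ValueError("cycle_end must exceed the last boundary")

    @property
    def cycle_length(self) -> float:
        return self.cycle_end - self.cycle_start

    def durations_s(self) -> np.ndarray:
        """Per-phase durations in seconds; sums exactly to cycle_length."""
        edges = np.array(self.boundaries + (self.cycle_end,))
        return np.diff(edges)


@dataclass(frozen=True)
class PeakVelocities:
    """Peak myocardial velocities: systolic (sm, > 0 canonical), early
    diastolic (em, < 0) and atrial contraction (am, < 0), in cm/s."""

    sm: float
    em: float
    am: float


@dataclass(frozen=True)
class IntervalSet:
    """Per-phase durations in milliseconds, keyed by phase name."""

    durations_ms: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.durations_ms) != set(PHASES):
            raise ValueError("durations must be keyed by the six phase names")
        if any(v < 0 for v in self.durations_ms.values()):
            raise ValueError("durations must be non-negative")

    @property
    def total_ms(self) -> float:
        return float(sum(self.durations_ms.values()))


@dataclass
class AnalysisResult:
    """Per-trace outcome of the automated analysis."""

    trace_label: str
    success: bool
    failure_reason: Optional[str] = None
    segmentations: list[PhaseSegmentation] = field(default_factory=list)
    peak_velocities: Optional[PeakVelocities] = None
    intervals: Optional[IntervalSet] = None
    acceleration_score: int = 1
    filter_setting_used: Optional[int] = None

    def __post_init__(self) -> None:
        if self.failure_reason is not None and self.failure_reason not in FAILURE_REASONS:
            raise ValueError(f"unknown failure_reason {self.failure_reason!r}")
        if not self.success:
            if self.failure_reason is None:
                raise ValueError("failed results must carry a failure_reason")
            if self.segmentations:
                raise ValueError("failed results must have no segmentations")
        if self.acceleration_score not in (1, 2, 3):
            raise ValueError("acceleration_score must be 1, 2 or 3")


# ---------------------------------------------------------------------------
# Trace tables (delimited text: column 1 = time [s], others = velocity [cm/s])
# ---------------------------------------------------------------------------

#: Allowed deviation of a timestamp from the uniform grid, as a fraction of
#: one sampling step.
UNIFORMITY_TOLERANCE = 0.25


def read_trace_table(
    path: str | os.PathLike,
    delimiter: str = ",",
    decimal: str = ".",
) -> list[VelocityTrace]:
    """Read a delimited trace table into one :class:`VelocityTrace` per
    velocity column.

    The first column is time in seconds and must be strictly increasing on a
    uniform grid; the sampling rate is inferred from the median time step and
    rows deviating from the grid by more than 25 % of a step are rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"trace table not found: {path}")
    df = pd.read_csv(path, sep=delimiter, decimal=decimal)
    if df.shape[0] < 2:
        raise TooFewRowsError(f"trace table {path} has <2 rows")
    if df.shape[1] < 2:
        raise TraceFormatError(f"trace table {path} has no velocity column")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise NonMonotoneTimeError(f"time column in {path} is not strictly increasing")
    dt = float(np.median(np.diff(t)))
    grid = t[0] + np.arange(t.size) * dt
    dev = np.abs(t - grid)
    if np.any(dev > UNIFORMITY_TOLERANCE * dt):
        raise NonUniformSamplingError(
            f"timestamps in {path} deviate from uniform grid by "
            f"{dev.max() / dt:.2f} steps (> {UNIFORMITY_TOLERANCE})"
        )
    rate = 1.0 / dt
    traces = []
    for col in df.columns[1:]:
        traces.append(
            VelocityTrace(
                label=str(col),
                sampling_rate=rate,
                samples=df[col].to_numpy(dtype=float),
                time_start=float(t[0]),
            )
        )
    return traces


def write_trace_table(
    traces: Sequence[VelocityTrace],
    path: str | os.PathLike,
    delimiter: str = ",",
    decimal: str = ".",
) -> None:
    """Write traces sharing one time grid to a delimited text table."""
    if not traces:
        raise ValueError("no traces to write")
    ref = traces[0]
    for tr in traces[1:]:
        if (
            tr.n != ref.n
            or tr.sampling_rate != ref.sampling_rate
            or tr.time_start != ref.time_start
        ):
            raise ValueError("all traces in one table must share the time grid")
    data = {"time_s": ref.times}
    for tr in traces:
        data[tr.label] = tr.samples
    pd.DataFrame(data).to_csv(path, sep=delimiter, decimal=decimal, index=False)


# ---------------------------------------------------------------------------
# Result files (JSON)
# ---------------------------------------------------------------------------


def _seg_to_dict(seg: PhaseSegmentation) -> dict:
    return {
        "cycle_start": seg.cycle_start,
        "boundaries": list(seg.boundaries),
        "cycle_end": seg.cycle_end,
        "shift_indices": list(seg.shift_indices),
    }


def _seg_from_dict(d: dict) -> PhaseSegmentation:
    return PhaseSegmentation(
        cycle_start=float(d["cycle_start"]),
        boundaries=tuple(float(x) for x in d["boundaries"]),
        cycle_end=float(d["cycle_end"]),
        shift_indices=tuple(int(i) for i in d["shift_indices"]),
    )


def result_to_dict(result: AnalysisResult) -> dict:
    return {
        "trace_label": result.trace_label,
        "success": result.success,
        "failure_reason": result.failure_reason,
        "segmentations": [_seg_to_dict(s) for s in result.segmentations],
        "peak_velocities": (
            None
            if result.peak_velocities is None
            else {
                "sm": result.peak_velocities.sm,
                "em": result.peak_velocities.em,
                "am": result.peak_velocities.am,
            }
        ),
        "intervals_ms": (
            None if result.intervals is None else dict(result.intervals.durations_ms)
        ),
        "acceleration_score": result.acceleration_score,
        "filter_setting_used": result.filter_setting_used,
    }


def result_from_dict(d: dict) -> AnalysisResult:
    peaks = d.get("peak_velocities")
    intervals = d.get("intervals_ms")
    return AnalysisResult(
        trace_label=d["trace_label"],
        success=bool(d["success"]),
        failure_reason=d.get("failure_reason"),
        segmentations=[_seg_from_dict(s) for s in d.get("segmentations", [])],
        peak_velocities=None if peaks is None else PeakVelocities(**peaks),
        intervals=None if intervals is None else IntervalSet({k: float(v) for k, v in intervals.items()}),
        acceleration_score=int(d.get("acceleration_score", 1)),
        filter_setting_used=d.get("filter_setting_used"),
    )


def write_result(result: AnalysisResult, path: str | os.PathLike) -> None:
    """Serialize an :class:`AnalysisResult` to a JSON document.

    Floats are written with Python's shortest round-trip repr, which
    preserves them bit-exactly on read-back.
    """
    with open(path, "w") as fh:
        json.dump(result_to_dict(result), fh, indent=2)
        fh.write("\n")


def read_result(path: str | os.PathLike) -> AnalysisResult:
    with open(path) as fh:
        return result_from_dict(json.load(fh))
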