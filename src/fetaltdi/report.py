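"""Peak-velocity and interval extraction, ROI percent-difference summaries,
feasibility percentages, ROI-fraction arithmetic and GA-based ROI
recommendations.

Conventions: percent differences for velocities are computed on magnitudes
so attenuation with larger ROIs is negative; quantiles use linear
interpolation; printed percentages round half away from zero to integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    PHASES,
    AnalysisResult,
    IntervalSet,
    PeakVelocities,
    PhaseSegmentation,
    ROISpec,
    VelocityTrace,
    ga_group_for,
)

__all__ = [
    "peak_velocities",
    "interval_durations",
    "percent_difference",
    "summarize_differences",
    "feasibility",
    "roi_fraction",
    "recommend_roi",
    "roi_study",
    "DifferenceSummary",
    "FeasibilitySummary",
    "ROI_HEIGHTS_MM",
    "ROI_WIDTH_MM",
]

#: ROI length ladder (mm) studied per gestational-age group.
ROI_HEIGHTS_MM = {"GA_I": (2.0, 3.0, 4.0), "GA_II": (2.0, 3.0, 4.0, 6.0), "GA_III": (2.0, 3.0, 4.0, 6.0, 8.0)}
#: Largest ROI width (mm) per group, covering the wall thickness.
ROI_WIDTH_MM = {"GA_I": 2.0, "GA_II": 3.0, "GA_III": 4.0}
#: Recommended ROI (height, width) per group.
RECOMMENDED_ROI_MM = {"GA_I": (2.0, 2.0), "GA_II": (4.0, 3.0), "GA_III": (6.0, 4.0)}

#: Reference ROI for percent differences: 2 x 2 mm at the AV-plane.
REFERENCE_ROI = ROISpec.at_av_plane(2.0, 2.0)


@dataclass(frozen=True)
class DifferenceSummary:
    metric: str
    roi: Optional[ROISpec]
    median_pct: float
    iqr_pct: float

    def __post_init__(self) -> None:
        if self.iqr_pct < 0:
            raise ValueError("IQR cannot be negative")


@dataclass(frozen=True)
class FeasibilitySummary:
    per_wall: dict[str, tuple[int, int]]  # wall -> (n_success, n_total)
    overall: tuple[int, int]
    percentages: dict[str, int]  # integer %, keys = walls + "overall"


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def peak_velocities(vel: VelocityTrace, seg: PhaseSegmentation) -> PeakVelocities:
    """Extract Sm/Em/Am from one segmented cycle (canonical polarity):
    Sm = max velocity during ejection, Em = min during rapid filling,
    Am = min during atrial contraction."""
    t = vel.times

    def window(a: float, b: float) -> np.ndarray:
        mask = (t >= a - 1e-12) & (t < b - 1e-12)
        if not np.any(mask):
            raise ValueError("empty phase window for peak extraction")
        return vel.samples[mask]

    b = seg.boundaries
    sm = float(np.max(window(b[2], b[3])))
    em = float(np.min(window(b[4], b[5])))
    am = float(np.min(window(b[0], b[1])))
    return PeakVelocities(sm=sm, em=em, am=am)


def interval_durations(seg: PhaseSegmentation) -> IntervalSet:
    """Phase durations in ms; they sum exactly to the cycle length."""
    durs = seg.durations_s() * 1000.0
    return IntervalSet({name: float(d) for name, d in zip(PHASES, durs)})


def percent_difference(value, reference, magnitude: bool = False):
    """``100 * (value - reference) / reference``; with ``magnitude=True``
    both operands enter as absolute values, so attenuation of a negative
    peak still yields a negative difference.  Vectorizes over arrays."""
    v = np.asarray(value, dtype=float)
    r = np.asarray(reference, dtype=float)
    if magnitude:
        v, r = np.abs(v), np.abs(r)
    if np.any(r == 0):
        raise ZeroDivisionError("reference must be nonzero")
    out = 100.0 * (v - r) / r
    return float(out) if out.ndim == 0 else out


def summarize_differences(
    values: Sequence[float], metric: str = "", roi: Optional[ROISpec] = None
) -> DifferenceSummary:
    """Median and interquartile range (Q3 - Q1, linear-interpolation
    quantiles) of a list of percent differences."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("no values to summarize")
    q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
    return DifferenceSummary(metric=metric, roi=roi, median_pct=float(med), iqr_pct=float(q3 - q1))


def feasibility(results: Iterable[AnalysisResult]) -> FeasibilitySummary:
    """Per-wall and pooled success counts with integer-rounded percentages
    (round half away from zero)."""
    per_wall: dict[str, list[int]] = {}
    for r in results:
        succ, tot = per_wall.setdefault(r.trace_label, [0, 0])
        per_wall[r.trace_label][1] += 1
        if r.success:
            per_wall[r.trace_label][0] += 1
    if not per_wall:
        raise ValueError("no results provided")
    per_wall_t = {w: (s, t) for w, (s, t) in per_wall.items()}
    n_succ = sum(s for s, _ in per_wall_t.values())
    n_tot = sum(t for _, t in per_wall_t.values())
    pct = {w: _round_half_away(100.0 * s / t) for w, (s, t) in per_wall_t.items()}
    pct["overall"] = _round_half_away(100.0 * n_succ / n_tot)
    return FeasibilitySummary(per_wall=per_wall_t, overall=(n_succ, n_tot), percentages=pct)


def roi_fraction(roi_length_mm: float, septal_length_mm: float) -> int:
    """ROI length as an integer percentage of the septal AV-plane-to-apex
    length."""
    if roi_length_mm <= 0 or septal_length_mm <= 0:
        raise ValueError("lengths must be positive")
    return _round_half_away(100.0 * roi_length_mm / septal_length_mm)


def recommend_roi(ga_weeks: float) -> ROISpec:
    """Recommended ROI per gestational-age group: 2x2 mm (GA I), 4x3 mm
    (GA II), 6x4 mm (GA III), top edge at the AV-plane."""
    grp = ga_group_for(ga_weeks)
    h, w = RECOMMENDED_ROI_MM[grp.name]
    return ROISpec.at_av_plane(h, w)


def roi_study(
    ga_weeks: float,
    seed: int = 0,
    heights_mm: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    config=None,
) -> pd.DataFrame:
    """Simulate one velocity field, sample the GA-appropriate ROI ladder,
    analyze every trace, and summarize percent differences of peak
    velocities (on magnitudes) and phase durations against the 2x2 mm
    reference ROI.

    Returns a tidy frame with one row per (metric, ROI height):
    columns metric, roi_height_mm, roi_width_mm, median_pct, iqr_pct, n.
    """
    from . import events  # deferred: events imports this module
    from .synthetic import HeartGeometry, HeartModelParams, generate_field, sample_roi

    grp = ga_group_for(ga_weeks)
    heights = tuple(heights_mm) if heights_mm is not None else ROI_HEIGHTS_MM[grp.name]
    width = ROI_WIDTH_MM[grp.name]
    cfg = config or events.AnalysisConfig()
    params = HeartModelParams(ga_weeks=ga_weeks, noise_sd=noise_sd)
    geometry = HeartGeometry.for_ga(ga_weeks)
    fld = generate_field(params, geometry, seed=seed)

    def measure(roi: ROISpec):
        trace = sample_roi(fld, roi)
        res = events.analyze_trace(trace, cfg)
        if not res.success:
            raise RuntimeError(f"ROI study trace failed analysis: {res.failure_reason}")
        peaks = {"Sm": [], "Em": [], "Am": []}
        intervals: dict[str, list[float]] = {p: [] for p in PHASES}
        base = events._canonical_base(trace, cfg)
        for seg in res.segmentations:
            pv = peak_velocities(base, seg)
            peaks["Sm"].append(pv.sm)
            peaks["Em"].append(pv.em)
            peaks["Am"].append(pv.am)
            for p, d in interval_durations(seg).durations_ms.items():
                intervals[p].append(d)
        return peaks, intervals

    ref_peaks, ref_intervals = measure(REFERENCE_ROI)
    rows = []
    for h in heights:
        if h == REFERENCE_ROI.height_mm:
            continue
        roi = ROISpec.at_av_plane(h, width)
        peaks, intervals = measure(roi)
        for metric in ("Sm", "Em", "Am"):
            n = min(len(peaks[metric]), len(ref_peaks[metric]))
            diffs = percent_difference(
                np.array(peaks[metric][:n]), np.array(ref_peaks[metric][:n]), magnitude=True
            )
            s = summarize_differences(np.atleast_1d(diffs), metric=metric, roi=roi)
            rows.append((metric, h, width, s.median_pct, s.iqr_pct, n))
        for p in PHASES:
            n = min(len(intervals[p]), len(ref_intervals[p]))
            diffs = percent_difference(np.array(intervals[p][:n]), np.array(ref_intervals[p][:n]))
            s = summarize_differences(np.atleast_1d(diffs), metric=p, roi=roi)
            rows.append((p, h, width, s.median_pct, s.iqr_pct, n))
    return pd.DataFrame(
        rows, columns=["metric", "roi_height_mm", "roi_width_mm", "median_pct", "iqr_pct", "n"]
    )
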