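"""Acceleration-shift detection, template-based phase assignment, and the
per-trace analysis pipeline.

Shift candidates are the zero crossings of the acceleration trace plus its
prominent local extrema.  Within each cycle the five interior phase onsets
(the atrial onset is pinned to the detected cycle start) are assigned to
candidates by constrained least squares: minimize the summed squared
distance between candidate positions (as cycle fractions) and the template
priors, subject to strict time ordering, per-event tolerance windows and
per-event allowed candidate kinds.  The optimum is found by dynamic
programming over the time-ordered candidates; tests check it against
exhaustive subset enumeration.

The full pipeline smooths the trace, then tries the four filter settings in
order, keeping the first for which at least half of the detected cycles
segment successfully; per-cycle measurements are aggregated by median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .core import (
    DEFAULT_PHASE_FRACTIONS,
    AccelerationTrace,
    AnalysisResult,
    IntervalSet,
    PeakVelocities,
    PhaseSegmentation,
    VelocityTrace,
)
from .cycles import (
    InsufficientDataError,
    NoPeriodicityError,
    estimate_period,
    locate_cycle_starts,
)
from .preprocess import acceleration, moving_average
from .quality import QualityThresholds, acceleration_score
from .report import interval_durations, peak_velocities

__all__ = [
    "ShiftCandidate",
    "EventTemplate",
    "AnalysisConfig",
    "InsufficientShiftsError",
    "TemplateMismatchError",
    "detect_shifts",
    "segment_cycle",
    "analyze_trace",
]


class InsufficientShiftsError(RuntimeError):
    """Fewer acceleration-shift candidates than events to assign."""


class TemplateMismatchError(RuntimeError):
    """No feasible ordered assignment of candidates to events."""


@dataclass(frozen=True)
class ShiftCandidate:
    """One acceleration shift: a zero crossing or a prominent local
    extremum of the acceleration trace."""

    time: float
    kind: str  # "zero_crossing" | "local_extremum"
    magnitude: float  # |a| at extremum, |slope| at crossing (cm/s^2, cm/s^3)
    sign: int  # extremum: sign of a; crossing: +1 rising, -1 falling
    index: int  # nearest sample index

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.kind not in ("zero_crossing", "local_extremum"):
            raise ValueError(f"unknown candidate kind {self.kind!r}")


@dataclass(frozen=True)
class EventTemplate:
    """Expected phase-onset positions as cycle fractions, with per-event
    tolerance windows and (optionally) allowed candidate kinds.

    The default priors are the cumulative sums of the default phase
    fractions; both are configuration, enabling recalibration.
    """

    prior_fractions: tuple[float, ...] = tuple(
        float(x) for x in np.cumsum((0.0,) + DEFAULT_PHASE_FRACTIONS[:-1])
    )
    tolerance: tuple[float, ...] = (0.08,) * 6
    required_kinds: tuple[Optional[tuple[str, ...]], ...] = (None,) * 6

    def __post_init__(self) -> None:
        pf = tuple(float(x) for x in self.prior_fractions)
        object.__setattr__(self, "prior_fractions", pf)
        tol = self.tolerance
        if np.isscalar(tol):
            tol = (float(tol),) * 6
        object.__setattr__(self, "tolerance", tuple(float(x) for x in tol))
        if len(pf) != 6 or pf[0] != 0.0 or any(pf[i + 1] <= pf[i] for i in range(5)):
            raise ValueError("prior_fractions must be 6 strictly increasing values starting at 0")
        if any(f < 0 or f >= 1 for f in pf):
            raise ValueError("prior_fractions must lie in [0, 1)")
        if len(self.tolerance) != 6 or any(t <= 0 for t in self.tolerance):
            raise ValueError("tolerances must be 6 positive values")
        if len(self.required_kinds) != 6:
            raise ValueError("required_kinds must have 6 entries")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the automated pipeline (YAML-overridable)."""

    smooth_window: int = 3
    filter_windows: tuple[int, ...] = (3, 5, 7, 9)
    bpm_range: tuple[float, float] = (80.0, 220.0)
    min_confidence: float = 0.5
    onset_band: float = 0.1
    quiet_fraction: float = 0.05
    shift_prominence: float = 0.15
    template: EventTemplate = field(default_factory=EventTemplate)
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    min_cycle_success: float = 0.5
    invert: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        """Load overrides from a YAML file with dotted sections, e.g.::

            smooth: {default_window: 3}
            filter: {windows: [3, 5, 7, 9]}
            cycle: {bpm_range: [80, 220], min_confidence: 0.5, onset_band: 0.1}
            shifts: {prominence: 0.15}
            template: {prior_fractions: [...], tolerance: 0.08}
            quality: {flat_threshold: 0.7, ...}
            invert: false
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw: dict = {}
        smooth = raw.get("smooth", {})
        if "default_window" in smooth:
            kw["smooth_window"] = int(smooth["default_window"])
        filt = raw.get("filter", {})
        if "windows" in filt:
            kw["filter_windows"] = tuple(int(w) for w in filt["windows"])
        cyc = raw.get("cycle", {})
        if "bpm_range" in cyc:
            kw["bpm_range"] = tuple(float(x) for x in cyc["bpm_range"])
        if "min_confidence" in cyc:
            kw["min_confidence"] = float(cyc["min_confidence"])
        if "onset_band" in cyc:
            kw["onset_band"] = float(cyc["onset_band"])
        if "quiet_fraction" in cyc:
            kw["quiet_fraction"] = float(cyc["quiet_fraction"])
        shifts = raw.get("shifts", {})
        if "prominence" in shifts:
            kw["shift_prominence"] = float(shifts["prominence"])
        tmpl = raw.get("template", {})
        if tmpl:
            tkw: dict = {}
            if "prior_fractions" in tmpl:
                tkw["prior_fractions"] = tuple(float(x) for x in tmpl["prior_fractions"])
            if "tolerance" in tmpl:
                tol = tmpl["tolerance"]
                tkw["tolerance"] = (
                    (float(tol),) * 6 if np.isscalar(tol) else tuple(float(x) for x in tol)
                )
            kw["template"] = EventTemplate(**tkw)
        qual = raw.get("quality", {})
        if qual:
            kw["quality"] = QualityThresholds(**{k: v for k, v in qual.items()})
        if "invert" in raw:
            kw["invert"] = bool(raw["invert"])
        if "min_cycle_success" in raw:
            kw["min_cycle_success"] = float(raw["min_cycle_success"])
        return cls(**kw)


# ---------------------------------------------------------------------------
# Shift detection
# ---------------------------------------------------------------------------


def detect_shifts(
    acc: AccelerationTrace,
    window: tuple[float, float],
    prominence: float = 0.15,
) -> list[ShiftCandidate]:
    """All acceleration zero crossings plus local extrema with
    ``|a| >= prominence * max|a|`` inside ``[start, end)``, time-ordered.

    Zero crossings include transitions into and out of exactly-zero runs
    (timed midway between the adjacent samples); sign changes between
    nonzero samples are timed by linear interpolation.  The left window
    edge can be an extremum (half-open window); the right cannot.
    """
    t0, t1 = window
    if not (t1 > t0):
        raise ValueError("empty detection window")
    rate = acc.sampling_rate
    i0 = max(0, int(math.ceil((t0 - acc.time_start) * rate - 1e-9)))
    i1 = min(acc.n, int(math.floor((t1 - acc.time_start) * rate + 1e-9)) + 1)
    a = acc.samples[i0:i1]
    if a.size < 2:
        raise ValueError("detection window contains fewer than 2 samples")
    times = acc.time_start + np.arange(i0, i1) / rate
    amax = float(np.max(np.abs(a)))
    if amax <= 0.0:
        return []
    zero_tol = 1e-9 * amax
    s = np.where(np.abs(a) <= zero_tol, 0, np.sign(a)).astype(int)
    cands: list[ShiftCandidate] = []

    def add_crossing(tc, idx, direction, slope):
        cands.append(
            ShiftCandidate(
                time=float(tc),
                kind="zero_crossing",
                magnitude=float(slope),
                sign=int(direction),
                index=int(idx),
            )
        )

    # Sign-change analysis over runs of constant sign: direct crossings are
    # interpolated; short zero runs (<= 2 samples) between opposite signs
    # collapse to one crossing at the run center; entries into and exits out
    # of longer zero runs (diastasis) each produce a candidate.
    runs: list[tuple[int, int, int]] = []  # (sign, start, stop-exclusive)
    start = 0
    for i in range(1, s.size):
        if s[i] != s[start]:
            runs.append((int(s[start]), start, i))
            start = i
    runs.append((int(s[start]), start, s.size))
    for r, (sgn, lo, hi) in enumerate(runs):
        if r == 0:
            continue
        prev_sgn, plo, phi = runs[r - 1]
        slope = abs(a[lo] - a[lo - 1]) * rate
        if prev_sgn != 0 and sgn != 0:
            frac = a[lo - 1] / (a[lo - 1] - a[lo])
            tc = times[lo - 1] + frac / rate
            add_crossing(tc, i0 + lo - (0 if frac > 0.5 else 1), sgn - prev_sgn > 0, slope)
        elif sgn == 0:
            if hi - lo <= 2 and r + 1 < len(runs) and runs[r + 1][0] == -prev_sgn:
                mid = 0.5 * (times[lo] + times[hi - 1])
                add_crossing(mid, i0 + (lo + hi - 1) // 2, -prev_sgn > 0, slope)
            else:
                add_crossing(times[lo - 1] + 0.5 / rate, i0 + lo, -prev_sgn > 0, slope)
        else:  # leaving a zero run
            if phi - plo <= 2 and r >= 2 and runs[r - 2][0] == -sgn:
                continue  # already emitted as a collapsed crossing
            add_crossing(times[lo] - 0.5 / rate, i0 + lo, sgn > 0, slope)

    # Local extrema (interior strict/plateau peaks plus the left edge).
    from scipy.signal import find_peaks

    for arr, sgn in ((a, 1), (-a, -1)):
        peaks, _ = find_peaks(arr)
        for p in peaks:
            if abs(a[p]) >= prominence * amax:
                cands.append(
                    ShiftCandidate(
                        time=float(times[p]), kind="local_extremum", magnitude=float(abs(a[p])), sign=sgn, index=int(i0 + p)
                    )
                )
    if abs(a[0]) >= prominence * amax and a.size > 1 and a[0] != a[1]:
        sgn = 1 if a[0] > a[1] else -1
        if (sgn > 0 and a[0] > 0) or (sgn < 0 and a[0] < 0):
            cands.append(
                ShiftCandidate(
                    time=float(times[0]), kind="local_extremum", magnitude=float(abs(a[0])), sign=int(np.sign(a[0])), index=int(i0)
                )
            )
    cands.sort(key=lambda c: c.time)
    return cands


# ---------------------------------------------------------------------------
# Template assignment
# ---------------------------------------------------------------------------


def _candidate_feasible(c: ShiftCandidate, event: int, template: EventTemplate) -> bool:
    kinds = template.required_kinds[event]
    return kinds is None or c.kind in kinds


def assign_events(
    candidates: Sequence[ShiftCandidate],
    cycle_start: float,
    period: float,
    template: EventTemplate,
) -> Optional[list[int]]:
    """Minimum-cost ordered assignment of candidates to events 2..6.

    Returns candidate indices (into ``candidates``, assumed time-ordered)
    for the five interior onsets, or None when no feasible assignment
    exists.  Cost is the summed squared deviation of candidate cycle
    fractions from the template priors.
    """
    n = len(candidates)
    fr = np.array([(c.time - cycle_start) / period for c in candidates])
    priors = template.prior_fractions[1:]
    tols = template.tolerance[1:]
    INF = np.inf
    cost = np.full((5, n), INF)
    back = np.full((5, n), -1, dtype=int)
    for e in range(5):
        for j in range(n):
            if not (0.0 < fr[j] < 1.0):
                continue
            if abs(fr[j] - priors[e]) > tols[e]:
                continue
            if not _candidate_feasible(candidates[j], e + 1, template):
                continue
            c = (fr[j] - priors[e]) ** 2
            if e == 0:
                cost[e, j] = c
            else:
                best, arg = INF, -1
                for jp in range(j):
                    if cost[e - 1, jp] < best and candidates[jp].time < candidates[j].time:
                        best, arg = cost[e - 1, jp], jp
                if arg >= 0:
                    cost[e, j] = best + c
                    back[e, j] = arg
    j = int(np.argmin(cost[4]))
    if not np.isfinite(cost[4, j]):
        return None
    sel = [j]
    for e in range(4, 0, -1):
        j = int(back[e, j])
        sel.append(j)
    return sel[::-1]


def segment_cycle(
    vel: VelocityTrace,
    acc: AccelerationTrace,
    cycle: tuple[float, float],
    template: Optional[EventTemplate] = None,
    prominence: float = 0.15,
) -> PhaseSegmentation:
    """Segment one cycle ``[onset, next onset)`` into the six phases.

    The atrial onset (event 1) is pinned to the cycle start; the remaining
    five onsets are assigned to acceleration-shift candidates by the
    constrained least-squares template match.
    """
    template = template or EventTemplate()
    t_start, t_end = cycle
    cands = detect_shifts(acc, (t_start, t_end), prominence=prominence)
    if len(cands) < 6:
        raise InsufficientShiftsError(f"only {len(cands)} shift candidates in cycle")
    sel = assign_events(cands, t_start, t_end - t_start, template)
    if sel is None:
        raise TemplateMismatchError("no feasible candidate-to-event assignment")
    boundaries = (t_start,) + tuple(cands[j].time for j in sel)
    indices = (vel.index_at(t_start),) + tuple(cands[j].index for j in sel)
    return PhaseSegmentation(
        cycle_start=t_start, boundaries=boundaries, cycle_end=t_end, shift_indices=indices
    )


# ---------------------------------------------------------------------------
# Full per-trace pipeline
# ---------------------------------------------------------------------------


def _canonical_base(trace: VelocityTrace, config: AnalysisConfig) -> VelocityTrace:
    """Orientation-corrected, lightly smoothed trace that measurements are
    read from."""
    t = trace.with_samples(-trace.samples) if config.invert else trace
    if trace.n >= config.smooth_window:
        t = moving_average(t, config.smooth_window)
    return t


def _failure(trace, reason, score, setting=None) -> AnalysisResult:
    return AnalysisResult(
        trace_label=trace.label,
        success=False,
        failure_reason=reason,
        acceleration_score=score,
        filter_setting_used=setting,
    )


_REASON_PRECEDENCE = ("no_periodicity", "insufficient_shifts", "template_mismatch")


def analyze_trace(trace: VelocityTrace, config: Optional[AnalysisConfig] = None) -> AnalysisResult:
    """Run the full automated analysis on one velocity trace.

    Pipeline: smooth -> for each filter setting 1..4: filter, differentiate,
    estimate the period, locate cycle starts, segment every complete cycle;
    the first setting for which at least ``min_cycle_success`` of the cycles
    segment successfully wins.  Per-cycle peaks, intervals and quality
    scores are aggregated by median.  Failures are encoded in the result,
    never raised.
    """
    config = config or AnalysisConfig()
    if trace.n < max(3, config.smooth_window):
        return _failure(trace, "degenerate_input", 1)
    base = _canonical_base(trace, config)
    reasons: list[str] = []
    fallback_score = None
    for setting in range(1, len(config.filter_windows) + 1):
        window = config.filter_windows[setting - 1]
        if window > base.n:
            reasons.append("degenerate_input")
            continue
        filt = moving_average(base, window)
        acc = acceleration(filt)
        if fallback_score is None:
            fallback_score = acceleration_score(acc, None, config.quality).score
        try:
            pe = estimate_period(
                filt,
                bpm_range=config.bpm_range,
                min_confidence=config.min_confidence,
                smooth_window=1,
            )
        except NoPeriodicityError:
            reasons.append("no_periodicity")
            continue
        try:
            onsets = locate_cycle_starts(
                filt,
                acc,
                pe.period,
                onset_band=config.onset_band,
                quiet_fraction=config.quiet_fraction,
            )
        except InsufficientDataError:
            reasons.append("insufficient_shifts")
            continue
        bounds = list(onsets)
        end_time = filt.time_start + filt.duration
        if bounds[-1] + pe.period <= end_time + 0.5 * filt.dt:
            bounds.append(bounds[-1] + pe.period)
        cycles = list(zip(bounds[:-1], bounds[1:]))
        if not cycles:
            reasons.append("insufficient_shifts")
            continue
        segs: list[PhaseSegmentation] = []
        cycle_reasons: list[str] = []
        for c in cycles:
            try:
                segs.append(
                    segment_cycle(filt, acc, c, config.template, prominence=config.shift_prominence)
                )
            except InsufficientShiftsError:
                cycle_reasons.append("insufficient_shifts")
            except TemplateMismatchError:
                cycle_reasons.append("template_mismatch")
        needed = math.ceil(config.min_cycle_success * len(cycles))
        if segs and len(segs) >= needed:
            sm, em, am = [], [], []
            per_phase: dict[str, list[float]] = {}
            scores: list[int] = []
            for seg in segs:
                pv = peak_velocities(base, seg)
                sm.append(pv.sm)
                em.append(pv.em)
                am.append(pv.am)
                for p, d in interval_durations(seg).durations_ms.items():
                    per_phase.setdefault(p, []).append(d)
                scores.append(acceleration_score(acc, seg, config.quality).score)
            agg_score = int(sorted(scores)[(len(scores) - 1) // 2])  # low median
            return AnalysisResult(
                trace_label=trace.label,
                success=True,
                segmentations=segs,
                peak_velocities=PeakVelocities(
                    sm=float(np.median(sm)), em=float(np.median(em)), am=float(np.median(am))
                ),
                intervals=IntervalSet({p: float(np.median(v)) for p, v in per_phase.items()}),
                acceleration_score=agg_score,
                filter_setting_used=setting,
            )
        reasons.extend(cycle_reasons or ["template_mismatch"])
    if not reasons:
        reasons = ["degenerate_input"]
    counts = {r: reasons.count(r) for r in set(reasons)}
    dominant = max(
        counts,
        key=lambda r: (counts[r], -_REASON_PRECEDENCE.index(r) if r in _REASON_PRECEDENCE else -9),
    )
    return _failure(trace, dominant, fallback_score or 1)
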