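"""Cardiac-period estimation and atrial-onset (cycle start) location
without an ECG.

The period comes from the highest normalized-autocorrelation peak within the
physiologic lag window (80-220 bpm by default).  Cycle starts are anchored
where the acceleration, after a sustained near-zero (diastasis) stretch,
departs from a relative band heading into the A-wave (velocity turning
negative under the canonical polarity), then refined backward to the zero
transition.  Only complete cycles are returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

from .core import AccelerationTrace, VelocityTrace
from .preprocess import moving_average_array

__all__ = [
    "PeriodEstimate",
    "NoPeriodicityError",
    "InsufficientDataError",
    "estimate_period",
    "locate_cycle_starts",
]


class NoPeriodicityError(RuntimeError):
    """No autocorrelation peak of sufficient confidence in the lag window."""


class InsufficientDataError(RuntimeError):
    """Trace does not contain one complete cardiac cycle."""


@dataclass(frozen=True)
class PeriodEstimate:
    period: float  # s
    confidence: float  # normalized autocorrelation at the chosen lag, in [0, 1]


def estimate_period(
    trace: VelocityTrace,
    bpm_range: tuple[float, float] = (80.0, 220.0),
    min_confidence: float = 0.5,
    smooth_window: int = 3,
) -> PeriodEstimate:
    """Estimate the cardiac period by normalized autocorrelation."""
    x = trace.samples
    if smooth_window > 1 and smooth_window <= x.size:
        x = moving_average_array(x, smooth_window)
    x = x - x.mean()
    n = x.size
    energy = float(np.dot(x, x))
    if energy <= 0.0:
        raise NoPeriodicityError("trace has no variation")
    rate = trace.sampling_rate
    lag_min = int(math.ceil(rate * 60.0 / bpm_range[1]))
    lag_max = int(math.floor(rate * 60.0 / bpm_range[0]))
    lag_max = min(lag_max, n - 2)
    if lag_min > lag_max:
        raise NoPeriodicityError("trace too short for the physiologic lag window")
    r = np.correlate(x, x, mode="full")[n - 1 :] / energy
    window = r[lag_min : lag_max + 1]
    best = int(np.argmax(window)) + lag_min
    confidence = float(r[best])
    if confidence < min_confidence:
        raise NoPeriodicityError(
            f"best autocorrelation peak {confidence:.3f} below threshold {min_confidence}"
        )
    return PeriodEstimate(period=best / rate, confidence=confidence)


def _refine_onset(a: np.ndarray, i: int, forward: int) -> int:
    """Refine a departure sample to the center of the negative acceleration
    excursion (its local minimum), which is symmetric-filter invariant."""
    hi = min(a.size, i + forward + 1)
    return i + int(np.argmin(a[i:hi]))


def _refit_rhythm(
    a: np.ndarray,
    onsets: list[int],
    n_per: int,
    onset_band: float,
    local_max: np.ndarray,
    quiet_ok,
) -> list[int]:
    """Snap onsets to the trace's own rhythm.

    Robust-fits the periodic sequence ``onset_k ~ c0 + k * T`` through the
    initially detected onsets, then re-locates every onset (including cycles
    whose departure was missed) at the local acceleration minimum near its
    fitted position.  Isolated mis-anchored onsets are pulled back onto the
    grid; windows with no real A-wave shift (minimum inside the near-zero
    band) are dropped.
    """
    if len(onsets) < 2:
        return onsets
    arr = np.asarray(onsets, dtype=float)
    ks = np.round((arr - arr[0]) / n_per).astype(int)
    gaps = np.diff(arr) / np.maximum(np.diff(ks), 1)
    t_fit = float(np.median(gaps))
    if not (0.7 * n_per <= t_fit <= 1.3 * n_per):
        t_fit = float(n_per)
    c0 = float(np.median(arr - ks * t_fit))
    w = max(2, int(round(0.03 * n_per)))
    refined: list[int] = []
    k = int(math.ceil((w - c0) / t_fit))
    n = a.size
    while True:
        p = int(round(c0 + k * t_fit))
        if p > n - 1 - w:
            break
        lo, hi = max(0, p - w), min(n, p + w + 1)
        j = lo + int(np.argmin(a[lo:hi]))
        if (
            a[j] < -onset_band * local_max[j]
            and quiet_ok(max(0, j - w))
            and (not refined or j > refined[-1])
        ):
            refined.append(j)
        k += 1
    return refined if refined else onsets


def locate_cycle_starts(
    trace: VelocityTrace,
    acc: AccelerationTrace,
    period: float,
    onset_band: float = 0.1,
    quiet_fraction: float = 0.05,
    invert: bool = False,
) -> np.ndarray:
    """Locate atrial-contraction onsets (cycle starts), one per period.

    A candidate onset is the first sample where acceleration drops below
    ``-onset_band * max|a|`` (window-relative) after a quiet stretch whose
    median ``|a|`` stays inside the band; the onset is then refined to the
    local minimum of the negative acceleration excursion (the center of the
    A-wave onset shift, invariant under symmetric smoothing).  Successive
    onsets are searched within -20 %/+25 % of the period around the
    expected position; a cycle with no qualifying departure is skipped.
    Returns onset times (s) of complete cycles only.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    sign = -1.0 if invert else 1.0
    a = sign * acc.samples
    n = a.size
    rate = trace.sampling_rate
    n_per = int(round(period * rate))
    if n_per < 4 or n_per > n - 1:
        raise InsufficientDataError("trace shorter than one cardiac period")
    # extra symmetric smoothing for anchoring only: the onset shift is an
    # even-symmetric acceleration extremum, so its location is unbiased
    # under any centered window while noise jitter shrinks
    loc_window = max(3, int(round(0.03 * n_per)) | 1)
    if loc_window <= n:
        a = moving_average_array(a, loc_window)
    quiet = max(2, int(round(quiet_fraction * n_per)))
    forward = max(3, int(round(0.06 * n_per)))
    local_max = maximum_filter1d(np.abs(a), size=n_per, mode="nearest")
    v = sign * trace.samples
    local_vmax = maximum_filter1d(np.abs(v), size=n_per, mode="nearest")

    def quiet_ok(i: int) -> bool:
        # before an atrial onset the trace idles near zero (diastasis);
        # this rejects the other negative departure in the cycle (the
        # post-ejection onset, which leaves the systolic plateau)
        lo = max(0, i - quiet)
        if i - lo < 2:
            return False
        return abs(float(np.median(v[lo:i]))) < 0.3 * local_vmax[i]

    def departure(i: int) -> bool:
        band = onset_band * local_max[i]
        if not (a[i] < -band):
            return False
        lo = max(0, i - quiet)
        if i - lo < 2:
            return False
        if float(np.median(np.abs(a[lo:i]))) >= band:
            return False
        return quiet_ok(i)

    onsets: list[int] = []
    # First onset: scan the first ~1.25 periods.
    first = None
    for i in range(1, min(n, int(1.25 * n_per) + 1)):
        if departure(i):
            first = _refine_onset(a, i, forward)
            break
    if first is None:
        raise InsufficientDataError("no atrial onset found in the first period")
    onsets.append(first)
    expected = first + n_per
    while expected + int(0.25 * n_per) < n:
        lo = max(onsets[-1] + 1, expected - int(0.2 * n_per))
        hi = min(n, expected + int(0.25 * n_per) + 1)
        found = None
        for i in range(lo, hi):
            if departure(i):
                found = _refine_onset(a, i, forward)
                break
        if found is not None and found > onsets[-1]:
            onsets.append(found)
            expected = found + n_per
        else:
            expected += n_per
    onsets = _refit_rhythm(a, onsets, n_per, onset_band, local_max, quiet_ok)
    # Keep only complete cycles: onset + one full period inside the trace.
    last_time = (n - 1) / rate
    times = np.array([o / rate for o in onsets])
    times = times[times + period <= last_time + 0.5 / rate]
    if times.size < 1:
        raise InsufficientDataError("no complete cycle inside the trace")
    return times + trace.time_start
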