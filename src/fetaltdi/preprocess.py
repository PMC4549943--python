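"""Smoothing, the four-setting filter bank, and velocity differentiation.

Edge policy: moving averages truncate the window at the record edges (mean
over the available samples), so output length equals input length and no
artificial endpoint transients leak into nearby cycles.  Differentiation
uses central differences in the interior (symmetric phase response keeps
detected event times unbiased) and one-sided differences at the two edges.
"""

from __future__ import annotations

import numpy as np

from .core import AccelerationTrace, VelocityTrace

__all__ = ["moving_average", "filter_bank", "acceleration", "FILTER_WINDOWS"]

#: Window width of each of the four filter settings (a reconstruction; the
#: original settings are unpublished).  Setting k uses FILTER_WINDOWS[k-1].
FILTER_WINDOWS = (3, 5, 7, 9)


def moving_average_array(x: np.ndarray, window: int) -> np.ndarray:
    """Centered unweighted moving mean with truncated edge windows."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    x = np.asarray(x, dtype=float)
    if window > x.size:
        raise ValueError("window exceeds trace length")
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def moving_average(trace: VelocityTrace, window: int = 3) -> VelocityTrace:
    """Smooth a velocity trace with a centered moving average (default
    three-point, matching the acquisition-side smoothing)."""
    return trace.with_samples(moving_average_array(trace.samples, window))


def filter_bank(trace: VelocityTrace, setting: int) -> VelocityTrace:
    """Apply filter setting 1-4 (moving averages of width 3/5/7/9).

    The four widths are a reconstruction of the unpublished originals; they
    can be overridden via the analysis configuration.
    """
    if setting not in (1, 2, 3, 4):
        raise ValueError(f"filter setting must be 1-4, got {setting}")
    return moving_average(trace, FILTER_WINDOWS[setting - 1])


def acceleration(trace: VelocityTrace) -> AccelerationTrace:
    """Differentiate velocity (cm/s) into acceleration (cm/s^2)."""
    if trace.n < 3:
        raise ValueError("need at least 3 samples to differentiate")
    a = np.gradient(trace.samples, trace.dt)
    return AccelerationTrace(
        label=f"{trace.label}:acc",
        sampling_rate=trace.sampling_rate,
        samples=a,
        source_trace_label=trace.label,
        time_start=trace.time_start,
    )
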