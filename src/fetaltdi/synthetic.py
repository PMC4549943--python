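"""Synthetic fetal AV-plane velocity fields with exact ground-truth event
times.

The one-cycle waveform is built so that *every phase onset is the center of
a smooth cosine step in velocity*: acceleration then carries an
even-symmetric extremum exactly at each boundary, and because centered
moving averages are symmetric filters those extremum locations are
invariant under any of the analysis filter settings.  Each phase holds a
plateau level between its two boundary steps; the three wave phases
(A-wave, S-wave, E-wave) additionally carry a raised-cosine interior bump
from the plateau to the configured peak velocity, so every peak is attained
exactly.  Diastasis is exactly zero.

Plateau levels for the A- and E-waves (falling back to the S-wave when
needed) are solved linearly so that the net displacement over one cycle is
exactly zero: symmetric steps integrate like their piecewise-constant
limit, and a raised-cosine bump contributes half its height times its
width, so the cycle integral is available in closed form.

Spatially, velocity decays linearly from the AV-plane (factor 1) to the
apex (factor 0), the textbook base-to-apex gradient of longitudinal
AV-plane motion.  Noise is additive white Gaussian, reproducible from a
seed.  All default amplitudes and phase fractions are synthetic modeling
conventions, not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .core import (
    DEFAULT_PHASE_FRACTIONS,
    PhaseSegmentation,
    ROISpec,
    VelocityTrace,
    ga_group_for,
)

__all__ = [
    "HeartModelParams",
    "HeartGeometry",
    "VelocityField",
    "build_waveform",
    "generate_field",
    "sample_roi",
    "generate_trace",
    "generate_dataset",
]

#: Mean septal AV-plane-to-apex length (mm) per gestational-age group.
SEPTAL_LENGTH_MM = {"GA_I": 15.6, "GA_II": 23.3, "GA_III": 32.5}
#: Representative wall thickness (mm) per group (mid-group gestations).
WALL_THICKNESS_MM = {"GA_I": 1.8, "GA_II": 2.9, "GA_III": 3.6}

#: Step half-width at a boundary, as a fraction of half the shorter
#: adjacent phase.
STEP_WIDTH_FACTOR = 0.5


@dataclass(frozen=True)
class HeartModelParams:
    """Parameters of the one-dimensional piston-like heart model."""

    heart_rate: float = 140.0  # beats/min
    phase_fractions: tuple[float, ...] = DEFAULT_PHASE_FRACTIONS
    peak_s: float = 5.0  # cm/s, > 0
    peak_e: float = -6.0  # cm/s, < 0
    peak_a: float = -4.5  # cm/s, < 0
    transient_amp: float = 1.5  # cm/s, pre-/post-ejection plateau amplitude
    noise_sd: float = 0.0  # cm/s
    frame_rate: float = 190.0  # Hz
    n_cycles: int = 7
    ga_weeks: float = 38.0
    #: When True an even velocity bump is superimposed at the pre- and
    #: post-ejection onsets, flanking each of those events with a pair of
    #: comparably large opposite-sign acceleration lobes (a double-lobed,
    #: "biphasic" shift; used to build score-2 quality fixtures).
    biphasic_transients: bool = False

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.phase_fractions)
        object.__setattr__(self, "phase_fractions", fr)
        if len(fr) != 6 or any(f <= 0 for f in fr):
            raise ValueError("phase_fractions must be six positive values")
        if abs(sum(fr) - 1.0) > 1e-12:
            raise ValueError("phase_fractions must sum to 1")
        if not (80.0 <= self.heart_rate <= 220.0):
            raise ValueError("heart_rate must lie in [80, 220] bpm")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not (self.peak_s > 0 and self.peak_e < 0 and self.peak_a < 0):
            raise ValueError("expected peak_s > 0, peak_e < 0, peak_a < 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.transient_amp < 0:
            raise ValueError("transient_amp must be >= 0")

    @property
    def cycle_length(self) -> float:
        """Cycle length in seconds."""
        return 60.0 / self.heart_rate


@dataclass(frozen=True)
class HeartGeometry:
    ventricular_length_mm: float  # AV-plane to apex
    wall_thickness_mm: float

    def __post_init__(self) -> None:
        if self.ventricular_length_mm <= 0 or self.wall_thickness_mm <= 0:
            raise ValueError("geometry dimensions must be > 0")

    @classmethod
    def for_ga(cls, ga_weeks: float) -> "HeartGeometry":
        grp = ga_group_for(ga_weeks)
        return cls(SEPTAL_LENGTH_MM[grp.name], WALL_THICKNESS_MM[grp.name])


@dataclass(eq=False)
class VelocityField:
    """Spatiotemporal velocity field, AV-plane (depth 0) to apex."""

    geometry: HeartGeometry
    positions: np.ndarray  # depths below AV-plane, mm
    times: np.ndarray  # s, uniform grid starting at 0
    values: np.ndarray  # cm/s, shape (n_positions, n_times)
    ground_truth: list[PhaseSegmentation]
    params: HeartModelParams
    seed: object


@dataclass(frozen=True)
class _Layout:
    """Resolved one-cycle geometry: boundary times, step half-widths,
    plateau levels and interior bump targets per phase."""

    T: float
    onsets: np.ndarray  # 6 boundary times, onsets[0] = 0
    durations: np.ndarray  # 6 phase durations
    half_widths: np.ndarray  # step half-width at each boundary
    levels: np.ndarray  # plateau level per phase
    bump_targets: np.ndarray  # interior bump extreme per phase (== level if flat)
    bip_amp: float  # amplitude of the boundary bumps in biphasic mode (0 = off)
    bip_half_widths: np.ndarray  # half-width of the boundary bump per boundary

    @property
    def interior_widths(self) -> np.ndarray:
        h_next = np.roll(self.half_widths, -1)
        return self.durations - self.half_widths - h_next


def _wave_integral(level: float, target: float, d: float, w: float) -> float:
    # symmetric steps integrate like the piecewise-constant plateau; the
    # raised-cosine bump adds half its height over its width
    return level * d + (target - level) * 0.5 * w


def _resolve_layout(params: HeartModelParams) -> _Layout:
    T = params.cycle_length
    d = np.array(params.phase_fractions) * T
    onsets = np.concatenate([[0.0], np.cumsum(d)[:-1]])
    d_prev = np.roll(d, 1)
    h = STEP_WIDTH_FACTOR * np.minimum(d_prev, d) / 2.0
    w = d - h - np.roll(h, -1)
    if np.any(w <= 0):
        raise ValueError("phase fractions leave no room for boundary steps")
    amp = params.transient_amp
    p_a, p_s, p_e = params.peak_a, params.peak_s, params.peak_e
    # biphasic mode: even cosine bump of half-width 2h at the pre-/post-
    # ejection onsets (integral = bump amplitude * half-width, opposite signs)
    bip_amp = 4.0 * amp if params.biphasic_transients else 0.0
    bip_h = 3.0 * h
    i_pre = _wave_integral(amp, amp, d[1], w[1]) + bip_amp * bip_h[1]
    i_post = _wave_integral(-amp, -amp, d[3], w[3]) - bip_amp * bip_h[3]

    def solve_gamma(peaks_d_w: list[tuple[float, float, float]], target: float) -> float:
        # I(gamma) = sum P * (0.5 w + gamma (d - 0.5 w)); solve I(gamma) = target
        base = sum(p * 0.5 * wk for p, _, wk in peaks_d_w)
        slope = sum(p * (dk - 0.5 * wk) for p, dk, wk in peaks_d_w)
        if slope == 0:
            raise ValueError("degenerate waveform layout")
        return (target - base) / slope

    gamma_s = 1.0
    target_ae = -(p_s * d[2] + i_pre + i_post)
    gamma_ae = solve_gamma([(p_a, d[0], w[0]), (p_e, d[4], w[4])], target_ae)
    if not (0.05 <= gamma_ae <= 1.0):
        gamma_ae = 1.0
        target_s = -(p_a * d[0] + p_e * d[4] + i_pre + i_post)
        gamma_s = solve_gamma([(p_s, d[2], w[2])], target_s)
        if not (0.05 <= gamma_s <= 1.0):
            raise ValueError(
                "cannot balance net displacement for these amplitudes/fractions"
            )
    levels = np.array([gamma_ae * p_a, amp, gamma_s * p_s, -amp, gamma_ae * p_e, 0.0])
    targets = np.array([p_a, amp, p_s, -amp, p_e, 0.0])
    return _Layout(
        T=T,
        onsets=onsets,
        durations=d,
        half_widths=h,
        levels=levels,
        bump_targets=targets,
        bip_amp=bip_amp,
        bip_half_widths=bip_h,
    )


def build_waveform(
    params: HeartModelParams,
) -> tuple[Callable[[np.ndarray], np.ndarray], np.ndarray]:
    """Build the periodic AV-plane velocity waveform.

    Returns ``(f, onsets)`` where ``f`` evaluates velocity (cm/s) at any
    time (periodic with the cycle length; the cycle starts at t = 0 with
    the atrial-contraction onset) and ``onsets`` holds the six exact
    phase-onset times (s) within one cycle.  ``f`` is C^1; its derivative
    has an even-symmetric extremum exactly at every onset, its maximum over
    the ejection phase is exactly ``peak_s`` (likewise the diastolic peaks)
    and its integral over one cycle is exactly zero.
    """
    lay = _resolve_layout(params)
    T = lay.T
    b = lay.onsets
    h = lay.half_widths
    L = lay.levels
    P = lay.bump_targets
    W = lay.interior_widths
    L_prev = np.roll(L, 1)

    def f(t):
        t_arr = np.asarray(t, dtype=float)
        s = np.mod(t_arr, T)
        out = np.empty_like(s)
        out.fill(np.nan)
        # boundary steps, centered at each onset (wrap-aware)
        for j in range(6):
            x = np.mod(s - b[j] + T / 2.0, T) - T / 2.0
            mask = np.abs(x) <= h[j]
            if np.any(mask):
                mid = 0.5 * (L_prev[j] + L[j])
                half = 0.5 * (L[j] - L_prev[j])
                out[mask] = mid + half * np.sin(np.pi * x[mask] / (2.0 * h[j]))
        # phase interiors: plateau plus raised-cosine bump to the peak;
        # small eps absorbs float mismatch at region edges
        eps = 1e-9 * T
        for k in range(6):
            lo = b[k] + h[k]
            hi = b[k] + lay.durations[k] - h[(k + 1) % 6]
            mask = (s >= lo - eps) & (s <= hi + eps) & np.isnan(out)
            if np.any(mask):
                u = np.clip((s[mask] - lo) / W[k], 0.0, 1.0)
                out[mask] = L[k] + (P[k] - L[k]) * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
        # biphasic mode: superimposed even bumps at the transient onsets
        if lay.bip_amp:
            for j, sign in ((1, 1.0), (3, -1.0)):
                hb = lay.bip_half_widths[j]
                x = np.mod(s - b[j] + T / 2.0, T) - T / 2.0
                mask = np.abs(x) <= hb
                if np.any(mask):
                    out[mask] += sign * lay.bip_amp * 0.5 * (1.0 + np.cos(np.pi * x[mask] / hb))
        return out if out.ndim else float(out)

    return f, lay.onsets.copy()


def _time_grid(params: HeartModelParams) -> tuple[np.ndarray, float]:
    """Sample times and the lead-in offset before the first cycle start.

    The grid starts half a diastasis before the first atrial onset and ends
    half a diastasis after the last cycle closes, so every one of the
    ``n_cycles`` complete cycles (including the first onset) is detectable.
    """
    T = params.cycle_length
    lead = 0.5 * params.phase_fractions[5] * T
    total = params.n_cycles * T + 2.0 * lead
    n = int(math.floor(total * params.frame_rate)) + 1
    return np.arange(n) / params.frame_rate, lead


def _ground_truth(
    params: HeartModelParams, onsets: np.ndarray, lead: float
) -> list[PhaseSegmentation]:
    T = params.cycle_length
    segs = []
    for k in range(params.n_cycles):
        start = lead + k * T
        bounds = tuple(start + o for o in onsets)
        idx = tuple(int(round(t * params.frame_rate)) for t in bounds)
        segs.append(
            PhaseSegmentation(
                cycle_start=start, boundaries=bounds, cycle_end=start + T, shift_indices=idx
            )
        )
    return segs


def generate_field(
    params: HeartModelParams,
    geometry: HeartGeometry,
    seed: object,
    dz_mm: float = 0.1,
) -> VelocityField:
    """Generate the spatiotemporal field ``waveform(t) * decay(z) + noise``
    with linear apex-ward decay and i.i.d. Gaussian noise per cell."""
    f, onsets = build_waveform(params)
    times, lead = _time_grid(params)
    L = geometry.ventricular_length_mm
    positions = np.arange(0.0, L + dz_mm / 2.0, dz_mm)
    decay = np.clip(1.0 - positions / L, 0.0, None)
    values = np.outer(decay, f(times - lead))
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, params.noise_sd, values.shape)
    return VelocityField(
        geometry=geometry,
        positions=positions,
        times=times,
        values=values,
        ground_truth=_ground_truth(params, onsets, lead),
        params=params,
        seed=seed,
    )


def sample_roi(field: VelocityField, roi: ROISpec, label: str = "other") -> VelocityTrace:
    """Unweighted spatial mean of the field over the ROI depth band.

    The ROI width is carried as metadata only; the 1-D field has no
    across-wall variation.
    """
    L = field.geometry.ventricular_length_mm
    top = roi.center_offset_mm - roi.height_mm / 2.0
    bottom = roi.center_offset_mm + roi.height_mm / 2.0
    if top < -1e-9:
        raise ValueError("ROI extends above the AV-plane")
    if bottom > L + 1e-9:
        raise ValueError("ROI extends beyond the apex")
    mask = (field.positions >= top - 1e-9) & (field.positions <= bottom + 1e-9)
    if not np.any(mask):
        # ROI narrower than the depth grid: fall back to the nearest row.
        mask = np.zeros_like(mask)
        mask[np.argmin(np.abs(field.positions - roi.center_offset_mm))] = True
    samples = field.values[mask].mean(axis=0)
    return VelocityTrace(
        label=label,
        sampling_rate=field.params.frame_rate,
        samples=samples,
        time_start=0.0,
        roi=roi,
    )


def generate_trace(
    params: HeartModelParams,
    geometry: HeartGeometry,
    roi: ROISpec,
    seed: object,
    label: str = "other",
) -> tuple[VelocityTrace, list[PhaseSegmentation]]:
    """Generate one ROI-sampled trace with trace-level additive noise.

    Equivalent to sampling the noise-free field (the ROI mean of the linear
    decay equals ``1 - center_offset / L`` exactly) and then adding
    Gaussian noise of sd ``params.noise_sd`` directly to the trace.
    """
    L = geometry.ventricular_length_mm
    bottom = roi.center_offset_mm + roi.height_mm / 2.0
    if bottom > L + 1e-9:
        raise ValueError("ROI extends beyond the apex")
    f, onsets = build_waveform(params)
    times, lead = _time_grid(params)
    samples = f(times - lead) * (1.0 - roi.center_offset_mm / L)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, params.noise_sd, samples.shape)
    trace = VelocityTrace(
        label=label,
        sampling_rate=params.frame_rate,
        samples=samples,
        time_start=0.0,
        roi=roi,
    )
    return trace, _ground_truth(params, onsets, lead)


def generate_dataset(
    n_traces: int,
    noise_grid: Sequence[float],
    ga_weeks: float,
    seed: int,
    roi: Optional[ROISpec] = None,
    base_params: Optional[HeartModelParams] = None,
    heart_rate_range: tuple[float, float] = (110.0, 160.0),
    n_cycles_range: tuple[int, int] = (5, 10),
) -> list[tuple[VelocityTrace, list[PhaseSegmentation]]]:
    """Reproducible batch of traces; trace ``i`` gets noise level
    ``noise_grid[i % len(noise_grid)]`` and a per-trace seed derived from
    the master seed by a counter scheme, so any subset regenerates
    identically."""
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    if len(noise_grid) == 0:
        raise ValueError("noise grid must not be empty")
    geometry = HeartGeometry.for_ga(ga_weeks)
    roi = roi or ROISpec.at_av_plane(2.0, 2.0)
    base = base_params or HeartModelParams(ga_weeks=ga_weeks)
    out = []
    for i in range(n_traces):
        draw = np.random.default_rng([int(seed), i, 0])
        hr = float(draw.uniform(*heart_rate_range))
        nc = int(draw.integers(n_cycles_range[0], n_cycles_range[1] + 1))
        params = replace(
            base,
            heart_rate=hr,
            n_cycles=nc,
            noise_sd=float(noise_grid[i % len(noise_grid)]),
            ga_weeks=ga_weeks,
        )
        out.append(
            generate_trace(params, geometry, roi, seed=[int(seed), i, 1], label=f"trace_{i:03d}")
        )
    return out
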