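"""Three-level acceleration-trace quality score and per-wall averages.

The published score is a human visual judgment (3 = clear, well-defined
shifts; 2 = less well-defined, often biphasic; 1 = indistinct, flat).  The
quantitative surrogate here grades a cycle on three scale-free features:

* ``flatness`` — ``(1 - rho) / 2`` where ``rho`` is the short-lag (~16 ms)
  autocorrelation of the mean-removed acceleration: organized shift
  structure is smooth at that scale (flatness near 0) while indistinct,
  structureless traces decorrelate (flatness near 1).  Scale-free.
* ``shift_prominence`` — median over the six matched shifts of the local
  peak ``|a|`` around each shift relative to the cycle peak.
* ``biphasic_count`` — matched events flanked by two comparably large
  opposite-sign acceleration extrema within a short window.

All thresholds are configurable; they are calibrated on generator fixtures,
not validated against human raters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .core import AccelerationTrace, PhaseSegmentation

__all__ = ["QualityThresholds", "QualityScore", "acceleration_score", "wall_average_score"]


@dataclass(frozen=True)
class QualityThresholds:
    flat_threshold: float = 0.6  # flatness above this -> score 1
    flatness_lag_s: float = 0.016  # autocorrelation lag for the flatness feature
    prominence_threshold: float = 0.25  # median shift prominence below -> score 2
    biphasic_window: float = 0.035  # half-window around an event, cycle fraction
    biphasic_ratio: float = 0.4  # minor/major extremum ratio to call biphasic
    biphasic_floor: float = 0.15  # major extremum must exceed this x cycle max
    biphasic_min: int = 2  # events biphasic -> score 2
    neighborhood: float = 0.02  # prominence half-window, cycle fraction


@dataclass(frozen=True)
class QualityScore:
    score: int
    features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.score not in (1, 2, 3):
            raise ValueError("score must be 1, 2 or 3")


def _cycle_slice(acc: AccelerationTrace, seg: Optional[PhaseSegmentation]) -> tuple[int, int]:
    if seg is None:
        return 0, acc.n
    i0 = acc.index_at(seg.cycle_start)
    i1 = acc.index_at(seg.cycle_end) + 1
    return i0, max(i1, i0 + 2)


def acceleration_score(
    acc: AccelerationTrace,
    seg: Optional[PhaseSegmentation] = None,
    thresholds: QualityThresholds = QualityThresholds(),
) -> QualityScore:
    """Grade one cycle (or the whole trace when ``seg`` is None) 1-3.

    Rules: flatness above threshold -> 1; else two or more biphasic events
    or median shift prominence below threshold -> 2; else 3.  Without a
    segmentation the shift features cannot be computed, so a non-flat
    unsegmentable trace grades 2.
    """
    i0, i1 = _cycle_slice(acc, seg)
    a = acc.samples[i0:i1]
    if a.size == 0:
        raise ValueError("empty acceleration window")
    amax = float(np.max(np.abs(a)))
    if amax <= 1e-12:
        return QualityScore(1, {"flatness": 1.0, "shift_prominence": 0.0, "biphasic_count": 0})
    am = a - a.mean()
    lag = max(1, int(round(thresholds.flatness_lag_s * acc.sampling_rate)))
    denom = float(np.dot(am, am))
    if lag >= am.size or denom <= 0.0:
        flatness = 1.0
    else:
        rho = float(np.dot(am[:-lag], am[lag:]) / denom)
        flatness = float(np.clip(0.5 * (1.0 - rho), 0.0, 1.0))
    if flatness > thresholds.flat_threshold:
        return QualityScore(1, {"flatness": flatness, "shift_prominence": 0.0, "biphasic_count": 0})
    if seg is None:
        return QualityScore(2, {"flatness": flatness, "shift_prominence": 0.0, "biphasic_count": 0})

    n_cycle = i1 - i0
    rate = acc.sampling_rate
    prom_half = max(1, int(round(thresholds.neighborhood * n_cycle)))
    bip_half = max(1, int(round(thresholds.biphasic_window * n_cycle)))
    prominences = []
    biphasic = 0
    for b in seg.boundaries:
        j = acc.index_at(b) - i0
        lo, hi = max(0, j - prom_half), min(a.size, j + prom_half + 1)
        prominences.append(float(np.max(np.abs(a[lo:hi]))) / amax)
        lo, hi = max(0, j - bip_half), min(a.size, j + bip_half + 1)
        pos = float(np.max(a[lo:hi]))
        neg = -float(np.min(a[lo:hi]))
        major, minor = max(pos, neg), min(pos, neg)
        if major >= thresholds.biphasic_floor * amax and minor >= thresholds.biphasic_ratio * major:
            biphasic += 1
    shift_prominence = float(np.median(prominences))
    features = {
        "flatness": flatness,
        "shift_prominence": shift_prominence,
        "biphasic_count": biphasic,
    }
    if biphasic >= thresholds.biphasic_min or shift_prominence < thresholds.prominence_threshold:
        return QualityScore(2, features)
    return QualityScore(3, features)


def wall_average_score(scored: Iterable[tuple[str, QualityScore]]) -> dict[str, float]:
    """Arithmetic mean score per wall label, rounded to 2 decimals."""
    groups: dict[str, list[int]] = {}
    for label, qs in scored:
        groups.setdefault(label, []).append(qs.score)
    if not groups:
        raise ValueError("no scores provided")
    return {label: round(float(np.mean(v)), 2) for label, v in groups.items()}
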