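"""Threshold separation of end-tidal breath gas from dead-space gas.

During a full exhalation the first ~30 % of the exhaled volume is anatomical
dead-space gas (conducting-airway air, compositionally close to ambient) and
the remaining ~70 % is end-tidal (alveolar) gas — a 7:3 end-tidal:dead-space
ratio.  The separation rule works on a pre-experiment flow trace:

1. cumulative exhaled volume  V(t) = integral of Q dt,
2. dead-space volume          V2   = 0.3 (V1 + V2)  (30 % of the total),
3. t1: earliest time with     V(t1) = V2            (dead space cleared
   the flow meter),
4. t2: earliest time with     V(t2) = V(t1) + V3    (the dead-space front
   cleared the gas container of volume V3).

The expiratory flow at t2 is the subject's separation threshold: in the
formal experiment, the collection valve switches to end-tidal collection
when flow drops below it.  The pre-experiment repeats three times and the
thresholds are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ContainerUnreachableError, InsufficientExhalationError
from .flow import LMIN_TO_ML_S, FlowTrace

__all__ = [
    "DEAD_SPACE_FRACTION",
    "DeviceGeometry",
    "SegmentationResult",
    "cumulative_volume",
    "dead_space_volume",
    "find_t1",
    "find_t2",
    "separation_threshold",
    "preexperiment_threshold",
]

#: Fraction of the total exhaled volume that is anatomical dead space.
DEAD_SPACE_FRACTION = 0.3


@dataclass(frozen=True)
class DeviceGeometry:
    """Gas-path geometry: ``container_volume`` is V3, the container in mL."""

    container_volume: float = 100.0

    def __post_init__(self) -> None:
        if self.container_volume < 0:
            raise ValueError("container_volume must be non-negative")


@dataclass(frozen=True)
class SegmentationResult:
    """Volumes, switch times and flow threshold for one pre-experiment breath.

    ``v_dead`` is exactly 30 % of ``v_total`` by construction and
    ``v_endtidal`` is the remainder.  ``threshold_flow`` is the
    (interpolated) expiratory flow at ``t2`` in L/min.
    """

    v_total: float
    v_dead: float
    v_endtidal: float
    t1: float
    t2: float
    threshold_flow: float
    container_volume: float


def cumulative_volume(trace: FlowTrace) -> np.ndarray:
    """Cumulative exhaled volume in mL at each time point (trapezoidal).

    Non-decreasing, starts at 0; the last value is the total exhaled volume.
    """
    rate_ml_s = trace.flow * LMIN_TO_ML_S
    out = np.empty_like(rate_ml_s)
    out[0] = 0.0
    np.cumsum((rate_ml_s[1:] + rate_ml_s[:-1]) * 0.5 * np.diff(trace.time), out=out[1:])
    return out


def dead_space_volume(v_total: float) -> float:
    """Dead-space volume (mL) from the 30 % rule: 0.3 × total exhaled volume.

    A 500 mL exhalation carries the textbook ~150 mL of anatomical dead space.
    """
    if v_total < 0:
        raise ValueError("v_total must be non-negative")
    return DEAD_SPACE_FRACTION * v_total


def _crossing_time(trace: FlowTrace, cumvol: np.ndarray, target: float) -> float:
    """Earliest time with cumulative volume >= target, linearly interpolated.

    Linear interpolation of V(t) inside the crossing sample interval matches
    the trapezoidal reading of the sampled flow meter to first order and
    removes sample-rate bias relative to snapping to grid points.
    """
    if target <= 0:
        return float(trace.time[0])
    idx = int(np.searchsorted(cumvol, target, side="left"))
    if idx >= cumvol.size:
        raise InsufficientExhalationError(
            f"target volume {target:.3f} mL exceeds total exhaled {cumvol[-1]:.3f} mL"
        )
    if idx == 0:
        return float(trace.time[0])
    v0, v1 = cumvol[idx - 1], cumvol[idx]
    t0, t1 = trace.time[idx - 1], trace.time[idx]
    if v1 == v0:  # zero-flow plateau: earliest time in the interval
        return float(t1)
    return float(t0 + (target - v0) / (v1 - v0) * (t1 - t0))


def find_t1(trace: FlowTrace, v_dead: float) -> float:
    """Time t1 at which the dead-space volume has passed the flow meter."""
    if v_dead < 0:
        raise ValueError("v_dead must be non-negative")
    cumvol = cumulative_volume(trace)
    try:
        return _crossing_time(trace, cumvol, v_dead)
    except InsufficientExhalationError:
        raise InsufficientExhalationError(
            f"dead-space volume {v_dead:.3f} mL exceeds total exhaled "
            f"{cumvol[-1]:.3f} mL"
        ) from None


def find_t2(trace: FlowTrace, t1: float, geometry: DeviceGeometry) -> float:
    """Time t2 at which the dead-space front has cleared the gas container.

    Earliest time with V(t2) = V(t1) + V3; equals ``t1`` when V3 = 0.
    """
    if not (trace.time[0] <= t1 <= trace.time[-1]):
        raise ValueError("t1 lies outside the trace")
    cumvol = cumulative_volume(trace)
    v_at_t1 = float(np.interp(t1, trace.time, cumvol))
    target = v_at_t1 + geometry.container_volume
    if target > cumvol[-1] + 1e-9:
        raise ContainerUnreachableError(
            f"only {cumvol[-1] - v_at_t1:.3f} mL exhaled after t1, container "
            f"needs {geometry.container_volume:.3f} mL"
        )
    if geometry.container_volume == 0:
        return float(t1)
    return _crossing_time(trace, cumvol, min(target, float(cumvol[-1])))


def interpolated_flow(trace: FlowTrace, t: float) -> float:
    """Flow (L/min) at an arbitrary time, linear between samples."""
    return float(np.interp(t, trace.time, trace.flow))


def separation_threshold(trace: FlowTrace, geometry: DeviceGeometry) -> SegmentationResult:
    """Run the full separation rule on one pre-experiment breath.

    Computes the cumulative volume, applies the 30 % dead-space rule, locates
    t1 and t2, and reads the (interpolated) flow at t2 as the threshold.
    """
    cumvol = cumulative_volume(trace)
    v_total = float(cumvol[-1])
    if v_total <= 0:
        raise InsufficientExhalationError("trace exhales zero volume")
    v_dead = dead_space_volume(v_total)
    t1 = find_t1(trace, v_dead)
    t2 = find_t2(trace, t1, geometry)
    return SegmentationResult(
        v_total=v_total,
        v_dead=v_dead,
        v_endtidal=v_total - v_dead,
        t1=t1,
        t2=t2,
        threshold_flow=interpolated_flow(trace, t2),
        container_volume=geometry.container_volume,
    )


def preexperiment_threshold(
    traces: Sequence[FlowTrace], geometry: DeviceGeometry
) -> float:
    """Average separation threshold over the three pre-experiment breaths.

    The pre-experiment is repeated three times per subject and the arithmetic
    mean of the three per-breath thresholds is the subject's final threshold.
    """
    if len(traces) != 3:
        raise ValueError(f"exactly three pre-experiment traces required, got {len(traces)}")
    thresholds = []
    for i, trace in enumerate(traces):
        try:
            thresholds.append(separation_threshold(trace, geometry).threshold_flow)
        except Exception as exc:
            raise type(exc)(f"pre-experiment trace {i}: {exc}") from exc
    return float(np.mean(thresholds))
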