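"""Acquisition state machine: valve-gated end-tidal collection on a flow trace.

Mirrors the device's experiment control flow as software.  A run passes
through (a prefix of) CLEANING -> DEAD_SPACE_REMOVAL -> COLLECTION ->
DETECTION.  During DEAD_SPACE_REMOVAL the exhaled gas vents; when the
expiratory flow — having first risen above the preset threshold — drops
below it, the valve switches and everything from that instant to the end of
exhalation is stored in the container (compressed past V3 for enrichment,
never truncated).

The log quantifies dead-space contamination of the stored gas by labeling
exhaled volume by cumulative rank: the first 30 % of the total exhaled
volume is dead-space gas, the rest end-tidal.  Collecting the whole breath
therefore yields a dead fraction of exactly 0.30; a well-placed trigger
yields ~0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoTriggerError
from .flow import FlowTrace
from .separation import (
    DEAD_SPACE_FRACTION,
    DeviceGeometry,
    cumulative_volume,
    separation_threshold,
)

__all__ = [
    "AcquisitionState",
    "CollectionLog",
    "run_collection",
    "contamination_vs_threshold_error",
]


class AcquisitionState(enum.Enum):
    """Gas-path states, entered in this order, each at most once per run."""

    CLEANING = "cleaning"
    DEAD_SPACE_REMOVAL = "dead_space_removal"
    COLLECTION = "collection"
    DETECTION = "detection"


#: Pump PWM duty per state — hardware metadata only, no motor model.
PWM_DUTY = {
    AcquisitionState.CLEANING: 0.9,
    AcquisitionState.DEAD_SPACE_REMOVAL: 0.0,
    AcquisitionState.COLLECTION: 0.0,
    AcquisitionState.DETECTION: 0.2,
}


@dataclass(frozen=True)
class CollectionLog:
    """Outcome of one valve-gated collection run.

    ``collected_dead_fraction`` is the fraction of the stored gas that is
    dead-space gas under the 30 %-by-volume labeling; ``compression_ratio``
    is collected volume over container volume (inf for V3 = 0).
    """

    state_timeline: tuple[tuple[AcquisitionState, float], ...]
    trigger_time: float
    collected_volume: float
    collected_dead_fraction: float
    compression_ratio: float
    armed_time: float
    threshold: float


def _armed_trigger_time(trace: FlowTrace, threshold: float) -> tuple[float, float]:
    """(arming time, trigger time) for the armed below-threshold crossing.

    The valve arms at the first up-crossing of the threshold and fires at the
    first subsequent down-crossing, both linearly interpolated.  Arming is
    required because exhalation starts at ~zero flow: the bare rule
    "switch when flow < threshold" would fire immediately at t = 0.
    """
    flow, time = trace.flow, trace.time
    above = flow > threshold
    if not above.any():
        raise NoTriggerError(
            f"flow never exceeds threshold {threshold:.3f} L/min (peak "
            f"{flow.max():.3f} L/min)"
        )
    i_up = int(np.argmax(above))
    if i_up == 0:
        armed = float(time[0])
    else:  # interpolate the up-crossing inside [i_up-1, i_up]
        f0, f1 = flow[i_up - 1], flow[i_up]
        armed = float(np.interp(threshold, [f0, f1], [time[i_up - 1], time[i_up]]))
    below_after = (flow < threshold) & (np.arange(flow.size) >= i_up)
    if not below_after.any():
        return armed, float(time[-1])  # flow stays above: trigger at exhalation end
    i_dn = int(np.argmax(below_after))
    f0, f1 = flow[i_dn - 1], flow[i_dn]
    if f0 == f1:
        trig = float(time[i_dn])
    else:  # down-crossing: flow decreasing through the threshold
        trig = float(time[i_dn - 1] + (f0 - threshold) / (f0 - f1) * (time[i_dn] - time[i_dn - 1]))
    return armed, trig


def run_collection(
    trace: FlowTrace,
    threshold: float,
    geometry: DeviceGeometry,
    trigger_at_start: bool = False,
) -> CollectionLog:
    """Simulate one valve-gated collection of a breath.

    ``trigger_at_start`` forces whole-breath collection (the no-gating
    baseline whose dead fraction is 0.30 by construction).

    Raises
    ------
    NoTriggerError
        If the flow never rises above ``threshold`` (the valve never arms).
    ValueError
        For a non-positive ``threshold``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cumvol = cumulative_volume(trace)
    v_total = float(cumvol[-1])
    if trigger_at_start:
        armed = trig = float(trace.time[0])
    else:
        armed, trig = _armed_trigger_time(trace, threshold)
    v_at_trig = float(np.interp(trig, trace.time, cumvol))
    collected = v_total - v_at_trig
    v_dead = DEAD_SPACE_FRACTION * v_total
    dead_collected = max(0.0, v_dead - v_at_trig)
    dead_fraction = dead_collected / collected if collected > 0 else 0.0
    v3 = geometry.container_volume
    timeline = (
        (AcquisitionState.CLEANING, float(trace.time[0])),
        (AcquisitionState.DEAD_SPACE_REMOVAL, float(trace.time[0])),
        (AcquisitionState.COLLECTION, trig),
        (AcquisitionState.DETECTION, float(trace.time[-1])),
    )
    return CollectionLog(
        state_timeline=timeline,
        trigger_time=trig,
        collected_volume=collected,
        collected_dead_fraction=dead_fraction,
        compression_ratio=collected / v3 if v3 > 0 else float("inf"),
        armed_time=armed,
        threshold=threshold,
    )


def contamination_vs_threshold_error(
    trace: FlowTrace,
    geometry: DeviceGeometry,
    relative_errors: list[float],
) -> pd.DataFrame:
    """Sensitivity of contamination to threshold mis-estimation.

    For each relative error eps, runs the collection at (1+eps) times the
    trace's true separation threshold and tabulates the resulting dead
    fraction and collected volume.  Rows where the perturbed threshold fails
    to trigger (or is non-positive) carry NaNs and the error name.
    """
    if not all(np.isfinite(relative_errors)):
        raise ValueError("relative_errors must be finite")
    true_thr = separation_threshold(trace, geometry).threshold_flow
    rows = []
    for eps in relative_errors:
        thr = (1.0 + eps) * true_thr
        row: dict = {"relative_error": eps, "threshold": thr}
        try:
            log = run_collection(trace, thr, geometry)
            row.update(
                collected_dead_fraction=log.collected_dead_fraction,
                collected_volume=log.collected_volume,
                trigger_time=log.trigger_time,
                error=None,
            )
        except (NoTriggerError, ValueError) as exc:
            row.update(
                collected_dead_fraction=np.nan,
                collected_volume=np.nan,
                trigger_time=np.nan,
                error=type(exc).__name__,
            )
        rows.append(row)
    columns = [
        "relative_error",
        "threshold",
        "collected_dead_fraction",
        "collected_volume",
        "trigger_time",
        "error",
    ]
    return pd.DataFrame(rows, columns=columns)
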