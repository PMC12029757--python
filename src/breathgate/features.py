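"""Preprocessing and feature extraction for sensor-array response curves.

Each 10-channel conductivity-ratio record is mean-filtered and summarized by
five per-channel features, giving the 50-dimensional descriptor the
classifiers consume (sensor-major order):

1. ``intratio`` — integration ratio: area under (ratio - 1) over the
   detection window, divided by the window duration.  Time-normalizing makes
   it invariant to the record length.
2. ``maxloc`` — location of the response maximum as a fraction of the
   window (0 at the start, 1 at the end).
3. ``maxderiv`` — maximum first-order finite difference of the curve,
   per second.
4. ``f1``, ``f2`` — magnitudes of the first two non-DC discrete-Fourier
   coefficients of the mean-removed curve, a coarse spectral shape summary.

Features 1 and 3–5 are exactly zero for a flat clean-air record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import HealthLabel, SensorResponse
from .errors import DomainError

__all__ = [
    "FEATURE_SUFFIXES",
    "FeatureVector",
    "mean_filter",
    "extract_features",
    "feature_table",
    "per_sensor_integral_ratio_summary",
    "feature_names",
]

FEATURE_SUFFIXES = ("intratio", "maxloc", "maxderiv", "f1", "f2")


def feature_names(n_sensors: int = 10) -> list[str]:
    """Column labels in sensor-major order: s01_intratio ... s10_f2."""
    return [f"s{i:02d}_{suf}" for i in range(1, n_sensors + 1) for suf in FEATURE_SUFFIXES]


@dataclass(frozen=True)
class FeatureVector:
    """50-element descriptor of one detection cycle (10 sensors x 5 features)."""

    values: np.ndarray
    names: tuple[str, ...]
    label: HealthLabel | None = None
    subject_id: str = "anonymous"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (50,) or len(self.names) != 50:
            raise ValueError("a feature vector has exactly 50 values and names")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")


def mean_filter(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with symmetric window shrinkage at the edges.

    ``window`` must be odd and positive; ``window = 1`` is the identity.  At
    position i the half-width shrinks to min(w//2, i, n-1-i), so edge samples
    average over whatever symmetric neighborhood exists.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    if window == 1:
        return x.copy()
    half = window // 2
    n = x.size
    out = np.empty(n)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def extract_features(response: SensorResponse, filter_window: int = 5) -> FeatureVector:
    """Extract the five per-channel features after mean filtering.

    Raises
    ------
    DomainError
        If the record has fewer than 8 time samples (no meaningful spectrum).
    """
    time, ratio = response.time, response.ratio
    if time.size < 8:
        raise DomainError(f"record has {time.size} samples; at least 8 required")
    duration = float(time[-1] - time[0])
    dt = float(time[1] - time[0])
    values = np.empty(50)
    for ch in range(ratio.shape[1]):
        y = mean_filter(ratio[:, ch], filter_window)
        excess = y - 1.0
        intratio = float(np.trapezoid(excess, time)) / duration
        maxloc = float(time[int(np.argmax(y))] - time[0]) / duration
        maxderiv = float(np.max(np.diff(y))) / dt
        spectrum = np.abs(np.fft.rfft(y - y.mean()))
        f1, f2 = float(spectrum[1]), float(spectrum[2])
        values[5 * ch : 5 * ch + 5] = (intratio, maxloc, maxderiv, f1, f2)
    return FeatureVector(
        values=values,
        names=tuple(feature_names(ratio.shape[1])),
        subject_id=response.subject_id,
    )


def feature_table(
    responses: list[SensorResponse],
    labels: list[HealthLabel] | None = None,
    filter_window: int = 5,
) -> pd.DataFrame:
    """Assemble one labeled feature row per response.

    Columns: ``subject_id``, ``label`` (empty string if unlabeled), then the
    50 feature columns in sensor-major order.  Row order follows the input.
    """
    if labels is not None and len(labels) != len(responses):
        raise ValueError("responses and labels must have equal length")
    cols = feature_names()
    rows = []
    for i, resp in enumerate(responses):
        fv = extract_features(resp, filter_window)
        row = {"subject_id": resp.subject_id,
               "label": labels[i].value if labels is not None else ""}
        row.update(zip(cols, fv.values))
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "label", *cols])


def per_sensor_integral_ratio_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Box-plot statistics of the integral-ratio feature, per sensor x class.

    Returns one row per (sensor, label) with median, mean, q1, q3 and iqr of
    that sensor's ``intratio`` column — the distributional comparison that
    shows whether the array separates the health classes at all.  Classes
    with no rows are omitted with a warning.
    """
    if "label" not in table.columns or (table["label"] == "").all():
        raise ValueError("table must carry class labels")
    import warnings

    rows = []
    present = [lbl for lbl in HealthLabel if (table["label"] == lbl.value).any()]
    missing = [lbl for lbl in HealthLabel if lbl not in present]
    if missing:
        warnings.warn(f"classes with no samples omitted: {[m.value for m in missing]}")
    for sensor in range(1, 11):
        col = f"s{sensor:02d}_intratio"
        for lbl in present:
            vals = table.loc[table["label"] == lbl.value, col].to_numpy()
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {
                    "sensor": f"s{sensor:02d}",
                    "label": lbl.value,
                    "median": med,
                    "mean": float(vals.mean()),
                    "q1": q1,
                    "q3": q3,
                    "iqr": q3 - q1,
                    "n": vals.size,
                }
            )
    return pd.DataFrame(rows)
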