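"""Expiratory flow traces and synthetic single-exhalation generation.

A single exhalation, as seen by an inline flow meter, is a rapid rise of
expiratory flow to a peak followed by a roughly exponential decay.  Flow is
carried in L/min (the natural unit of clinical flow meters); all volume
arithmetic converts to mL/s at one point (:data:`LMIN_TO_ML_S`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LMIN_TO_ML_S",
    "FlowTrace",
    "BreathProfile",
    "generate_breath",
    "constant_flow_trace",
]

#: L/min -> mL/s.  The single flow/volume unit-conversion point of the package.
LMIN_TO_ML_S = 1000.0 / 60.0


@dataclass(frozen=True)
class FlowTrace:
    """Uniformly sampled expiratory flow versus time for one exhalation.

    Parameters
    ----------
    time
        Sample times in seconds, starting at 0, strictly increasing with a
        constant step.
    flow
        Expiratory flow in L/min, one value per time point, non-negative.
    subject_id
        Opaque identifier of the exhaling subject.
    """

    time: np.ndarray
    flow: np.ndarray
    subject_id: str = "anonymous"

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        flow = np.asarray(self.flow, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "flow", flow)
        if time.ndim != 1 or flow.ndim != 1 or time.shape != flow.shape:
            raise ValueError("time and flow must be 1-D arrays of equal length")
        if time.size < 2:
            raise ValueError("a flow trace needs at least 2 samples")
        if not (np.all(np.isfinite(time)) and np.all(np.isfinite(flow))):
            raise ValueError("flow trace contains non-finite values")
        steps = np.diff(time)
        if np.any(steps <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time must be uniformly spaced")
        if np.any(flow < 0):
            raise ValueError("flow must be non-negative everywhere")

    @property
    def dt(self) -> float:
        """Sampling step in seconds."""
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return float(self.time[-1] - self.time[0])

    def total_volume_ml(self) -> float:
        """Trapezoidal integral of flow over the trace, in mL."""
        return float(np.trapezoid(self.flow * LMIN_TO_ML_S, self.time))


@dataclass(frozen=True)
class BreathProfile:
    """Parametric shape of a synthetic exhalation.

    The canonical curve is a linear rise to ``peak_flow`` over ``rise_time``
    followed by exponential decay with time constant ``decay_constant``; the
    amplitude is rescaled so the trapezoidal integral hits ``total_volume``.
    ``peak_flow`` therefore sets the pre-rescaling shape only.
    """

    total_volume: float = 500.0  # mL
    peak_flow: float = 30.0  # L/min (shape parameter; rescaled)
    rise_time: float = 0.4  # s
    decay_constant: float = 1.0  # s
    duration: float = 4.0  # s
    noise_sd: float = 0.0  # L/min, additive Gaussian, clipped at 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_volume <= 0:
            raise ValueError("total_volume must be positive")
        if not (self.duration > self.rise_time > 0):
            raise ValueError("need duration > rise_time > 0")
        if self.decay_constant <= 0:
            raise ValueError("decay_constant must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_breath(
    profile: BreathProfile, sample_rate: float = 100.0, subject_id: str = "anonymous"
) -> FlowTrace:
    """Generate a synthetic single-exhalation flow trace.

    The noiseless curve rises linearly to a single peak and decays
    exponentially; its amplitude is rescaled so the trapezoidal volume equals
    ``profile.total_volume`` (within discretization error, well under 1 % at
    the default 100 Hz).  Additive Gaussian noise of ``profile.noise_sd``
    (L/min) is then applied and clipped at zero.

    Raises
    ------
    ValueError
        For a non-positive ``sample_rate`` (profile validity is enforced by
        :class:`BreathProfile` itself).
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    n = int(round(profile.duration * sample_rate)) + 1
    time = np.arange(n) / sample_rate
    shape = np.where(
        time <= profile.rise_time,
        profile.peak_flow * time / profile.rise_time,
        profile.peak_flow * np.exp(-(time - profile.rise_time) / profile.decay_constant),
    )
    volume = np.trapezoid(shape * LMIN_TO_ML_S, time)
    flow = shape * (profile.total_volume / volume)
    if profile.noise_sd > 0:
        rng = np.random.default_rng(profile.seed)
        flow = flow + rng.normal(0.0, profile.noise_sd, size=flow.shape)
        flow = np.clip(flow, 0.0, None)
    return FlowTrace(time=time, flow=flow, subject_id=subject_id)


def constant_flow_trace(
    flow: float, duration: float, sample_rate: float = 100.0, subject_id: str = "anonymous"
) -> FlowTrace:
    """Constant-flow trace: the closed-form fixture for volume arithmetic.

    30 L/min is exactly 500 mL/s, so one second of 30 L/min exhales 500 mL.
    """
    if flow < 0:
        raise ValueError("flow must be non-negative")
    if duration <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample_rate must be positive")
    n = int(round(duration * sample_rate)) + 1
    time = np.arange(n) / sample_rate
    return FlowTrace(time=time, flow=np.full(n, float(flow)), subject_id=subject_id)
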