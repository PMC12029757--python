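"""Synthetic study generator: health labels, breath VOC mixtures, and
10-channel MOS sensor responses.

The generator emulates the statistical structure the downstream classifier
assumes rather than any particular chemistry:

* Health status comes from a six-item self-assessed scale (each item 0–10,
  total 0–60; <=45 poor, 46–55 good, >=56 excellent).
* Each subject exhales a seven-gas alveolar mixture (hydrogen, methane,
  hydrogen sulfide, carbon monoxide, propane, acetone, ethanol — the
  endogenous breath biomarkers a MOS array targets).  Concentrations are
  log-normal; the class log-means are displaced along fixed per-gas patterns
  by ``effect_size`` standard deviations.
* Dead-space contamination dilutes the analyzed aliquot toward ambient air:
  c_analyzed = (1 - f) * c_alveolar + f * c_ambient.  Because dead-space gas
  is essentially ambient air, ambient levels are near zero for the
  endogenous markers (atmospheric methane being the exception).
* A 10-sensor MOS array responds with a saturating power law at steady state
  (ratio = 1 + sum_j s_ij * c_j**alpha) and first-order rise/recovery
  kinetics, multiplicative noise on top.  Conductivity is reported as the
  ratio G_gas / G_air, which normalizes away baseline and drift.
"""

from __future__ import annotations

import enum
import zlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GAS_NAMES",
    "SENSOR_NAMES",
    "HealthLabel",
    "ScaleResponse",
    "GasSample",
    "SensorResponse",
    "SensorKinetics",
    "score_scale",
    "label_from_score",
    "generate_cohort",
    "sensor_response",
    "conductivity_ratio",
]

GAS_NAMES = (
    "hydrogen",
    "methane",
    "hydrogen_sulfide",
    "carbon_monoxide",
    "propane",
    "acetone",
    "ethanol",
)

SENSOR_NAMES = tuple(f"ch{i:02d}" for i in range(1, 11))

#: Typical alveolar levels, ppm (order of GAS_NAMES).
BASELINE_PPM = np.array([15.0, 8.0, 0.01, 2.0, 0.1, 0.6, 0.3])

#: Ambient (dead-space) levels, ppm.  Endogenous markers near zero;
#: atmospheric methane ~2 ppm and trace CO/H2 persist outdoors.
AMBIENT_PPM = np.array([0.5, 2.0, 0.0, 0.2, 0.0, 0.001, 0.001])

#: Log-scale SD of each gas across subjects within a class.
LOG_SD = 0.4

#: Class displacement patterns (rows: POOR, GOOD, EXCELLENT), unit rows.
#: Multiplied by effect_size * LOG_SD and added to the baseline log-mean.
#: Poor health elevates the gut/oxidative markers (H2, H2S, CO, propane);
#: excellent health runs low on the metabolic VOCs (acetone, ethanol).  The
#: two displacement directions are near-orthogonal, so no class sits on the
#: line between the other two.
_CLASS_PATTERN = np.array(
    [
        [+0.6, +0.2, +0.5, +0.4, +0.3, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, -0.2, 0.0, 0.0, 0.0, -0.7, -0.6],
    ]
)
_CLASS_PATTERN = np.where(
    np.linalg.norm(_CLASS_PATTERN, axis=1, keepdims=True) > 0,
    _CLASS_PATTERN
    / np.maximum(np.linalg.norm(_CLASS_PATTERN, axis=1, keepdims=True), 1e-12),
    0.0,
)

#: 10 x 7 sensitivity matrix mapping gases to sensors.  Rows are sensors,
#: columns GAS_NAMES.  Deliberately overlapping (cross-sensitive): every
#: sensor sees several gases, which is why an array plus pattern recognition
#: is needed at all.  Units: (ratio - 1) per ppm**alpha.
SENSITIVITY = np.array(
    [
        # H2    CH4   H2S   CO    C3H8  acet  EtOH
        [0.60, 0.05, 0.10, 0.05, 0.02, 0.01, 0.02],  # ch01 hydrogen-leaning
        [0.10, 0.55, 0.02, 0.05, 0.15, 0.01, 0.02],  # ch02 methane-leaning
        [0.05, 0.02, 0.90, 0.05, 0.01, 0.02, 0.03],  # ch03 sulfide-leaning
        [0.08, 0.05, 0.05, 0.60, 0.05, 0.02, 0.05],  # ch04 CO-leaning
        [0.05, 0.20, 0.02, 0.05, 0.55, 0.02, 0.03],  # ch05 propane-leaning
        [0.02, 0.01, 0.05, 0.03, 0.02, 0.70, 0.15],  # ch06 acetone-leaning
        [0.03, 0.02, 0.03, 0.05, 0.03, 0.20, 0.65],  # ch07 ethanol-leaning
        [0.30, 0.25, 0.10, 0.20, 0.20, 0.10, 0.10],  # ch08 broad reducing
        [0.10, 0.10, 0.30, 0.10, 0.05, 0.30, 0.30],  # ch09 broad VOC
        [0.20, 0.15, 0.15, 0.25, 0.10, 0.15, 0.20],  # ch10 broad mixed
    ]
)


class HealthLabel(enum.Enum):
    """Three-level self-assessed health status."""

    POOR = "poor"
    GOOD = "good"
    EXCELLENT = "excellent"


_LABEL_ORDER = (HealthLabel.POOR, HealthLabel.GOOD, HealthLabel.EXCELLENT)


@dataclass(frozen=True)
class ScaleResponse:
    """Six self-assessed item scores, each an integer 0–10."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 6:
            raise ValueError("a scale response has exactly 6 items")
        for v in self.items:
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 10):
                raise ValueError(f"item score {v!r} outside [0, 10]")


@dataclass(frozen=True)
class GasSample:
    """Analyzed gas aliquot of one subject.

    ``concentrations`` are the post-dilution ppm levels actually presented to
    the sensor array; ``dead_fraction`` is the realized contamination of this
    aliquot (0 = pure end-tidal, 1 = pure ambient/dead-space air).
    """

    concentrations: np.ndarray
    label: HealthLabel
    dead_fraction: float
    subject_id: str
    score: int = -1

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        if conc.shape != (len(GAS_NAMES),):
            raise ValueError(f"expected {len(GAS_NAMES)} gas concentrations")
        if np.any(conc < 0) or not np.all(np.isfinite(conc)):
            raise ValueError("concentrations must be finite and non-negative")
        if not (0.0 <= self.dead_fraction <= 1.0):
            raise ValueError("dead_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SensorResponse:
    """time x 10-channel conductivity-ratio matrix for one detection cycle."""

    time: np.ndarray
    ratio: np.ndarray
    channel_names: tuple[str, ...] = SENSOR_NAMES
    subject_id: str = "anonymous"

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        ratio = np.asarray(self.ratio, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "ratio", ratio)
        if ratio.ndim != 2 or ratio.shape != (time.size, len(self.channel_names)):
            raise ValueError("ratio must be time x channels")
        if len(self.channel_names) != 10:
            raise ValueError("the sensor array has exactly 10 channels")
        if np.any(ratio <= 0):
            raise ValueError("conductivity ratios must be positive")
        if not np.allclose(ratio[0], 1.0):
            raise ValueError("ratio must equal 1 at t = 0 (clean-air baseline)")


@dataclass(frozen=True)
class SensorKinetics:
    """Temporal model of the detection cycle.

    During exposure each channel rises toward its steady-state ratio as the
    sum of a fast first-order component (surface reaction, time constant
    ``rise_tau_s``) and a slower first-order component (bulk diffusion,
    ``slow_tau_s`` with weight ``slow_weight``) — the two-time-constant
    transient typical of MOS sensors, which keeps the response creeping
    upward until the exposure ends.  Recovery is first-order back toward 1.
    ``alpha`` is the power-law exponent of the steady-state concentration
    response (0.5 is typical MOS behavior).
    """

    exposure_s: float = 40.0
    recovery_s: float = 20.0
    sample_rate: float = 5.0
    alpha: float = 0.5
    rise_tau_s: tuple[float, ...] = (4.0, 5.0, 3.5, 6.0, 5.5, 4.5, 5.0, 6.5, 4.0, 5.5)
    recovery_tau_s: tuple[float, ...] = (8.0, 10.0, 7.0, 12.0, 11.0, 9.0, 10.0, 13.0, 8.0, 11.0)
    slow_weight: float = 0.3
    slow_tau_s: float = 40.0
    noise_sd: float = 0.01  # multiplicative, relative

    def __post_init__(self) -> None:
        if self.exposure_s <= 0 or self.recovery_s < 0 or self.sample_rate <= 0:
            raise ValueError("exposure, recovery and sample_rate must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0 <= self.slow_weight < 1) or self.slow_tau_s <= 0:
            raise ValueError("slow_weight must be in [0, 1) with positive slow_tau_s")
        if len(self.rise_tau_s) != 10 or len(self.recovery_tau_s) != 10:
            raise ValueError("need one rise/recovery time constant per channel")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def score_scale(response: ScaleResponse) -> int:
    """Total scale score: the sum of the six item scores, in [0, 60]."""
    return int(sum(response.items))


def label_from_score(total: int) -> HealthLabel:
    """Map a total score to the three-level health label.

    Bands: below 45 poor, 46–55 good, 56 and above excellent.  A total of
    exactly 45 falls between the published bands and is assigned to POOR
    (the conservative choice), which makes the split <=45 / 46–55 / >=56.
    """
    if not (0 <= total <= 60):
        raise ValueError(f"total score {total} outside [0, 60]")
    if total <= 45:
        return HealthLabel.POOR
    if total <= 55:
        return HealthLabel.GOOD
    return HealthLabel.EXCELLENT


_SCORE_RANGES = {
    HealthLabel.POOR: (20, 45),
    HealthLabel.GOOD: (46, 55),
    HealthLabel.EXCELLENT: (56, 60),
}


def _draw_scale_items(rng: np.random.Generator, label: HealthLabel) -> ScaleResponse:
    """Random six-item response whose total lands in the label's band."""
    lo, hi = _SCORE_RANGES[label]
    total = int(rng.integers(lo, hi + 1))
    # distribute `total` over 6 items, each capped at 10 (bounds keep it feasible)
    items = [0] * 6
    remaining = total
    for i in range(6):
        lo_i = max(0, remaining - 10 * (5 - i))
        hi_i = min(10, remaining)
        items[i] = int(rng.integers(lo_i, hi_i + 1))
        remaining -= items[i]
    return ScaleResponse(items=tuple(items))


def generate_cohort(
    n: int = 115,
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    effect_size: float = 4.0,
    dead_fraction: float = 0.0,
    seed: int = 0,
    dead_fraction_jitter: float = 0.6,
) -> list[GasSample]:
    """Generate a seeded synthetic cohort of analyzed gas samples.

    Parameters
    ----------
    n
        Cohort size; the default mirrors a 115-subject study.
    class_mix
        Proportions of (poor, good, excellent); must sum to 1.
    effect_size
        Separation of adjacent class log-means in units of the within-class
        log-SD, applied along fixed per-gas patterns.
    dead_fraction
        Nominal contamination f of every analyzed aliquot; each subject's
        realized f is jittered with sd ``dead_fraction_jitter * f * (1 - f)``
        (so f = 0 and f = 1 stay exact).  Without flow-gated valve timing
        the dead-space share of the stored gas tracks each breath's volume
        and maneuver, so contamination varies substantially around its
        nominal level — the variability the threshold-gated collection
        removes.  Analyzed concentrations are (1 - f) * alveolar +
        f * ambient.
    seed
        Seeds every random draw; identical seeds give identical cohorts.
        The jitter uses an independent stream, so cohorts generated at
        different ``dead_fraction`` but the same seed share identical
        labels and alveolar concentrations (paired comparisons).
    """
    if n < 3:
        raise ValueError("cohort size must be at least 3")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (3,) or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
        raise ValueError("class_mix must be 3 non-negative proportions summing to 1")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    if not (0.0 <= dead_fraction <= 1.0):
        raise ValueError("dead_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rng_jitter = np.random.default_rng((seed, 1))
    counts = np.floor(mix * n).astype(int)
    while counts.sum() < n:  # largest-remainder rounding
        counts[np.argmax(mix * n - counts)] += 1
    log_base = np.log(BASELINE_PPM)
    samples: list[GasSample] = []
    idx = 0
    for cls, label in enumerate(_LABEL_ORDER):
        log_mean = log_base + effect_size * LOG_SD * _CLASS_PATTERN[cls]
        for _ in range(int(counts[cls])):
            scale = _draw_scale_items(rng, label)
            alveolar = np.exp(rng.normal(log_mean, LOG_SD))
            f = dead_fraction
            if 0.0 < f < 1.0 and dead_fraction_jitter > 0:
                f = float(
                    np.clip(
                        rng_jitter.normal(f, dead_fraction_jitter * f * (1.0 - f)),
                        0.0,
                        1.0,
                    )
                )
            analyzed = (1.0 - f) * alveolar + f * AMBIENT_PPM
            samples.append(
                GasSample(
                    concentrations=analyzed,
                    label=label,
                    dead_fraction=f,
                    subject_id=f"S{idx:03d}",
                    score=score_scale(scale),
                )
            )
            idx += 1
    return samples


def steady_state_ratio(concentrations: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Closed-form steady-state conductivity ratio per channel.

    ratio_i = 1 + sum_j s_ij * c_j**alpha.
    """
    c = np.asarray(concentrations, dtype=float)
    return 1.0 + SENSITIVITY @ np.power(c, alpha)


def sensor_response(
    sample: GasSample,
    kinetics: SensorKinetics | None = None,
    seed: int | None = None,
) -> SensorResponse:
    """Simulate one detection cycle of the 10-channel MOS array.

    Each channel rises first-order toward its steady-state ratio during the
    exposure phase and recovers first-order toward 1 afterwards, with
    multiplicative Gaussian noise (the t = 0 clean-air sample is exact).
    ``seed`` defaults to a hash of the subject id for reproducibility.
    """
    k = kinetics or SensorKinetics()
    if seed is None:  # stable across processes, unlike the builtin str hash
        seed = zlib.crc32(sample.subject_id.encode()) % (2**31)
    rng = np.random.default_rng(seed)
    n = int(round((k.exposure_s + k.recovery_s) * k.sample_rate)) + 1
    time = np.arange(n) / k.sample_rate
    ss = steady_state_ratio(sample.concentrations, k.alpha)  # (10,)
    rise_tau = np.asarray(k.rise_tau_s)
    rec_tau = np.asarray(k.recovery_tau_s)
    t = time[:, None]
    w = k.slow_weight

    def rise(tt):  # fast + slow first-order components, both -> 1 as t -> inf
        return (1 - w) * (1.0 - np.exp(-tt / rise_tau)) + w * (
            1.0 - np.exp(-tt / k.slow_tau_s)
        )

    exposure = 1.0 + (ss - 1.0) * rise(t)
    r_end = 1.0 + (ss - 1.0) * rise(np.array([[k.exposure_s]]))
    recovery = 1.0 + (r_end - 1.0) * np.exp(-(t - k.exposure_s) / rec_tau)
    ratio = np.where(t <= k.exposure_s, exposure, recovery)
    if k.noise_sd > 0:
        ratio = ratio * (1.0 + rng.normal(0.0, k.noise_sd, size=ratio.shape))
        ratio = np.clip(ratio, 1e-6, None)
    ratio[0] = 1.0  # clean-air baseline is exact by definition of the ratio
    return SensorResponse(time=time, ratio=ratio, subject_id=sample.subject_id)


def conductivity_ratio(g_gas: float, g_air: float) -> float:
    """Rg = G_gas / G_air: sensor conductance in sample gas over clean air."""
    if g_air <= 0:
        raise ValueError("g_air must be positive")
    return g_gas / g_air
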