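"""File formats, run configuration, and the end-to-end experiment runner.

CSV carries tabular data (flow traces, sensor responses, feature tables),
JSON carries reports and manifests; both are diffable plain text.  All times
are 0-based seconds, volumes mL, flows L/min at every interface.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as _cohort
from . import features as _features
from . import learn as _learn
from .acquisition import run_collection
from .cohort import (
    HealthLabel,
    SensorKinetics,
    generate_cohort,
    sensor_response,
)
from .errors import FormatError
from .flow import BreathProfile, FlowTrace, generate_breath
from .learn import EvaluationReport, GAConfig, LDAPipeline, cross_validate, ga_optimize
from .separation import DeviceGeometry, preexperiment_threshold

__all__ = [
    "read_flow_csv",
    "write_flow_csv",
    "read_sensor_csv",
    "write_sensor_csv",
    "RunConfig",
    "run_experiment",
]

logger = logging.getLogger("breathgate")

FLOW_HEADER = ["time_s", "flow_l_min"]


def write_flow_csv(trace: FlowTrace, path) -> None:
    """Write a flow trace as `time_s,flow_l_min` with full decimal precision."""
    df = pd.DataFrame({"time_s": trace.time, "flow_l_min": trace.flow})
    df.to_csv(path, index=False, float_format="%.17g")


def read_flow_csv(path, subject_id: str | None = None) -> FlowTrace:
    """Read a `time_s,flow_l_min` CSV back into a :class:`FlowTrace`.

    Raises
    ------
    FormatError
        For a missing/wrong header, an empty file, non-monotone time or
        negative flow — naming the offending row where applicable.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if list(df.columns) != FLOW_HEADER:
        raise FormatError(f"{path}: expected header {','.join(FLOW_HEADER)}, "
                          f"got {','.join(map(str, df.columns))}")
    if len(df) < 2:
        raise FormatError(f"{path}: fewer than 2 samples")
    time = df["time_s"].to_numpy(dtype=float)
    flow = df["flow_l_min"].to_numpy(dtype=float)
    bad = np.where(np.diff(time) <= 0)[0]
    if bad.size:  # sample bad[0]+1 breaks monotonicity; +1 header, 1-based
        raise FormatError(f"{path}: non-increasing time at row {bad[0] + 3}")
    bad = np.where(flow < 0)[0]
    if bad.size:
        raise FormatError(f"{path}: negative flow at row {bad[0] + 1}")
    try:
        return FlowTrace(time=time, flow=flow, subject_id=subject_id or path.stem)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_sensor_csv(response: _cohort.SensorResponse, path) -> None:
    """Write a detection cycle as `time_s,ch01..ch10`."""
    df = pd.DataFrame(response.ratio, columns=list(response.channel_names))
    df.insert(0, "time_s", response.time)
    df.to_csv(path, index=False, float_format="%.17g")


def read_sensor_csv(path, subject_id: str | None = None) -> _cohort.SensorResponse:
    """Read a `time_s,ch01..ch10` CSV back into a :class:`SensorResponse`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    expected = ["time_s", *_cohort.SENSOR_NAMES]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected header {','.join(expected)}")
    try:
        return _cohort.SensorResponse(
            time=df["time_s"].to_numpy(dtype=float),
            ratio=df[list(_cohort.SENSOR_NAMES)].to_numpy(dtype=float),
            subject_id=subject_id or path.stem,
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end synthetic experiment needs, fully seeded."""

    n_subjects: int = 115
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    effect_size: float = 4.0
    dead_fraction_override: float | None = None  # None: use simulated collection
    container_volume_ml: float = 100.0
    breath: BreathProfile = field(default_factory=BreathProfile)
    breath_volume_sd_ml: float = 80.0  # between-subject lung-capacity spread
    kinetics: SensorKinetics = field(default_factory=SensorKinetics)
    filter_window: int = 5
    classifier: str = "svm"
    use_ga: bool = True
    ga: GAConfig = field(default_factory=GAConfig)
    c: float = 1.0
    gamma: float = 1.0
    folds: int = 5
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("breath"), dict):
            d["breath"] = BreathProfile(**d["breath"])
        if isinstance(d.get("kinetics"), dict):
            k = dict(d["kinetics"])
            for key in ("rise_tau_s", "recovery_tau_s"):
                if key in k:
                    k[key] = tuple(k[key])
            d["kinetics"] = SensorKinetics(**k)
        if isinstance(d.get("ga"), dict):
            g = dict(d["ga"])
            for key in ("c_range", "gamma_range"):
                if key in g:
                    g[key] = tuple(g[key])
            d["ga"] = GAConfig(**g)
        if isinstance(d.get("class_mix"), list):
            d["class_mix"] = tuple(d["class_mix"])
        return cls(**d)


def _subject_threshold_and_contamination(
    rng: np.random.Generator, config: RunConfig, subject_id: str
) -> tuple[float, float]:
    """Pre-experiment (3 breaths -> mean threshold) plus one gated collection."""
    geometry = DeviceGeometry(config.container_volume_ml)
    base = config.breath
    volume = max(150.0, rng.normal(base.total_volume, config.breath_volume_sd_ml))
    traces = []
    for _ in range(4):  # 3 pre-experiment breaths + 1 formal breath
        profile = dataclasses.replace(
            base,
            total_volume=max(120.0, rng.normal(volume, 25.0)),
            decay_constant=base.decay_constant * float(rng.uniform(0.9, 1.1)),
            seed=int(rng.integers(0, 2**31)),
        )
        traces.append(generate_breath(profile, subject_id=subject_id))
    threshold = preexperiment_threshold(traces[:3], geometry)
    log = run_collection(traces[3], threshold, geometry)
    return threshold, log.collected_dead_fraction


def run_experiment(config: RunConfig) -> EvaluationReport:
    """Run the five experiment stages end to end on a synthetic cohort.

    Per subject: three pre-experiment breaths determine the averaged
    separation threshold; a formal breath is collected through the valve
    state machine, yielding the realized dead-space contamination; a gas
    sample at that contamination drives the 10-channel sensor array; the
    50 features are extracted.  The labeled feature table then goes through
    stratified cross-validation of the chosen LDA pipeline.  When
    ``dead_fraction_override`` is set, it replaces the simulated
    contamination for every subject (0 = ideal end-tidal collection,
    0.3 = whole-breath collection).

    Artifacts (feature table CSV, report JSON, manifest with all seeds) are
    written to ``config.out_dir`` when set.
    """
    rng = np.random.default_rng(config.seed)
    thresholds, contaminations = [], []
    for i in range(config.n_subjects):
        thr, frac = _subject_threshold_and_contamination(rng, config, f"S{i:03d}")
        thresholds.append(thr)
        contaminations.append(frac)
    if config.dead_fraction_override is not None:
        nominal = config.dead_fraction_override
        samples = generate_cohort(
            n=config.n_subjects,
            class_mix=config.class_mix,
            effect_size=config.effect_size,
            dead_fraction=nominal,
            seed=config.seed,
        )
    else:
        # realized contamination from the simulated collections, per subject
        samples = generate_cohort(
            n=config.n_subjects,
            class_mix=config.class_mix,
            effect_size=config.effect_size,
            dead_fraction=0.0,
            seed=config.seed,
        )
        amb = _cohort.AMBIENT_PPM
        samples = [
            dataclasses.replace(
                s,
                concentrations=(1 - f) * s.concentrations + f * amb,
                dead_fraction=f,
            )
            for s, f in zip(samples, contaminations)
        ]
    responses = [
        sensor_response(s, config.kinetics, seed=int(rng.integers(0, 2**31)))
        for s in samples
    ]
    table = _features.feature_table(
        responses, [s.label for s in samples], config.filter_window
    )
    X = table[_features.feature_names()].to_numpy()
    y = table["label"].to_numpy()
    if config.classifier == "svm" and config.use_ga:
        best_c, best_gamma, history = ga_optimize(
            X, y, config.ga,
            pipeline_factory=lambda c, g: LDAPipeline("svm", c=c, gamma=g),
        )
        logger.info("GA best c=%.4g gamma=%.4g (final fitness %.3f)",
                    best_c, best_gamma, history[-1])
    else:
        best_c, best_gamma, history = config.c, config.gamma, []
    factory = lambda: LDAPipeline(
        config.classifier, c=best_c, gamma=best_gamma, seed=config.seed
    )
    report = cross_validate(factory, X, y, config.folds, config.seed)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "features.csv", index=False)
        manifest = {
            "config": _jsonable(config.to_dict()),
            "thresholds_l_min": thresholds,
            "contamination_fractions": contaminations,
            "ga": {"c": best_c, "gamma": best_gamma, "history": history},
            "report": report.to_dict(),
        }
        (out / "report.json").write_text(json.dumps(manifest, indent=2))
        logger.info("wrote %s", out / "report.json")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
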