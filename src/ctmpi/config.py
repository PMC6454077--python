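"""Experiment configuration: defaults, YAML loading and object builders.

The configuration is a nested mapping with sections ``aif``, ``tissue``,
``simulation``, ``noise``, ``hearts``, ``ischemic_segments``, ``grades``,
``schemes``, ``estimation`` and ``experiment``.  Every default below can be
overridden from a YAML file; unknown keys are rejected with the offending
key named.
"""

from __future__ import annotations

import copy
import logging
from pathlib import Path

import yaml

from .errors import ConfigError
from .estimators import UpslopeConfig
from .kinetics import (
    AifParameters,
    GRADE_LABELS,
    HeartPhantom,
    StenosisGrade,
    TissueKinetics,
    _validate_grade_order,
)
from .sampling import SamplingScheme, ScanMode

__all__ = ["default_config", "load_config", "validate_config", "build_objects"]

log = logging.getLogger(__name__)

#: Default study conditions: 60 s scans started 5 s before a 15 mL @ 3 mL/s
#: contrast injection, hearts spanning the ex-vivo pump range (input flow
#: 1.0–1.2 L/min), heart rates 107–115 bpm, FFR-graded circumflex stenosis.
_DEFAULTS: dict = {
    "aif": {
        "baseline_hu": 40.0,
        "t_arrival": 4.0,
        "alpha": 3.0,
        "beta": 1.2,
        "peak_enhancement": 250.0,
    },
    "tissue": {
        "extraction_e": 0.6,
        "dist_volume": 0.3,
        "tissue_density": 1.05,
    },
    "simulation": {
        "duration_s": 60.0,
        "injection_start_s": 5.0,
        "internal_dt_s": 0.01,
    },
    # sigma_hu is image (voxel) noise; analyzed curves are ROI means over
    # n voxels and inherit sigma/sqrt(n).  Counts follow the image-phantom
    # geometry (~80 voxels per segment, ~50 in the tube).
    "noise": {
        "sigma_hu": 10.0,
        "tac_roi_voxels": 80,
        "aif_roi_voxels": 50,
    },
    "hearts": [
        {"id": "heart_1", "weight_g": 560.0, "input_flow_ml_min": 1000.0},
        {"id": "heart_2", "weight_g": 430.0, "input_flow_ml_min": 1200.0},
        {"id": "heart_3", "weight_g": 580.0, "input_flow_ml_min": 1100.0},
    ],
    "ischemic_segments": [5, 6, 11, 12, 16],
    "grades": [
        {"label": "FFR09", "ffr": 0.9, "input_flow_factor": 1.0},
        {"label": "FFR08", "ffr": 0.8, "input_flow_factor": 1.0},
        {"label": "FFR07", "ffr": 0.7, "input_flow_factor": 0.9},
        {"label": "FFR06", "ffr": 0.6, "input_flow_factor": 0.8},
        {"label": "FFR05", "ffr": 0.5, "input_flow_factor": 0.7},
        {"label": "OCCLUSION", "ffr": None, "input_flow_factor": 0.7},
    ],
    "schemes": {
        "shuttle": {
            "heart_rate_bpm": [107.0, 115.0],
            "trigger_phase": 0.35,
            "slab_revisit_beats": 4,
            "rotation_time_s": 0.25,
            "duration_s": 60.0,
        },
        "non_shuttle": {
            "heart_rate_bpm": [107.0, 115.0],
            "trigger_phase": 0.35,
            "slab_revisit_beats": 1,
            "rotation_time_s": 0.25,
            "duration_s": 60.0,
        },
        "continuous": {
            "frame_interval_s": 0.0625,
            "rotation_time_s": 0.25,
            "duration_s": 60.0,
        },
    },
    "estimation": {
        "baseline_window_end_s": 5.0,
        # ECG-triggered frames are pre-smoothed (3-frame moving average)
        # before the max-slope search; the continuous mode's 1 s LS window
        # provides the smoothing instead.
        "slope_window_ecg": 3,
        "smoothing_ecg": 3,
        "slope_window_continuous_s": 1.0,
        "smoothing_continuous": None,
        "rotation_window_averaging": False,
    },
    "experiment": {
        "replicates": 1,
        "methods": ["upslope", "patlak"],
        "modes": ["shuttle", "non_shuttle", "continuous"],
        "include_occlusion": False,
    },
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    for key, value in override.items():
        where = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ConfigError(f"unknown configuration key: {where}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"configuration key {where} must be a mapping")
            _merge(base[key], value, where)
        else:
            base[key] = value
    return base


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file and/or a dict."""
    cfg = default_config()
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("configuration file must contain a mapping")
        _merge(cfg, loaded)
    if overrides:
        _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Cross-field checks; raises ConfigError naming the offending key."""
    for i, heart in enumerate(cfg["hearts"]):
        for key in ("id", "weight_g", "input_flow_ml_min"):
            if key not in heart:
                raise ConfigError(f"hearts[{i}] is missing key: {key}")
        if heart["weight_g"] <= 0:
            raise ConfigError(f"hearts[{i}].weight_g must be positive")
        if heart["input_flow_ml_min"] <= 0:
            raise ConfigError(f"hearts[{i}].input_flow_ml_min must be positive")
    labels = [g.get("label") for g in cfg["grades"]]
    for label in labels:
        if label not in GRADE_LABELS:
            raise ConfigError(f"grades: unknown label {label!r}")
    for mode in cfg["experiment"]["modes"]:
        if mode not in cfg["schemes"]:
            raise ConfigError(f"experiment.modes: no scheme defined for {mode!r}")
    for method in cfg["experiment"]["methods"]:
        if method not in ("upslope", "patlak"):
            raise ConfigError(f"experiment.methods: unknown method {method!r}")
    if cfg["experiment"]["replicates"] < 1:
        raise ConfigError("experiment.replicates must be >= 1")
    if cfg["noise"]["sigma_hu"] < 0:
        raise ConfigError("noise.sigma_hu must be non-negative")
    for key in ("tac_roi_voxels", "aif_roi_voxels"):
        if cfg["noise"][key] < 1:
            raise ConfigError(f"noise.{key} must be >= 1")


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_aif_params(cfg: dict) -> AifParameters:
    a = cfg["aif"]
    return AifParameters(
        baseline_hu=a["baseline_hu"],
        t_arrival=a["t_arrival"],
        alpha=a["alpha"],
        beta=a["beta"],
        peak_enhancement=a["peak_enhancement"],
    )


def build_kinetics(cfg: dict, flow_f: float = 1.0) -> TissueKinetics:
    t = cfg["tissue"]
    return TissueKinetics(
        flow_f=flow_f,
        extraction_e=t["extraction_e"],
        dist_volume=t["dist_volume"],
        tissue_density=t["tissue_density"],
    )


def build_hearts(cfg: dict) -> list[HeartPhantom]:
    ischemic = frozenset(cfg["ischemic_segments"])
    return [
        HeartPhantom(
            heart_id=h["id"],
            heart_weight=h["weight_g"],
            input_flow=h["input_flow_ml_min"],
            ischemic_segments=ischemic,
        )
        for h in cfg["hearts"]
    ]


def build_grades(cfg: dict) -> list[StenosisGrade]:
    grades = [
        StenosisGrade(g["label"], g.get("ffr"), g["input_flow_factor"])
        for g in cfg["grades"]
    ]
    _validate_grade_order(grades)
    return grades


def build_scheme(cfg: dict, mode: str) -> SamplingScheme:
    s = cfg["schemes"][mode]
    kwargs = {"mode": ScanMode(mode), "duration": s.get("duration_s", 60.0)}
    if "heart_rate_bpm" in s:
        kwargs["heart_rate_range"] = tuple(s["heart_rate_bpm"])
    if "trigger_phase" in s:
        kwargs["trigger_phase"] = s["trigger_phase"]
    if "slab_revisit_beats" in s:
        kwargs["slab_revisit_beats"] = s["slab_revisit_beats"]
    if "frame_interval_s" in s:
        kwargs["frame_interval"] = s["frame_interval_s"]
    if "rotation_time_s" in s:
        kwargs["rotation_time"] = s["rotation_time_s"]
    return SamplingScheme(**kwargs)


def build_upslope_config(cfg: dict, scheme: SamplingScheme) -> UpslopeConfig:
    """Mode-resolved slope-estimation settings.

    ECG-triggered modes use a fixed sample-count window with moving-average
    pre-smoothing; the continuous mode's window spans a fixed time (1 s
    -> 17 samples at 16 Hz) and needs no extra smoothing.
    """
    e = cfg["estimation"]
    if scheme.mode is ScanMode.CONTINUOUS:
        window = int(round(e["slope_window_continuous_s"] / scheme.frame_interval)) + 1
        smoothing = e["smoothing_continuous"]
    else:
        window = e["slope_window_ecg"]
        smoothing = e["smoothing_ecg"]
    return UpslopeConfig(
        slope_window=max(2, window),
        baseline_window_end=e["baseline_window_end_s"],
        smoothing=smoothing,
    )
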