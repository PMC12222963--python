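"""Run configuration: strictly validated, fully serialisable.

Unknown keys are rejected with the offending path so typos never
silently fall back to defaults.  A run manifest (config hash + seed +
versions) makes every artifact regenerable from config and seed alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SlideSimSection(_Strict):
    n_slides: int = 8
    width: int = 768
    height: int = 768
    n_glomeruli: int = 10
    class_weights: tuple[float, float, float, float, float] = (
        0.7063,
        0.2012,
        0.0585,
        0.0186,
        0.0154,
    )
    radius_range: tuple[float, float] = (25.0, 45.0)
    overlap_fraction: float = 0.1
    texture_contrast: float = 0.8


class CohortSimSection(_Strict):
    event_base_logodds: float = -1.9
    beta_gs_ratio: float = 2.0
    followup_months_range: tuple[float, float] = (12.0, 120.0)


class TilingSection(_Strict):
    patch_size: int = 512
    overlap: float = 0.5
    working_mpp: float = 1.0


class SamplerSection(_Strict):
    undersample_keep_prob: float = 0.5
    oversample_gs: int = 2
    oversample_ss: int = 4
    oversample_cr: int = 8
    oversample_isc: int = 8


class PredictorSection(_Strict):
    kind: str = "oracle"  # oracle | threshold
    boundary_shift_px: int = 0
    class_confusion_rate: float = 0.0
    prob_noise_sd: float = 0.0
    use_tta: bool = False
    harden_threshold: float = 0.5
    color_tolerance: float = 60.0


class SeparationSection(_Strict):
    min_marker_distance_px: int = 15
    min_instance_area_px: int = 300
    smoothing_sigma_px: float = 2.0
    marker_depth_px: float = 1.0


class EvaluationSection(_Strict):
    coverage_threshold: float = 0.5
    require_class_match: bool = True
    use_iou: bool = False
    bootstrap_B: int = 1000


class PrognosisSection(_Strict):
    families: tuple[str, ...] = ("xgboost", "random_forest", "logistic_regression")
    feature_sets: tuple[str, ...] = (
        "image",
        "clinical",
        "image+clinical",
        "iigan_pt",
        "image+iigan_pt",
    )
    train_fraction: float = 0.5


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "glomkit_out"
    log_level: str = "INFO"
    slides: SlideSimSection = SlideSimSection()
    cohort: CohortSimSection = CohortSimSection()
    tiling: TilingSection = TilingSection()
    sampler: SamplerSection = SamplerSection()
    predictor: PredictorSection = PredictorSection()
    separation: SeparationSection = SeparationSection()
    evaluation: EvaluationSection = EvaluationSection()
    prognosis: PrognosisSection = PrognosisSection()


def _coerce(value: str):
    try:
        return yaml.safe_load(value)
    except yaml.YAMLError:
        return value


def apply_overrides(data: dict, overrides: list[str]) -> dict:
    """Apply ``section.key=value`` dotted overrides to a config dict."""
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not of the form section.key=value")
        path, raw = item.split("=", 1)
        keys = path.strip().split(".")
        node = data
        for k in keys[:-1]:
            node = node.setdefault(k, {})
            if not isinstance(node, dict):
                raise ValueError(f"override path {path!r} traverses a non-section value")
        node[keys[-1]] = _coerce(raw)
    return data


def load_config(path: str | Path | None = None, overrides: list[str] | None = None) -> RunConfig:
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data = apply_overrides(data, overrides)
    return RunConfig(**data)


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.model_dump(), sort_keys=True, default=list)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_run_manifest(config: RunConfig, out_dir: Path) -> Path:
    import glomkit

    manifest = {
        "config": config.model_dump(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "glomkit_version": glomkit.__version__,
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=list))
    return path
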