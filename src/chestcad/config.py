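"""Validated run configuration loaded from YAML/JSON.

One flat document collects every tunable the pipeline exposes (pyramid
levels, rib-contrast weight, enhancement radii, clustering thresholds, GLCM
settings, SVM grid, hit distance, seeds).  Unknown keys are rejected and
every field is range-checked at load, so a typo fails immediately instead of
silently running with a default.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .detect import DetectorConfig
from .features import FeatureConfig
from .mann import SuppressorHyperparams
from .pipeline import PipelineConfig

__all__ = ["load_run_config", "DEFAULT_RUN_CONFIG"]

DEFAULT_RUN_CONFIG = {
    "n_levels": 3,
    "w_c": 0.4,
    "scales": [6.0, 14.0],
    "merge_fraction": 0.8,
    "likelihood_floor": 0.3,
    "max_candidates_per_image": 30,
    "hit_distance_mm": 25.0,
    "glcm_bins": 16,
    "gradient_t1_percentile": 10.0,
    "gradient_t2_percentile": 98.0,
    "epochs": 60,
    "learning_rate": 0.05,
    "batch_size": 256,
    "max_pairs_per_level": 20000,
    "folds": 3,
    "detrend": True,
    "seed": 0,
}

_CHECKS = {
    "n_levels": lambda v: 0 <= v <= 6,
    "w_c": lambda v: 0.0 <= v <= 1.0,
    "merge_fraction": lambda v: 0.0 <= v <= 1.0,
    "likelihood_floor": lambda v: 0.0 <= v <= 1.0,
    "max_candidates_per_image": lambda v: v >= 1,
    "hit_distance_mm": lambda v: v > 0,
    "glcm_bins": lambda v: v >= 2,
    "gradient_t1_percentile": lambda v: 0 <= v < 100,
    "gradient_t2_percentile": lambda v: 0 < v <= 100,
    "epochs": lambda v: v >= 0,
    "learning_rate": lambda v: v > 0,
    "batch_size": lambda v: v >= 1,
    "max_pairs_per_level": lambda v: v >= 1,
    "folds": lambda v: v >= 2,
    "scales": lambda v: len(v) == 2 and 0 < v[0] < v[1],
    "detrend": lambda v: isinstance(v, bool),
    "seed": lambda v: isinstance(v, int),
}


def load_run_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load, validate and assemble a :class:`PipelineConfig`.

    ``path`` may be a YAML or JSON file; missing keys fall back to defaults,
    unknown keys raise.
    """
    doc = dict(DEFAULT_RUN_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(loaded) - set(DEFAULT_RUN_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doc.update(loaded)
    if overrides:
        unknown = set(overrides) - set(DEFAULT_RUN_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doc.update(overrides)
    for key, check in _CHECKS.items():
        try:
            ok = check(doc[key])
        except Exception:
            ok = False
        if not ok:
            raise ValueError(f"config key {key!r} has invalid value {doc[key]!r}")
    return PipelineConfig(
        n_levels=int(doc["n_levels"]),
        w_c=float(doc["w_c"]),
        detector=DetectorConfig(
            scales=tuple(doc["scales"]),
            merge_fraction=float(doc["merge_fraction"]),
            likelihood_floor=float(doc["likelihood_floor"]),
            max_candidates_per_image=int(doc["max_candidates_per_image"]),
            hit_distance_mm=float(doc["hit_distance_mm"]),
        ),
        features=FeatureConfig(
            glcm_bins=int(doc["glcm_bins"]),
            gradient_t1_percentile=float(doc["gradient_t1_percentile"]),
            gradient_t2_percentile=float(doc["gradient_t2_percentile"]),
        ),
        suppressor=SuppressorHyperparams(
            epochs=int(doc["epochs"]),
            learning_rate=float(doc["learning_rate"]),
            batch_size=int(doc["batch_size"]),
            max_pairs_per_level=int(doc["max_pairs_per_level"]),
            seed=int(doc["seed"]),
        ),
        detrend=bool(doc["detrend"]),
        folds=int(doc["folds"]),
        seed=int(doc["seed"]),
    )
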