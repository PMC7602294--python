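"""End-to-end orchestration: suppress, detect, extract, classify, evaluate.

The per-image path mirrors the four-stage CAD design: lung-field mask,
background trend correction, rib-suppressed soft-tissue synthesis, two-step
enhancement with clustering-watershed candidate extraction on the
soft-tissue image, dual-domain feature extraction, and SVM scoring with FROC
evaluation.  Phantom samples carry their ground-truth masks and nodule
annotations, so the same entry points serve both experiments and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import classify as _classify
from .detect import DetectorConfig, detect_with_maps, enhance_nodules
from .features import (
    FeatureConfig,
    PER_DOMAIN_FEATURE_NAMES,
    edge_chains,
    extract_all,
    preprocess,
)
from .lungfield import correct_background_trend
from .mann import (
    SuppressorHyperparams,
    SuppressorModel,
    predict_bone,
    soft_tissue,
    sweep_rib_contrast,
    train_suppressor,
)

__all__ = [
    "PipelineConfig",
    "process_sample",
    "build_feature_table",
    "run_experiment",
    "compare_pipelines",
]

FEATURE_COLUMNS = [f"xray.{n}" for n in PER_DOMAIN_FEATURE_NAMES] + [
    f"soft.{n}" for n in PER_DOMAIN_FEATURE_NAMES
]


@dataclass(frozen=True)
class PipelineConfig:
    """One document of pipeline-level settings."""

    n_levels: int = 3
    w_c: float = 0.4
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    suppressor: SuppressorHyperparams = field(
        default_factory=SuppressorHyperparams
    )
    detrend: bool = True
    folds: int = 3
    seed: int = 0


def process_sample(
    sample,
    model: SuppressorModel | None,
    config: PipelineConfig,
    image_id: str,
) -> pd.DataFrame:
    """Run one phantom through suppression, detection and feature extraction.

    Returns one row per candidate with bookkeeping columns
    (``image_id, candidate_id, row, col, area_px, peak_likelihood, label``)
    followed by the 62 feature columns.  ``label`` marks candidates whose
    centroid falls within the detector hit distance of a true nodule.
    """
    mask = sample.lung_mask
    xray = np.asarray(sample.xray, dtype=np.float64)
    if model is not None and config.w_c > 0:
        bone = predict_bone(model, xray, mask)
        soft = soft_tissue(xray, bone, mask, config.w_c)
    else:
        soft = xray.copy()
    if config.detrend:
        xray_d, _ = correct_background_trend(xray, mask)
        soft_d, _ = correct_background_trend(soft, mask)
    else:
        xray_d, soft_d = xray, soft
    cands, soft_maps = detect_with_maps(soft_d, mask, config.detector)
    xray_maps = enhance_nodules(xray_d, mask, config.detector.scales)
    fc = config.features
    pre_cache = (preprocess(xray_d, fc), preprocess(soft_d, fc))
    edge_cache = (
        edge_chains(xray_d, fc.edge_sigma, fc.edge_low, fc.edge_high),
        edge_chains(soft_d, fc.edge_sigma, fc.edge_low, fc.edge_high),
    )
    hit_px = config.detector.hit_distance_mm / sample.pixel_spacing_mm
    rows = []
    for i, cand in enumerate(cands):
        label = 0
        for (r, c, _rad, _g) in sample.nodules:
            if np.hypot(cand.centroid[0] - r, cand.centroid[1] - c) <= hit_px:
                label = 1
                break
        try:
            feats = extract_all(
                cand, xray_d, soft_d, xray_maps, soft_maps, mask,
                config.features, preprocessed=pre_cache, edges=edge_cache,
            )
        except ValueError:
            continue  # degenerate region (too small for a quartic fit etc.)
        rows.append({
            "image_id": image_id,
            "candidate_id": i,
            "row": cand.centroid[0],
            "col": cand.centroid[1],
            "area_px": cand.area_px,
            "peak_likelihood": cand.peak_likelihood,
            "label": label,
            **feats,
        })
    cols = [
        "image_id", "candidate_id", "row", "col", "area_px",
        "peak_likelihood", "label", *FEATURE_COLUMNS,
    ]
    return pd.DataFrame(rows, columns=cols)


def build_feature_table(
    samples, model, config: PipelineConfig, id_prefix: str = "img"
) -> pd.DataFrame:
    frames = [
        process_sample(s, model, config, f"{id_prefix}{i:03d}")
        for i, s in enumerate(samples)
    ]
    return pd.concat(frames, ignore_index=True)


def _truth_tables(samples, id_prefix: str = "img"):
    truth, grades, ids = {}, {}, []
    for i, s in enumerate(samples):
        img = f"{id_prefix}{i:03d}"
        ids.append(img)
        truth[img] = [(r, c) for (r, c, _rad, _g) in s.nodules]
        grades[img] = [g for (_r, _c, _rad, g) in s.nodules]
    return truth, grades, ids


def run_experiment(
    samples, model: SuppressorModel | None, config: PipelineConfig
) -> dict:
    """Feature table, grouped-CV candidate scores, and FROC for one arm."""
    table = build_feature_table(samples, model, config)
    truth, grades, ids = _truth_tables(samples)
    result = {"table": table, "truth": truth, "grades": grades,
              "image_ids": ids}
    if table.empty or table["label"].nunique() < 2:
        result["froc"] = None
        return result
    scores = _classify.cross_val_scores(
        table[FEATURE_COLUMNS], table["label"], table["image_id"],
        folds=config.folds, seed=config.seed,
    )
    scored = table[["image_id", "row", "col"]].copy()
    scored["score"] = scores
    spacing = samples[0].pixel_spacing_mm
    result["froc"] = _classify.froc(
        scored, truth, config.detector.hit_distance_mm, spacing, ids
    )
    result["scores"] = scores
    return result


def _per_grade_sensitivity(arm: dict, fp_rate: float) -> dict:
    """Sensitivity per subtlety grade at the score threshold hit at fp_rate."""
    curve = arm["froc"]
    if curve is None:
        return {}
    # threshold achieving the requested FP rate (last one not exceeding it)
    ok = np.nonzero(curve.fp_per_image <= fp_rate)[0]
    th = curve.thresholds[ok[-1]] if len(ok) else np.inf
    table, truth, grades = arm["table"], arm["truth"], arm["grades"]
    scores = arm["scores"]
    hit_by_grade: dict = {}
    total_by_grade: dict = {}
    spacing_hit_px = None
    for img, centers in truth.items():
        for j, (r, c) in enumerate(centers):
            g = grades[img][j]
            total_by_grade[g] = total_by_grade.get(g, 0) + 1
    claimed = set()
    order = np.argsort(-scores)
    for idx in order:
        if scores[idx] < th:
            break
        rec = table.iloc[idx]
        centers = truth[rec["image_id"]]
        for j, (r, c) in enumerate(centers):
            key = (rec["image_id"], j)
            if key in claimed:
                continue
            if np.hypot(rec["row"] - r, rec["col"] - c) <= arm["hit_px"]:
                claimed.add(key)
                g = grades[rec["image_id"]][j]
                hit_by_grade[g] = hit_by_grade.get(g, 0) + 1
                break
    return {
        int(g): hit_by_grade.get(g, 0) / n for g, n in total_by_grade.items()
    }


def compare_pipelines(
    samples,
    model: SuppressorModel,
    config: PipelineConfig | None = None,
    wc_suppressed: float | None = None,
    fp_rate: float = 1.0,
) -> dict:
    """Run both arms (w_c = 0 and suppression at the given/optimal w_c).

    Returns a JSON-serializable report with each arm's FROC operating
    points, sensitivity at ``fp_rate`` false positives per image, and
    per-subtlety-grade sensitivities at the same operating point.
    """
    cfg = config or PipelineConfig()
    w_on = wc_suppressed if wc_suppressed is not None else cfg.w_c
    report = {"fp_rate": fp_rate, "arms": {}}
    for name, wc in (("no_suppression", 0.0), ("suppression", w_on)):
        arm_cfg = replace(cfg, w_c=wc)
        arm = run_experiment(samples, model if wc > 0 else None, arm_cfg)
        spacing = samples[0].pixel_spacing_mm
        arm["hit_px"] = cfg.detector.hit_distance_mm / spacing
        curve = arm["froc"]
        entry = {"w_c": wc}
        if curve is None:
            entry["sensitivity_at_fp"] = 0.0
            entry["per_grade_sensitivity"] = {}
            entry["froc_points"] = []
        else:
            entry["sensitivity_at_fp"] = curve.sensitivity_at_fp(fp_rate)
            entry["per_grade_sensitivity"] = _per_grade_sensitivity(arm, fp_rate)
            entry["froc_points"] = [
                [float(f), float(s)]
                for f, s in zip(curve.fp_per_image, curve.sensitivity)
            ]
            entry["n_candidates"] = int(len(arm["table"]))
        report["arms"][name] = entry
    report["delta_sensitivity"] = (
        report["arms"]["suppression"]["sensitivity_at_fp"]
        - report["arms"]["no_suppression"]["sensitivity_at_fp"]
    )
    return report
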