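"""Candidate classification and FROC evaluation.

False-positive reduction uses a Gaussian-kernel SVM over the standardized
62-feature vectors, with hyperparameters chosen by cross-validation grouped
by image (all candidates from one radiograph stay in the same fold, so a
nodule's own image never leaks into its training folds).  A single-hidden-
layer sigmoid network trained by gradient descent is provided as the
conventional-CAD baseline classifier.

Detection performance is summarized by free-response ROC analysis: a
candidate is a true positive when its centroid lies within a fixed physical
distance (default 25 mm) of an unclaimed nodule center, matched greedily in
descending score order; sweeping the score threshold traces sensitivity
against false positives per image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._mlp import ThreeLayerNet

__all__ = [
    "KernelConfig",
    "ClassifierModel",
    "FrocCurve",
    "train_svm",
    "cross_validate",
    "cross_val_scores",
    "train_baseline_mlp",
    "froc",
    "compare_pipelines",
]

DEFAULT_KERNEL_GRID = tuple(
    KC for KC in (
        {"C": C, "gamma": g}
        for C in (0.1, 1.0, 10.0, 100.0)
        for g in (0.01, 0.1, 1.0)
    )
)


@dataclass(frozen=True)
class KernelConfig:
    C: float = 1.0
    gamma: float = 0.1


@dataclass
class ClassifierModel:
    """A fitted scorer plus its standardization and feature manifest."""

    scaler: StandardScaler
    estimator: object
    feature_names: list
    kind: str = "svm"
    seed: int = 0

    def decision_scores(self, features: pd.DataFrame) -> np.ndarray:
        X = self.scaler.transform(
            np.asarray(features[self.feature_names], dtype=np.float64)
        )
        if self.kind == "svm":
            return self.estimator.decision_function(X)
        return self.estimator.forward(X)


def _validate_table(features: pd.DataFrame, labels) -> np.ndarray:
    X = np.asarray(features, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite values")
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need candidates of both classes to train")
    return y


def train_svm(
    features: pd.DataFrame,
    labels,
    kernel_config: KernelConfig | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Standardize and fit a Gaussian-kernel SVM; deterministic given seed."""
    cfg = kernel_config or KernelConfig()
    y = _validate_table(features, labels)
    scaler = StandardScaler().fit(np.asarray(features, dtype=np.float64))
    X = scaler.transform(np.asarray(features, dtype=np.float64))
    svc = SVC(kernel="rbf", C=cfg.C, gamma=cfg.gamma, random_state=seed)
    svc.fit(X, y)
    return ClassifierModel(
        scaler=scaler,
        estimator=svc,
        feature_names=list(features.columns),
        kind="svm",
        seed=seed,
    )


def _grouped_folds(groups: np.ndarray, n_folds: int, seed: int):
    """Deterministic image-grouped folds: shuffle images, deal round-robin."""
    uniq = np.unique(groups)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    assignment = {uniq[j]: i % n_folds for i, j in enumerate(order)}
    fold_of = np.array([assignment[g] for g in groups])
    for k in range(n_folds):
        yield np.nonzero(fold_of != k)[0], np.nonzero(fold_of == k)[0]


def cross_validate(
    features: pd.DataFrame,
    labels,
    groups,
    folds: int = 3,
    kernel_grid=None,
    seed: int = 0,
):
    """Select the kernel config maximizing mean grouped-fold validation AUC.

    Folds are assigned by image so no radiograph contributes candidates to
    both sides of a split.  Ties break to the first grid entry.  Returns
    ``(best KernelConfig, DataFrame of per-fold AUCs per config)``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = _validate_table(features, labels)
    groups = np.asarray(groups)
    grid = [
        cfg if isinstance(cfg, KernelConfig) else KernelConfig(**cfg)
        for cfg in (kernel_grid or DEFAULT_KERNEL_GRID)
    ]
    splits = list(_grouped_folds(groups, folds, seed))
    rows = []
    means = []
    for cfg in grid:
        aucs = []
        for tr, va in splits:
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
                continue
            model = train_svm(features.iloc[tr], y[tr], cfg, seed=seed)
            scores = model.decision_scores(features.iloc[va])
            aucs.append(roc_auc_score(y[va], scores))
        if not aucs:
            raise ValueError(
                "every fold was single-class; use fewer folds or more images"
            )
        rows.append({"C": cfg.C, "gamma": cfg.gamma, "aucs": aucs,
                     "mean_auc": float(np.mean(aucs))})
        means.append(float(np.mean(aucs)))
    best = int(np.argmax(means))  # argmax takes the first maximum
    return grid[best], pd.DataFrame(rows)


def cross_val_scores(
    features: pd.DataFrame,
    labels,
    groups,
    kernel_config: KernelConfig | None = None,
    folds: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold decision scores for every candidate (image-grouped)."""
    y = _validate_table(features, labels)
    groups = np.asarray(groups)
    scores = np.full(len(y), np.nan)
    for tr, va in _grouped_folds(groups, folds, seed):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("single-class training fold; reduce folds")
        model = train_svm(features.iloc[tr], y[tr], kernel_config, seed=seed)
        scores[va] = model.decision_scores(features.iloc[va])
    return scores


def train_baseline_mlp(
    features: pd.DataFrame,
    labels,
    hidden_units: int = 1000,
    seed: int = 0,
    epochs: int = 200,
    learning_rate: float = 0.1,
    batch_size: int = 32,
) -> ClassifierModel:
    """Single-hidden-layer sigmoid classifier trained by gradient descent."""
    if hidden_units < 1:
        raise ValueError("hidden_units must be >= 1")
    y = _validate_table(features, labels)
    scaler = StandardScaler().fit(np.asarray(features, dtype=np.float64))
    X = scaler.transform(np.asarray(features, dtype=np.float64))
    net = ThreeLayerNet(X.shape[1], hidden_units, seed=seed, output="sigmoid")
    if epochs > 0:
        net.fit(X, y.astype(float), epochs=epochs, lr=learning_rate,
                batch_size=batch_size, seed=seed + 1)
    return ClassifierModel(
        scaler=scaler,
        estimator=net,
        feature_names=list(features.columns),
        kind="mlp",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# FROC


@dataclass
class FrocCurve:
    """Operating points (FP/image, sensitivity) swept over score thresholds."""

    fp_per_image: np.ndarray
    sensitivity: np.ndarray
    thresholds: np.ndarray
    n_images: int
    n_nodules: int
    hit_distance_mm: float

    def sensitivity_at_fp(self, rate: float) -> float:
        """Linear interpolation of sensitivity at a given FP/image rate."""
        fp, se = self.fp_per_image, self.sensitivity
        if len(fp) == 0:
            return 0.0
        if rate <= fp[0]:
            return float(se[0]) if rate == fp[0] else float(
                np.interp(rate, np.concatenate([[0.0], fp]),
                          np.concatenate([[0.0], se]))
            )
        if rate >= fp[-1]:
            return float(se[-1])
        return float(np.interp(rate, fp, se))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "fp_per_image": self.fp_per_image,
            "sensitivity": self.sensitivity,
        })


def froc(
    candidates: pd.DataFrame,
    truth: dict,
    hit_distance_mm: float = 25.0,
    pixel_spacing_mm: float = 0.7,
    image_ids=None,
) -> FrocCurve:
    """FROC over a candidate table with greedy distance matching.

    ``candidates`` needs columns ``image_id, row, col, score``; ``truth``
    maps image id to a list of nodule centers ``(row, col)``.  ``image_ids``
    may list additional candidate-free images that still count in the
    FP/image denominator.  Greedy matching in descending score order claims
    at most one candidate per truth nodule; the sweep then only counts
    matches above each threshold, so the curve is monotone by construction.
    """
    required = {"image_id", "row", "col", "score"}
    if not required.issubset(candidates.columns):
        raise ValueError(f"candidate table must have columns {sorted(required)}")
    known = set(truth)
    missing = set(candidates["image_id"]) - known
    if missing:
        raise ValueError(f"images with candidates but no truth entry: {missing}")
    all_ids = set(known) | set(image_ids or [])
    n_images = len(all_ids)
    n_nodules = sum(len(v) for v in truth.values())
    hit_px = hit_distance_mm / pixel_spacing_mm

    df = candidates.sort_values(
        ["score", "image_id", "row", "col"], ascending=[False, True, True, True]
    ).reset_index(drop=True)
    claimed = {img: [False] * len(truth[img]) for img in truth}
    is_tp = np.zeros(len(df), dtype=bool)
    for idx, rec in df.iterrows():
        centers = truth[rec["image_id"]]
        best_j, best_d = -1, np.inf
        for j, (tr, tc) in enumerate(centers):
            if claimed[rec["image_id"]][j]:
                continue
            d = np.hypot(rec["row"] - tr, rec["col"] - tc)
            if d <= hit_px and d < best_d:
                best_j, best_d = j, d
        if best_j >= 0:
            claimed[rec["image_id"]][best_j] = True
            is_tp[idx] = True

    thresholds = np.unique(df["score"].to_numpy())[::-1]
    fp_rate, sens = [], []
    scores = df["score"].to_numpy()
    for th in thresholds:
        above = scores >= th
        tp = int((is_tp & above).sum())
        fp = int((~is_tp & above).sum())
        fp_rate.append(fp / n_images if n_images else 0.0)
        sens.append(tp / n_nodules if n_nodules else 0.0)
    return FrocCurve(
        fp_per_image=np.asarray(fp_rate),
        sensitivity=np.asarray(sens),
        thresholds=thresholds,
        n_images=n_images,
        n_nodules=n_nodules,
        hit_distance_mm=hit_distance_mm,
    )


def compare_pipelines(*args, **kwargs):
    """Two-arm (no suppression vs optimal suppression) pipeline comparison.

    Thin re-export; the orchestration lives in :mod:`chestcad.pipeline`.
    """
    from .pipeline import compare_pipelines as _impl

    return _impl(*args, **kwargs)
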