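"""Massive-training pixel-regression rib suppressor and soft-tissue synthesis.

The suppressor is a bank of small patch-in/pixel-out regressors — one per
multi-resolution difference level plus one for the base — each a fully
connected three-layer network (81 inputs from a 9x9 patch, 20 sigmoid hidden
units, one linear output) trained to predict the bone-only teaching image's
pixel from the local x-ray patch at the same pyramid level.  Splitting by
resolution lets each small network handle one rib frequency band instead of
one network having to suppress all of them.

Soft-tissue synthesis subtracts the predicted bone image, weighted by the rib
contrast parameter ``w_c`` in [0, 1] and gated by the lung mask:

    soft = xray - w_c * bone_pred * mask

``w_c = 0`` leaves the radiograph untouched; intermediate values trade rib
removal against nodule-contrast preservation, and the sweep utility locates
the sensitivity-optimal setting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._mlp import ThreeLayerNet
from .pyramid import Pyramid, decompose, downsample, reconstruct

__all__ = [
    "SuppressorHyperparams",
    "SuppressorModel",
    "TrainingSet",
    "make_training_set",
    "train_suppressor",
    "predict_bone",
    "soft_tissue",
    "sweep_rib_contrast",
    "SweepResult",
]

PATCH_HALF = 4  # 9x9 patch


@dataclass(frozen=True)
class SuppressorHyperparams:
    n_hidden: int = 20
    epochs: int = 60
    learning_rate: float = 0.05
    batch_size: int = 256
    max_pairs_per_level: int = 20000
    seed: int = 0


@dataclass
class TrainingSet:
    """Patch/teaching-value pairs drawn from one pyramid level."""

    patches: np.ndarray  # (N, 81)
    targets: np.ndarray  # (N,)
    level: int = 0


@dataclass
class SuppressorModel:
    """Per-level regressors plus normalization constants and metadata."""

    nets: list
    x_mean: list
    x_sd: list
    t_center: list
    t_half: list
    n_levels: int
    w_c: float = 0.4
    hyperparams: SuppressorHyperparams = field(default_factory=SuppressorHyperparams)
    train_mse: list = field(default_factory=list)

    def save(self, path) -> None:
        """Write arrays (.npz) plus a JSON metadata sidecar."""
        path = Path(path)
        arrays = {}
        for k, net in enumerate(self.nets):
            arrays[f"W1_{k}"] = net.W1
            arrays[f"b1_{k}"] = net.b1
            arrays[f"W2_{k}"] = net.W2
            arrays[f"b2_{k}"] = net.b2
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "n_levels": self.n_levels,
            "w_c": self.w_c,
            "x_mean": self.x_mean,
            "x_sd": self.x_sd,
            "t_center": self.t_center,
            "t_half": self.t_half,
            "train_mse": self.train_mse,
            "hyperparams": asdict(self.hyperparams),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "SuppressorModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path.with_suffix(".npz"))
        hp = SuppressorHyperparams(**meta["hyperparams"])
        nets = []
        for k in range(meta["n_levels"] + 1):
            net = ThreeLayerNet(data[f"W1_{k}"].shape[0], hp.n_hidden, seed=0)
            net.W1 = data[f"W1_{k}"]
            net.b1 = data[f"b1_{k}"]
            net.W2 = data[f"W2_{k}"]
            net.b2 = data[f"b2_{k}"]
            nets.append(net)
        return cls(
            nets=nets,
            x_mean=meta["x_mean"],
            x_sd=meta["x_sd"],
            t_center=meta["t_center"],
            t_half=meta["t_half"],
            n_levels=meta["n_levels"],
            w_c=meta["w_c"],
            hyperparams=hp,
            train_mse=meta["train_mse"],
        )


def _interior_patches(image: np.ndarray) -> np.ndarray:
    """All full 9x9 patches, shape (H-8, W-8, 81)."""
    win = sliding_window_view(image, (2 * PATCH_HALF + 1, 2 * PATCH_HALF + 1))
    return win.reshape(win.shape[0], win.shape[1], -1)


def make_training_set(
    xray_level: np.ndarray, bone_level: np.ndarray, region: np.ndarray, level: int = 0
) -> TrainingSet:
    """One (patch, teaching value) pair per region pixel with a full patch.

    Only pixels at least 4 pixels from every image border qualify, so every
    patch lies fully inside the image.
    """
    xray_level = np.asarray(xray_level, dtype=np.float64)
    bone_level = np.asarray(bone_level, dtype=np.float64)
    if xray_level.shape != bone_level.shape or xray_level.shape != region.shape:
        raise ValueError("xray, bone and region must share a shape")
    h, w = xray_level.shape
    inner = np.zeros((h, w), dtype=bool)
    if h > 2 * PATCH_HALF and w > 2 * PATCH_HALF:
        inner[PATCH_HALF : h - PATCH_HALF, PATCH_HALF : w - PATCH_HALF] = True
    sel = inner & (np.asarray(region) > 0)
    if not sel.any():
        raise ValueError(
            "training region empty after removing the 4-pixel border margin"
        )
    patches = _interior_patches(xray_level)
    rows, cols = np.nonzero(sel)
    return TrainingSet(
        patches=patches[rows - PATCH_HALF, cols - PATCH_HALF],
        targets=bone_level[rows, cols],
        level=level,
    )


def train_suppressor(
    samples: list,
    n_levels: int = 3,
    hyperparams: SuppressorHyperparams | None = None,
) -> SuppressorModel:
    """Fit one regressor per pyramid level from (x-ray, bone) phantom pairs.

    Training pixels come from each sample's lung mask (block-mean downsampled
    and thresholded at 0.5 for the coarser levels).  Deterministic for a
    fixed ``hyperparams.seed``.
    """
    hp = hyperparams or SuppressorHyperparams()
    if not samples:
        raise ValueError("need at least one training sample with a bone image")
    per_level_X = [[] for _ in range(n_levels + 1)]
    per_level_t = [[] for _ in range(n_levels + 1)]
    for s in samples:
        xp = decompose(s.xray, n_levels)
        bp = decompose(s.bone, n_levels)
        mask = np.asarray(s.lung_mask, dtype=np.float64)
        for k in range(n_levels + 1):
            if k < n_levels:
                ximg, bimg = xp.levels[k], bp.levels[k]
            else:
                ximg, bimg = xp.base, bp.base
            region = mask > 0.5
            ts = make_training_set(ximg, bimg, region, level=k)
            per_level_X[k].append(ts.patches)
            per_level_t[k].append(ts.targets)
            mask = downsample(mask)

    rng = np.random.default_rng(hp.seed)
    nets, x_means, x_sds, t_centers, t_halves, mses = [], [], [], [], [], []
    for k in range(n_levels + 1):
        X = np.concatenate(per_level_X[k], axis=0)
        t = np.concatenate(per_level_t[k], axis=0)
        if X.shape[0] > hp.max_pairs_per_level:
            keep = rng.choice(X.shape[0], hp.max_pairs_per_level, replace=False)
            X, t = X[keep], t[keep]
        x_mean = float(X.mean())
        x_sd = float(X.std())
        x_sd = x_sd if x_sd > 1e-12 else 1.0
        t_center = float((t.max() + t.min()) / 2.0)
        t_half = float((t.max() - t.min()) / 2.0)
        t_half = t_half if t_half > 1e-12 else 1.0
        Xn = (X - x_mean) / x_sd
        tn = (t - t_center) / t_half
        net = ThreeLayerNet(X.shape[1], hp.n_hidden, seed=hp.seed + 1000 + k)
        try:
            mse_n = net.fit(
                Xn, tn, epochs=hp.epochs, lr=hp.learning_rate,
                batch_size=hp.batch_size, seed=hp.seed + 2000 + k,
            )
        except FloatingPointError as exc:
            raise FloatingPointError(f"level {k}: {exc}") from exc
        nets.append(net)
        x_means.append(x_mean)
        x_sds.append(x_sd)
        t_centers.append(t_center)
        t_halves.append(t_half)
        mses.append(mse_n * t_half**2)  # back to intensity units
    return SuppressorModel(
        nets=nets, x_mean=x_means, x_sd=x_sds, t_center=t_centers,
        t_half=t_halves, n_levels=n_levels, hyperparams=hp, train_mse=mses,
    )


def _predict_level(model: SuppressorModel, k: int, level_image: np.ndarray) -> np.ndarray:
    padded = np.pad(level_image, PATCH_HALF, mode="edge")
    patches = _interior_patches(padded)  # (H, W, 81)
    h, w = level_image.shape
    Xn = (patches.reshape(-1, patches.shape[-1]) - model.x_mean[k]) / model.x_sd[k]
    out = model.nets[k].forward(Xn)
    return (out * model.t_half[k] + model.t_center[k]).reshape(h, w)


def predict_bone(
    model: SuppressorModel, xray: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Predicted bone image f_b, same shape as ``xray``.

    Each level's regressor runs at every pixel of the corresponding x-ray
    pyramid level (edge-replicated patches at borders); the predicted level
    images are reassembled through the exact pyramid composition.
    """
    xray = np.asarray(xray, dtype=np.float64)
    f = 2**model.n_levels
    if xray.shape[0] % f or xray.shape[1] % f:
        raise ValueError(
            f"image shape {xray.shape} not divisible by 2**{model.n_levels}"
        )
    xp = decompose(xray, model.n_levels)
    pred_levels = [
        _predict_level(model, k, xp.levels[k]) for k in range(model.n_levels)
    ]
    pred_base = _predict_level(model, model.n_levels, xp.base)
    bone = reconstruct(Pyramid(levels=pred_levels, base=pred_base))
    if mask is not None:
        bone = bone * (np.asarray(mask) > 0)
    return bone


def soft_tissue(
    xray: np.ndarray, bone_pred: np.ndarray, mask: np.ndarray, w_c: float
) -> np.ndarray:
    """Pixelwise ``xray - w_c * bone_pred * mask``; identity outside the mask."""
    if not 0.0 <= w_c <= 1.0:
        raise ValueError(f"w_c must lie in [0, 1], got {w_c}")
    xray = np.asarray(xray, dtype=np.float64)
    bone_pred = np.asarray(bone_pred, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if xray.shape != bone_pred.shape or xray.shape != mask.shape:
        raise ValueError("xray, bone_pred and mask must share a shape")
    if w_c == 0.0:
        return xray.copy()
    return xray - w_c * bone_pred * (mask > 0)


@dataclass
class SweepResult:
    """Sensitivity over a grid of rib-contrast weights, argmax flagged."""

    points: list  # (w_c, sensitivity) pairs, grid order
    best_index: int

    @property
    def best_wc(self) -> float:
        return self.points[self.best_index][0]


def sweep_rib_contrast(
    model: SuppressorModel,
    dataset: list,
    w_c_grid,
    detector_config=None,
    max_candidates: int = 10,
) -> SweepResult:
    """Candidate-stage localization sensitivity as a function of ``w_c``.

    For each grid value the soft-tissue image is synthesized and run
    through candidate detection.  A nodule counts as localized when one of
    the top
    ``max_candidates`` candidate centroids falls inside the nodule (within
    its annotated radius) — a strict calibration criterion: it rewards
    weights at which nodules are both found and prominent, and degrades both
    when ribs clutter the candidate list (low ``w_c``) and when
    over-subtraction erodes nodule contrast (``w_c`` near 1).  Bone
    prediction is computed once per image and reused across the grid.
    """
    from dataclasses import replace as _replace

    from .detect import DetectorConfig, detect_candidates

    w_c_grid = list(w_c_grid)
    if not w_c_grid:
        raise ValueError("w_c grid must be nonempty")
    if any(not 0.0 <= w <= 1.0 for w in w_c_grid):
        raise ValueError("all grid values must lie in [0, 1]")
    cfg = detector_config or DetectorConfig()
    cfg = _replace(cfg, max_candidates_per_image=max_candidates)
    bones = [predict_bone(model, s.xray, s.lung_mask) for s in dataset]
    points = []
    for w_c in w_c_grid:
        hits = total = 0
        for s, bone in zip(dataset, bones):
            if not s.nodules:
                continue
            soft = soft_tissue(s.xray, bone, s.lung_mask, w_c)
            cands = detect_candidates(soft, s.lung_mask, cfg)
            for (r, c, rad, _g) in s.nodules:
                total += 1
                if any(
                    np.hypot(cd.centroid[0] - r, cd.centroid[1] - c) <= rad
                    for cd in cands
                ):
                    hits += 1
        points.append((float(w_c), hits / total if total else 0.0))
    best = max(range(len(points)), key=lambda i: (points[i][1], -i))
    return SweepResult(points=points, best_index=best)
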