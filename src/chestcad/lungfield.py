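"""Lung-field segmentation and background trend correction.

Segmentation uses a point-distribution active shape model over the two lung
lobes: equal-count boundary landmarks (arc-length resampled, partitioned into
named anatomical segments), aligned by translation and scale, with principal
shape modes retained to 95% variance.  Search iterates landmark moves to the
strongest gradient along the boundary normal, constrained to the learned
shape subspace.

Trend correction removes a least-squares second-order bivariate polynomial

    F(x, y) = a x^2 + b y^2 + c xy + d x + e y + f

fitted to the intensities inside the lung mask, flattening the smooth
anatomical background so nodules stand out.  The fit is performed on
coordinates normalized to [-1, 1]^2 for conditioning; the reported
coefficients are converted back to pixel-coordinate units (x = column,
y = row).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import draw, measure

__all__ = [
    "ShapeModel",
    "TrendSurface",
    "SegmentationResult",
    "fit_shape_model",
    "segment_lung",
    "fit_background_trend",
    "correct_background_trend",
]

SEGMENT_NAMES = ("apex", "rib-cage", "diaphragm", "mediastinal")


# ---------------------------------------------------------------------------
# trend correction


@dataclass
class TrendSurface:
    """Quadratic surface coefficients in pixel units (x = col, y = row)."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def coefficients(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e, self.f])

    def evaluate(self, shape) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
        x, y = cc, rr
        return (
            self.a * x**2 + self.b * y**2 + self.c * x * y
            + self.d * x + self.e * y + self.f
        )


def _design(x, y):
    return np.column_stack([x**2, y**2, x * y, x, y, np.ones_like(x)])


def fit_background_trend(image: np.ndarray, mask: np.ndarray) -> TrendSurface:
    """Least-squares quadratic trend of the masked intensities."""
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask) > 0
    if mask.sum() < 6:
        raise ValueError("mask must contain at least 6 pixels for a quadratic fit")
    h, w = image.shape
    rows, cols = np.nonzero(mask)
    # normalized coordinates for conditioning
    u = 2.0 * cols / max(w - 1, 1) - 1.0
    v = 2.0 * rows / max(h - 1, 1) - 1.0
    A = _design(u, v)
    coef, _res, rank, _sv = np.linalg.lstsq(A, image[mask], rcond=None)
    if rank < 6:
        raise ValueError(
            "rank-deficient trend fit: mask pixels are collinear or too few "
            "distinct coordinates"
        )
    at, bt, ct, dt, et, ft = coef
    # convert the polynomial in (u, v) = (alpha x + beta, gamma y + delta)
    # back to pixel coordinates
    alpha, beta = 2.0 / max(w - 1, 1), -1.0
    gamma, delta = 2.0 / max(h - 1, 1), -1.0
    a = at * alpha**2
    b = bt * gamma**2
    c = ct * alpha * gamma
    d = 2 * at * alpha * beta + ct * alpha * delta + dt * alpha
    e = 2 * bt * gamma * delta + ct * beta * gamma + et * gamma
    f = (
        at * beta**2 + bt * delta**2 + ct * beta * delta
        + dt * beta + et * delta + ft
    )
    return TrendSurface(*(float(v_) for v_ in (a, b, c, d, e, f)))


def correct_background_trend(image: np.ndarray, mask: np.ndarray):
    """Subtract the fitted quadratic trend inside the mask.

    Returns ``(corrected, trend)``; pixels outside the mask are untouched.
    Idempotent: re-correcting changes the image only at float round-off.
    """
    image = np.asarray(image, dtype=np.float64)
    mask_b = np.asarray(mask) > 0
    trend = fit_background_trend(image, mask_b)
    corrected = image.copy()
    corrected[mask_b] = image[mask_b] - trend.evaluate(image.shape)[mask_b]
    return corrected, trend


# ---------------------------------------------------------------------------
# active shape model


@dataclass
class ShapeModel:
    """Two-lobe point-distribution model with segment-labelled landmarks."""

    mean_shape: np.ndarray          # (2 * n_points, 2) normalized (row, col)
    modes: np.ndarray               # (2 * n_points * 2, n_modes)
    variances: np.ndarray           # (n_modes,)
    mean_centroid: np.ndarray       # (2,) pixels
    mean_scale: float               # pixels
    n_per_lobe: int
    segments: list = field(default_factory=list)  # per-landmark segment name

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]


def _lobe_boundary(lobe_mask: np.ndarray, n_points: int) -> np.ndarray:
    """Closed boundary resampled to ``n_points`` by arc length.

    Starts at the topmost boundary point and runs with positive signed area
    so landmark correspondence is consistent across shapes.
    """
    padded = np.pad(lobe_mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("degenerate mask: a lobe has no boundary")
    contour = max(contours, key=len) - 1.0
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    area = 0.5 * np.sum(
        contour[:, 0] * np.roll(contour[:, 1], -1)
        - np.roll(contour[:, 0], -1) * contour[:, 1]
    )
    if area < 0:
        contour = contour[::-1]
    start = np.lexsort((contour[:, 1], contour[:, 0]))[0]
    contour = np.roll(contour, -start, axis=0)
    closed = np.vstack([contour, contour[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    out = np.empty((n_points, 2))
    out[:, 0] = np.interp(targets, s, closed[:, 0])
    out[:, 1] = np.interp(targets, s, closed[:, 1])
    return out


def _mask_landmarks(mask: np.ndarray, n_per_lobe: int) -> np.ndarray:
    labels = measure.label(np.asarray(mask) > 0)
    props = measure.regionprops(labels)
    if len(props) < 2:
        raise ValueError(
            f"expected two lung lobes, found {len(props)} connected components"
        )
    props = sorted(props, key=lambda p: p.area, reverse=True)[:2]
    props = sorted(props, key=lambda p: p.centroid[1])  # left lobe first
    pts = [_lobe_boundary(labels == p.label, n_per_lobe) for p in props]
    return np.vstack(pts)


def _align(points: np.ndarray):
    """Translation + scale normalization; returns (normalized, centroid, scale)."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    scale = np.sqrt((centered**2).sum(axis=1).mean())
    if scale < 1e-12:
        raise ValueError("degenerate shape with zero extent")
    return centered / scale, centroid, scale


def fit_shape_model(
    training_masks: list, n_per_lobe: int = 48, variance_kept: float = 0.95
) -> ShapeModel:
    """Build the point-distribution model from binary two-lobe masks."""
    if len(training_masks) < 3:
        raise ValueError("need at least 3 training masks")
    shapes, centroids, scales = [], [], []
    for m in training_masks:
        pts = _mask_landmarks(m, n_per_lobe)
        norm, cen, sc = _align(pts)
        shapes.append(norm.ravel())
        centroids.append(cen)
        scales.append(sc)
    X = np.array(shapes)
    mean_flat = X.mean(axis=0)
    centered = X - mean_flat
    _u, svals, vt = np.linalg.svd(centered, full_matrices=False)
    var = svals**2 / max(len(shapes) - 1, 1)
    total = var.sum()
    if total < 1e-20:
        modes = np.zeros((X.shape[1], 0))
        kept_var = np.zeros(0)
    else:
        cum = np.cumsum(var) / total
        k = int(np.searchsorted(cum, variance_kept) + 1)
        k = min(k, len(var))
        modes = vt[:k].T
        kept_var = var[:k]
    per_lobe_segments = []
    for frac in np.arange(n_per_lobe) / n_per_lobe:
        # boundary starts at the apex and runs down the lateral rib-cage side
        if frac < 0.15 or frac >= 0.90:
            per_lobe_segments.append("apex")
        elif frac < 0.45:
            per_lobe_segments.append("rib-cage")
        elif frac < 0.65:
            per_lobe_segments.append("diaphragm")
        else:
            per_lobe_segments.append("mediastinal")
    return ShapeModel(
        mean_shape=mean_flat.reshape(-1, 2),
        modes=modes,
        variances=kept_var,
        mean_centroid=np.mean(centroids, axis=0),
        mean_scale=float(np.mean(scales)),
        n_per_lobe=n_per_lobe,
        segments=per_lobe_segments * 2,
    )


@dataclass
class SegmentationResult:
    """Filled two-lobe mask plus convergence diagnostics."""

    mask: np.ndarray
    converged: bool
    warning: str | None = None
    n_iterations: int = 0


def _project_to_subspace(points: np.ndarray, model: ShapeModel) -> np.ndarray:
    norm, cen, sc = _align(points)
    y = norm.ravel() - model.mean_shape.ravel()
    if model.n_modes:
        bvec = model.modes.T @ y
        limit = 3.0 * np.sqrt(np.maximum(model.variances, 1e-12))
        bvec = np.clip(bvec, -limit, limit)
        y = model.modes @ bvec
    else:
        y = np.zeros_like(y)
    recon = (model.mean_shape.ravel() + y).reshape(-1, 2)
    return recon * sc + cen


def _rasterize(points: np.ndarray, shape, n_per_lobe: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=np.uint8)
    for lobe in (points[:n_per_lobe], points[n_per_lobe:]):
        rr, cc = draw.polygon(lobe[:, 0], lobe[:, 1], shape=shape)
        mask[rr, cc] = 1
    return ndi.binary_fill_holes(mask).astype(np.uint8)


def segment_lung(
    image: np.ndarray,
    model: ShapeModel,
    max_iterations: int = 12,
    search_length: int = 8,
    tol_px: float = 0.5,
    init_points: np.ndarray | None = None,
) -> SegmentationResult:
    """Iterative ASM search: normal-direction gradient matching + projection."""
    image = np.asarray(image, dtype=np.float64)
    grad = ndi.gaussian_gradient_magnitude(image, sigma=2.0)
    if grad.max() < 1e-9:
        pts = (
            init_points
            if init_points is not None
            else model.mean_shape * model.mean_scale + model.mean_centroid
        )
        return SegmentationResult(
            mask=_rasterize(pts, image.shape, model.n_per_lobe),
            converged=False,
            warning="no gradient evidence in image; returning initial shape",
        )
    if init_points is None:
        points = model.mean_shape * model.mean_scale + model.mean_centroid
    else:
        points = np.asarray(init_points, dtype=np.float64).copy()
    h, w = image.shape
    n = model.n_per_lobe
    offsets = np.arange(-search_length, search_length + 1)
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        moved = points.copy()
        for lobe_start in (0, n):
            lobe = points[lobe_start : lobe_start + n]
            tang = np.roll(lobe, -1, axis=0) - np.roll(lobe, 1, axis=0)
            norms = np.column_stack([-tang[:, 1], tang[:, 0]])
            lens = np.linalg.norm(norms, axis=1, keepdims=True)
            norms = norms / np.maximum(lens, 1e-12)
            for i in range(n):
                cand = lobe[i] + offsets[:, None] * norms[i]
                rr = np.clip(np.round(cand[:, 0]).astype(int), 0, h - 1)
                cc = np.clip(np.round(cand[:, 1]).astype(int), 0, w - 1)
                best = np.argmax(grad[rr, cc])
                moved[lobe_start + i] = cand[best]
        projected = _project_to_subspace(moved, model)
        shift = np.linalg.norm(projected - points, axis=1).mean()
        points = projected
        if shift < tol_px:
            converged = True
            break
    warning = None if converged else "ASM search did not converge"
    return SegmentationResult(
        mask=_rasterize(points, image.shape, model.n_per_lobe),
        converged=converged,
        warning=warning,
        n_iterations=it,
    )
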