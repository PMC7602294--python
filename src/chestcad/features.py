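"""Candidate feature extraction.

The proposed scheme measures 31 features per image domain — position and
likelihood of the candidate, shape (area, axis ratio, solidity, normalized
center distance), gray-level region-vs-surround contrasts on the
preprocessed and nodule-enhanced images, gradient concentration over eight
angular sectors, principal curvatures of a fitted quartic surface, GLCM
texture statistics, and a boundary/edge-chain overlap score — and computes
them twice, once on the x-ray image and once at the identical region in the
soft-tissue image, for 62 values total.  A nodule whose rib-like traits were
attenuated by suppression can still be recognized from its x-ray-domain
block, and vice versa.

A separate 14-feature baseline set reproduces a conventional CAD's
measurements (GLCM statistics, first-order gray statistics, circularity,
area, perimeter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from scipy.stats import skew
from skimage import exposure, feature as skfeature, measure, morphology

__all__ = [
    "FeatureConfig",
    "PER_DOMAIN_FEATURE_NAMES",
    "BASELINE_FEATURE_NAMES",
    "preprocess",
    "binarize_and_label",
    "circularity",
    "perimeter_length",
    "shape_features",
    "gray_features",
    "gradient_features",
    "surface_features",
    "texture_features",
    "false_positive_feature",
    "candidate_likelihood_features",
    "extract_all",
    "baseline_features",
]

PER_DOMAIN_FEATURE_NAMES = (
    ["can.u", "can.v", "can.Grad_1", "can.CV_1", "can.Grad_2", "can.CV_2"]
    + [f"Shape_{i}" for i in range(1, 5)]
    + [f"Gray_{i}" for i in range(1, 9)]
    + [f"Grad_{i}" for i in range(1, 4)]
    + [f"Surface_{i}" for i in range(1, 4)]
    + [f"Texture_{i}" for i in range(1, 7)]
    + ["FalsePositive"]
)

BASELINE_FEATURE_NAMES = (
    "glcm_contrast", "glcm_correlation", "glcm_energy", "glcm_homogeneity",
    "gray_level", "mean", "std", "entropy", "circularity", "uniformity",
    "smoothness", "skewness", "area", "perimeter",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction tunables (GLCM quantization, gradient gating, edges)."""

    glcm_bins: int = 16
    glcm_offsets: tuple = ((0, 1), (1, 0), (1, 1), (1, -1))
    gradient_t1_percentile: float = 10.0
    gradient_t2_percentile: float = 98.0
    normalize_gradient_sd: bool = False
    edge_sigma: float = 2.0
    edge_low: float | None = None
    edge_high: float | None = None
    unsharp_radius: float = 2.0
    unsharp_amount: float = 1.0


# ---------------------------------------------------------------------------
# preprocessing of the conventional pipeline


def preprocess(
    image: np.ndarray,
    config: FeatureConfig | None = None,
    median: bool = True,
    sharpen: bool = True,
    equalize: bool = True,
) -> np.ndarray:
    """5x5 median filter, unsharp-mask sharpening, histogram equalization.

    Output is float in [0, 1] (full dynamic range after equalization).
    Deterministic; individual stages can be toggled for diagnostics.
    """
    cfg = config or FeatureConfig()
    out = np.asarray(image, dtype=np.float64)
    if median:
        out = ndi.median_filter(out, size=5)
    if sharpen:
        blurred = ndi.gaussian_filter(out, sigma=cfg.unsharp_radius)
        out = out + cfg.unsharp_amount * (out - blurred)
    if equalize:
        out = exposure.equalize_hist(out)
    return out


def binarize_and_label(
    image: np.ndarray, threshold: float, remove_border: bool = False
) -> np.ndarray:
    """Global threshold followed by 8-connected component labelling."""
    binary = np.asarray(image) > threshold
    if remove_border:
        from skimage.segmentation import clear_border

        binary = clear_border(binary)
    return measure.label(binary, connectivity=2)


# ---------------------------------------------------------------------------
# shape


def perimeter_length(region: np.ndarray) -> float:
    """Perimeter estimate: length of the convex hull of the pixel squares.

    Treating each region pixel as a unit square and taking the convex hull
    of all square corners gives the continuous perimeter exactly for convex
    axis-aligned shapes (4 for a single pixel, 4s for an s-pixel square) and
    a close outer estimate for rasterized disks, which is what a circularity
    index needs.
    """
    region = np.asarray(region) > 0
    rows, cols = np.nonzero(region)
    if rows.size == 0:
        raise ValueError("empty region")
    if rows.size == 1:
        return 4.0
    corners = np.concatenate(
        [
            np.column_stack([rows + dr, cols + dc])
            for dr in (-0.5, 0.5)
            for dc in (-0.5, 0.5)
        ]
    )
    if np.ptp(rows) == 0 or np.ptp(cols) == 0:
        # 1-pixel-wide line: hull is a rectangle
        return 2.0 * (np.ptp(rows) + 1) + 2.0 * (np.ptp(cols) + 1)
    hull = ConvexHull(corners)
    pts = corners[hull.vertices]
    return float(np.hypot(*(pts - np.roll(pts, -1, axis=0)).T).sum())


def circularity(region: np.ndarray) -> float:
    """4 * pi * A / R^2: near 1 for disks, small for elongated regions."""
    region = np.asarray(region) > 0
    area = float(region.sum())
    if area == 0:
        raise ValueError("empty region")
    return 4.0 * np.pi * area / perimeter_length(region) ** 2


def _region_centroid(region: np.ndarray):
    rows, cols = np.nonzero(region)
    return rows.mean(), cols.mean()


def shape_features(region: np.ndarray, lung_mask: np.ndarray | None = None) -> dict:
    """Area, axis ratio, solidity, normalized center distance, centroid.

    ``Shape_4`` measures how far the candidate sits from the lung-field
    centroid, in units of the candidate's own equivalent radius.
    """
    region = np.asarray(region) > 0
    if not region.any():
        raise ValueError("empty region")
    props = measure.regionprops(region.astype(np.uint8))[0]
    area = float(props.area)
    if props.axis_major_length > 1e-12:
        axis_ratio = props.axis_minor_length / props.axis_major_length
    else:
        axis_ratio = 0.0
    solidity = float(props.solidity)
    cr, cc = props.centroid
    if lung_mask is not None and np.asarray(lung_mask).sum() > 0:
        lr, lc = _region_centroid(np.asarray(lung_mask) > 0)
    else:
        lr, lc = (region.shape[0] - 1) / 2.0, (region.shape[1] - 1) / 2.0
    dist = np.hypot(cr - lr, cc - lc)
    return {
        "Shape_1": area,
        "Shape_2": float(axis_ratio),
        "Shape_3": solidity,
        "Shape_4": float(dist / np.sqrt(area / np.pi)),
        "can.u": float(cc),
        "can.v": float(cr),
    }


# ---------------------------------------------------------------------------
# gray level


def default_surround_radius(area: float) -> int:
    return max(3, int(round(0.5 * np.sqrt(area / np.pi))))


def gray_features(
    region: np.ndarray,
    preprocessed: np.ndarray,
    enhanced: np.ndarray,
    dilation_radius: int | None = None,
) -> dict:
    """Region-minus-surround mean/sd/min/max on two images (8 values).

    The surround is the dilated region minus the region itself; its radius
    defaults to half the candidate's equivalent radius (at least 3 px).
    """
    region = np.asarray(region) > 0
    if not region.any():
        raise ValueError("empty region")
    r = dilation_radius or default_surround_radius(region.sum())
    surround = morphology.dilation(region, morphology.disk(r)) & ~region
    if not surround.any():
        raise ValueError("empty surround: region touches the border everywhere")
    out = {}
    for base, img in (("Gray_1", preprocessed), ("Gray_5", enhanced)):
        img = np.asarray(img, dtype=np.float64)
        a, b = img[region], img[surround]
        k = int(base.split("_")[1])
        out[f"Gray_{k}"] = float(a.mean() - b.mean())
        out[f"Gray_{k + 1}"] = float(a.std() - b.std())
        out[f"Gray_{k + 2}"] = float(a.min() - b.min())
        out[f"Gray_{k + 3}"] = float(a.max() - b.max())
    return out


# ---------------------------------------------------------------------------
# gradient concentration


def gradient_features(
    region: np.ndarray,
    image: np.ndarray,
    t1: float | None = None,
    t2: float | None = None,
    normalize_sd: bool = False,
) -> dict:
    """Gradient-concentration statistics over eight angular sectors.

    At each region pixel whose gradient magnitude lies in [t1, t2], the
    cosine of the angle between the image gradient and the direction toward
    the region centroid is taken; sector means Gr^h are averaged into Grad_1,
    spread into Grad_2 (square root of the raw sum of squared deviations; an
    optional 1/8 normalization is available), and Grad_3 = Grad_1 / Grad_2.
    High positive Grad_1 with small Grad_2 marks a radially symmetric bright
    blob.
    """
    region = np.asarray(region) > 0
    if not region.any():
        raise ValueError("empty region")
    image = np.asarray(image, dtype=np.float64)
    gr, gc = np.gradient(image)
    rows, cols = np.nonzero(region)
    cr, cc = rows.mean(), cols.mean()
    grv, gcv = gr[rows, cols], gc[rows, cols]
    mag = np.hypot(grv, gcv)
    if t1 is None:
        t1 = np.percentile(mag, 10.0)
    if t2 is None:
        t2 = np.percentile(mag, 98.0)
    if t1 >= t2:
        raise ValueError(f"require t1 < t2, got {t1} >= {t2}")
    dr, dc = cr - rows, cc - cols
    dist = np.hypot(dr, dc)
    ok = (mag >= t1) & (mag <= t2) & (mag > 0) & (dist > 0)
    if not ok.any():
        raise ValueError("no pixels survive the gradient-magnitude gating")
    cosang = (grv * dr + gcv * dc) / np.where(ok, mag * dist, 1.0)
    theta = np.arctan2(rows - cr, cols - cc)
    sector = ((theta + np.pi) / (np.pi / 4.0)).astype(int) % 8
    means = np.zeros(8)
    for h in range(8):
        sel = ok & (sector == h)
        if sel.any():
            means[h] = cosang[sel].mean()
    g1 = float(means.mean())
    ss = float(((means - g1) ** 2).sum())
    g2 = float(np.sqrt(ss / 8.0)) if normalize_sd else float(np.sqrt(ss))
    g3 = g1 / g2 if g2 > 1e-12 else 0.0
    return {"Grad_1": g1, "Grad_2": g2, "Grad_3": float(g3)}


# ---------------------------------------------------------------------------
# surface curvature


def surface_features(region: np.ndarray, enhanced: np.ndarray) -> dict:
    """Principal curvatures of a quartic surface fit at its highest point.

    The enhanced image over the region is least-squares fitted with a full
    bivariate fourth-order polynomial; Surface_1 and Surface_2 are the
    Hessian eigenvalues (smaller and larger absolute value, signs preserved)
    at the highest fitted value inside the region, and Surface_3 is their
    product (the Gaussian curvature numerator).
    """
    region = np.asarray(region) > 0
    rows, cols = np.nonzero(region)
    if rows.size < 15:
        raise ValueError("need >= 15 region pixels for a quartic fit")
    z = np.asarray(enhanced, dtype=np.float64)[rows, cols]
    cr, cc = rows.mean(), cols.mean()
    x, y = cols - cc, rows - cr
    terms = [(i, j) for total in range(5) for i in range(total + 1)
             for j in [total - i]]
    A = np.column_stack([x**i * y**j for i, j in terms])
    coef, _res, rank, _sv = np.linalg.lstsq(A, z, rcond=None)
    if rank < len(terms):
        raise ValueError("rank-deficient quartic fit over this region")
    fitted = A @ coef
    k = int(np.argmax(fitted))
    x0, y0 = x[k], y[k]
    fxx = fyy = fxy = 0.0
    for c, (i, j) in zip(coef, terms):
        if i >= 2:
            fxx += c * i * (i - 1) * x0 ** (i - 2) * y0**j
        if j >= 2:
            fyy += c * j * (j - 1) * x0**i * y0 ** (j - 2)
        if i >= 1 and j >= 1:
            fxy += c * i * j * x0 ** (i - 1) * y0 ** (j - 1)
    eigs = np.linalg.eigvalsh(np.array([[fxx, fxy], [fxy, fyy]]))
    lam_min, lam_max = sorted(eigs, key=abs)
    return {
        "Surface_1": float(lam_min),
        "Surface_2": float(lam_max),
        "Surface_3": float(lam_min * lam_max),
    }


# ---------------------------------------------------------------------------
# texture (GLCM)


def _glcm(region, image, n_bins, offsets):
    region = np.asarray(region) > 0
    image = np.asarray(image, dtype=np.float64)
    vals = image[region]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        levels = np.clip(
            ((image - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1
        )
    else:
        levels = np.zeros_like(image, dtype=int)
    C = np.zeros((n_bins, n_bins))
    for dr, dc in offsets:
        ra, rb = _shift_views(region, dr, dc)
        la, lb = _shift_views(levels, dr, dc)
        sel = ra & rb
        if sel.any():
            np.add.at(C, (la[sel], lb[sel]), 1.0)
            np.add.at(C, (lb[sel], la[sel]), 1.0)  # symmetric
    total = C.sum()
    if total == 0:
        raise ValueError("no co-occurring pixel pairs inside the region")
    return C / total


def _shift_views(x, dr, dc):
    h, w = x.shape
    ra = slice(0, h - dr) if dr >= 0 else slice(-dr, h)
    rb = slice(dr, h) if dr >= 0 else slice(0, h + dr)
    ca = slice(0, w - dc) if dc >= 0 else slice(-dc, w)
    cb = slice(dc, w) if dc >= 0 else slice(0, w + dc)
    return x[ra, ca], x[rb, cb]


def texture_features(
    region: np.ndarray,
    preprocessed: np.ndarray,
    n_bins: int = 16,
    offsets: tuple = ((0, 1), (1, 0), (1, 1), (1, -1)),
) -> dict:
    """Co-occurrence statistics of the quantized region gray levels.

    Texture_1 and Texture_2 square the matrix entries (energy and a
    squared-weighted contrast); Texture_3..6 are the conventional GLCM
    contrast, homogeneity, correlation and entropy of the same matrix.
    """
    C = _glcm(region, preprocessed, n_bins, offsets)
    i, j = np.indices(C.shape)
    t1 = float((C**2).sum())
    t2 = float(((i - j) ** 2 * C**2).sum())
    t3 = float(((i - j) ** 2 * C).sum())
    t4 = float((C / (1.0 + (i - j) ** 2)).sum())
    mu_i = (i * C).sum()
    mu_j = (j * C).sum()
    sd_i = np.sqrt(((i - mu_i) ** 2 * C).sum())
    sd_j = np.sqrt(((j - mu_j) ** 2 * C).sum())
    if sd_i > 1e-12 and sd_j > 1e-12:
        t5 = float((((i - mu_i) * (j - mu_j) * C).sum()) / (sd_i * sd_j))
    else:
        t5 = 1.0
    nz = C[C > 0]
    t6 = float(-(nz * np.log2(nz)).sum())
    return {
        "Texture_1": t1, "Texture_2": t2, "Texture_3": t3,
        "Texture_4": t4, "Texture_5": t5, "Texture_6": t6,
    }


# ---------------------------------------------------------------------------
# boundary / edge overlap


def edge_chains(
    image: np.ndarray,
    edge_sigma: float = 2.0,
    edge_low: float | None = None,
    edge_high: float | None = None,
) -> np.ndarray:
    """Canny edge chains dilated by one pixel (the overlap tolerance)."""
    edges = skfeature.canny(
        np.asarray(image, dtype=np.float64),
        sigma=edge_sigma, low_threshold=edge_low, high_threshold=edge_high,
    )
    return morphology.dilation(edges, morphology.disk(1))


def false_positive_feature(
    region: np.ndarray,
    image: np.ndarray,
    edge_sigma: float = 2.0,
    edge_low: float | None = None,
    edge_high: float | None = None,
    edges: np.ndarray | None = None,
) -> float:
    """Fraction of the region boundary lying on an edge chain.

    Edge chains are Canny edges (non-maximum suppression + hysteresis),
    dilated by one pixel for tolerance; the boundary is the region's inner
    8-connected boundary.  Candidates that merely trace an anatomical edge
    (a rib border, the lung wall) score near 1.
    """
    region = np.asarray(region) > 0
    if not region.any():
        raise ValueError("empty region")
    if edges is None:
        edges = edge_chains(image, edge_sigma, edge_low, edge_high)
    boundary = region & ~morphology.erosion(
        region, morphology.footprint_rectangle((3, 3))
    )
    n_boundary = boundary.sum()
    if n_boundary == 0:
        return 0.0
    return float((boundary & edges).sum() / n_boundary)


# ---------------------------------------------------------------------------
# likelihood-map descriptors


def candidate_likelihood_features(
    candidate, step1_map, step2_map, image: np.ndarray
) -> dict:
    """Peak likelihoods and gray-level coefficients of variation per step.

    ``can.Grad_k`` is the candidate region's maximum likelihood in the
    step-k map; ``can.CV_k`` is sd/mean of the candidate's gray levels over
    the step-k support inside the region (0 when the mean vanishes).
    """
    region = np.asarray(candidate.region) > 0
    image = np.asarray(image, dtype=np.float64)
    out = {}
    for k, lmap in ((1, step1_map), (2, step2_map)):
        vals = np.asarray(lmap.values, dtype=np.float64)
        out[f"can.Grad_{k}"] = float(vals[region].max()) if region.any() else 0.0
        support = region & (vals > 0)
        g = image[support]
        if g.size and abs(g.mean()) > 1e-12:
            out[f"can.CV_{k}"] = float(g.std() / g.mean())
        else:
            out[f"can.CV_{k}"] = 0.0
    return out


# ---------------------------------------------------------------------------
# assembly


def _extract_domain(
    candidate, image, step1, step2, lung_mask, cfg: FeatureConfig,
    pre: np.ndarray | None = None,
    edges: np.ndarray | None = None,
) -> dict:
    region = (
        candidate.core_region if candidate.core_region is not None
        else candidate.region
    )
    region = np.asarray(region) > 0
    if pre is None:
        pre = preprocess(image, cfg)
    enhanced = np.asarray(step2.values, dtype=np.float64)
    out = {}

    def run(name, fn):
        try:
            res = fn()
        except Exception as exc:
            raise type(exc)(f"{name}: {exc}") from exc
        out.update(res if isinstance(res, dict) else {name: res})

    run("likelihood", lambda: candidate_likelihood_features(
        candidate, step1, step2, image))
    run("shape", lambda: shape_features(region, lung_mask))
    out["can.u"] = float(candidate.centroid[1])
    out["can.v"] = float(candidate.centroid[0])
    run("gray", lambda: gray_features(region, pre, enhanced))
    run("gradient", lambda: gradient_features(
        region, image,
        normalize_sd=cfg.normalize_gradient_sd))
    run("surface", lambda: surface_features(region, enhanced))
    run("texture", lambda: texture_features(
        region, pre, cfg.glcm_bins, cfg.glcm_offsets))
    run("FalsePositive", lambda: false_positive_feature(
        region, image, cfg.edge_sigma, cfg.edge_low, cfg.edge_high,
        edges=edges))
    return {name: out[name] for name in PER_DOMAIN_FEATURE_NAMES}


def extract_all(
    candidate,
    xray: np.ndarray,
    soft: np.ndarray,
    xray_maps: tuple,
    soft_maps: tuple,
    lung_mask: np.ndarray | None = None,
    config: FeatureConfig | None = None,
    preprocessed: tuple | None = None,
    edges: tuple | None = None,
) -> dict:
    """The full 62-value vector: 31 per domain, x-ray block then soft block.

    Both domains use the identical candidate region; keys are prefixed
    ``xray.`` and ``soft.``.  ``preprocessed`` may carry the two
    already-preprocessed images so callers extracting many candidates from
    one image pay the median/unsharp/equalization cost once.
    """
    cfg = config or FeatureConfig()
    pre_x, pre_s = preprocessed if preprocessed is not None else (None, None)
    edges_x = edges[0] if edges is not None else None
    edges_s = edges[1] if edges is not None else None
    out = {}
    for prefix, image, maps, pre, edg in (
        ("xray", xray, xray_maps, pre_x, edges_x),
        ("soft", soft, soft_maps, pre_s, edges_s),
    ):
        block = _extract_domain(
            candidate, image, maps[0], maps[1], lung_mask, cfg, pre, edg
        )
        out.update({f"{prefix}.{k}": v for k, v in block.items()})
    return out


def baseline_features(
    region: np.ndarray,
    preprocessed: np.ndarray,
    n_bins: int = 16,
    offsets: tuple = ((0, 1), (1, 0), (1, 1), (1, -1)),
) -> dict:
    """The conventional 14-feature set of the comparison CAD."""
    region = np.asarray(region) > 0
    if not region.any():
        raise ValueError("empty region")
    img = np.asarray(preprocessed, dtype=np.float64)
    vals = img[region]
    tex = texture_features(region, img, n_bins, offsets)
    sd = float(vals.std())
    # histogram entropy / uniformity over the same quantization as the GLCM
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        levels = np.clip(((vals - lo) / (hi - lo) * n_bins).astype(int),
                         0, n_bins - 1)
    else:
        levels = np.zeros(vals.size, dtype=int)
    p = np.bincount(levels, minlength=n_bins) / vals.size
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {
        "glcm_contrast": tex["Texture_3"],
        "glcm_correlation": tex["Texture_5"],
        "glcm_energy": tex["Texture_1"],
        "glcm_homogeneity": tex["Texture_4"],
        "gray_level": float(np.median(vals)),
        "mean": float(vals.mean()),
        "std": sd,
        "entropy": entropy,
        "circularity": circularity(region),
        "uniformity": float((p**2).sum()),
        "smoothness": float(1.0 - 1.0 / (1.0 + sd**2)),
        "skewness": float(skew(vals)) if sd > 1e-12 else 0.0,
        "area": float(region.sum()),
        "perimeter": perimeter_length(region),
    }
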