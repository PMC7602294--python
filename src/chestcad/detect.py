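"""Nodule enhancement and clustering-watershed candidate extraction.

Enhancement is a two-step opening-residue (top-hat) filter: the image minus
its gray-level morphological opening with a disk, at two structuring-element
scales bracketing the expected nodule radius.  The residue is clipped at
zero and rescaled by the mask-interior maximum to a likelihood in [0, 1].

Candidates come from the watershed transform of the negated likelihood: one
catchment basin per regional likelihood maximum.  A clustering pass merges a
seed's basin with adjacent basins whenever the saddle between them is high
relative to the two basins' peaks, so one jagged opacity split across several
peaks becomes a single candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation

__all__ = [
    "DetectorConfig",
    "LikelihoodMap",
    "Candidate",
    "enhance_nodules",
    "watershed_basins",
    "cluster_candidates",
    "detect_candidates",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Tunables for enhancement and clustering.

    Disk radii default to 6 and 14 px, bracketing the ~13 px nodule radius at
    the 512 px / 0.7 mm reference geometry; scale them with the image.
    """

    scales: tuple = (6.0, 14.0)
    merge_fraction: float = 0.8
    likelihood_floor: float = 0.3
    max_candidates_per_image: int = 30
    core_fraction: float = 0.5
    hit_distance_mm: float = 25.0


@dataclass
class LikelihoodMap:
    """Nodule-likelihood image in [0, 1], zero outside the lung mask."""

    values: np.ndarray
    step: int  # enhancement step (1 or 2) that produced the map


@dataclass
class Candidate:
    """A merged-basin candidate region with its summary measurements.

    ``region`` is the union of merged catchment basins; ``core_region`` is
    the connected half-peak support around the candidate's maximum, the
    compact segment feature extraction operates on.
    """

    region: np.ndarray
    centroid: tuple
    peak_likelihood: float
    basin_count: int
    domain: str = "soft-tissue"
    core_region: np.ndarray | None = None
    basin_labels: frozenset = frozenset()

    @property
    def area_px(self) -> int:
        return int(self.region.sum())


def enhance_nodules(image: np.ndarray, mask: np.ndarray, scales=(6.0, 14.0)):
    """Two top-hat likelihood maps at increasing structuring-element radii."""
    image = np.asarray(image, dtype=np.float64)
    mask_b = np.asarray(mask) > 0
    r1, r2 = scales
    if r1 <= 0 or r2 <= 0:
        raise ValueError("structuring-element radii must be positive")
    if r2 <= r1:
        raise ValueError("step-2 radius must exceed step-1 radius")
    if 2 * r2 + 1 > min(image.shape):
        raise ValueError(
            f"radius {r2} px exceeds the image size {image.shape}"
        )
    maps = []
    for step, r in enumerate((r1, r2), start=1):
        footprint = morphology.disk(int(round(r)))
        residue = image - morphology.opening(image, footprint)
        residue = np.clip(residue, 0.0, None)
        residue[~mask_b] = 0.0
        peak = residue[mask_b].max() if mask_b.any() else 0.0
        values = residue / peak if peak > 0 else np.zeros_like(residue)
        maps.append(LikelihoodMap(values=values, step=step))
    return maps[0], maps[1]


def _plateau_maxima(values: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Labelled regional-maximum plateaus of the masked likelihood."""
    work = np.where(mask_b, values, -1.0)
    maxima = morphology.local_maxima(work, connectivity=2, allow_borders=True)
    maxima &= mask_b
    return measure.label(maxima, connectivity=2)


def watershed_basins(likelihood: LikelihoodMap, mask: np.ndarray) -> np.ndarray:
    """Catchment basins of the negated likelihood, one per regional maximum.

    Basins partition the mask: every mask pixel receives exactly one label
    (labels start at 1; 0 marks outside-mask pixels).  Plateau maxima merge
    into a single marker.
    """
    values = np.asarray(likelihood.values, dtype=np.float64)
    mask_b = np.asarray(mask) > 0
    markers = _plateau_maxima(values, mask_b)
    if markers.max() == 0:
        return mask_b.astype(np.int32)
    return segmentation.watershed(
        -values, markers=markers, mask=mask_b, connectivity=2
    ).astype(np.int32)


def _shifted_pair(x: np.ndarray, dr: int, dc: int):
    """Views of x at each pixel and at its (dr, dc) neighbor."""
    h, w = x.shape
    ra = slice(0, h - dr) if dr >= 0 else slice(-dr, h)
    rb = slice(dr, h) if dr >= 0 else slice(0, h + dr)
    ca = slice(0, w - dc) if dc >= 0 else slice(-dc, w)
    cb = slice(dc, w) if dc >= 0 else slice(0, w + dc)
    return x[ra, ca], x[rb, cb]


def _basin_saddles(basins: np.ndarray, values: np.ndarray) -> dict:
    """Saddle height between each pair of 8-adjacent basins.

    The saddle of a pair is the highest crossing of their shared boundary:
    max over adjacent pixel pairs of the lower of the two likelihoods.
    """
    saddles: dict = {}
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a, b = _shifted_pair(basins, dr, dc)
        va, vb = _shifted_pair(values, dr, dc)
        diff = (a != b) & (a > 0) & (b > 0)
        if not diff.any():
            continue
        la, lb = a[diff], b[diff]
        lo = np.minimum(va[diff], vb[diff])
        for ka, kb, v in zip(np.minimum(la, lb), np.maximum(la, lb), lo):
            key = (int(ka), int(kb))
            if v > saddles.get(key, -np.inf):
                saddles[key] = float(v)
    return saddles


def _core_region(region: np.ndarray, values: np.ndarray, fraction: float):
    peak = values[region].max()
    core = region & (values >= fraction * peak)
    labels = measure.label(core, connectivity=2)
    peak_pos = np.unravel_index(np.argmax(np.where(region, values, -1.0)),
                                values.shape)
    lab = labels[peak_pos]
    return labels == lab if lab else region


def cluster_candidates(
    basins: np.ndarray,
    likelihood: LikelihoodMap,
    seeds,
    merge_fraction: float = 0.8,
    core_fraction: float = 0.5,
    domain: str = "soft-tissue",
) -> list:
    """Grow one candidate per seed by merging basins across high saddles.

    A neighbor basin joins the cluster when the saddle to some member basin
    is at least ``merge_fraction`` times the lower of the two basins' peaks;
    merging iterates to a fixed point.  Candidates with identical merged
    regions are deduplicated.  Seeds outside the mask are skipped with a
    warning.
    """
    values = np.asarray(likelihood.values, dtype=np.float64)
    n_basins = int(basins.max())
    peaks = np.zeros(n_basins + 1)
    if n_basins:
        peaks[1:] = ndi.maximum(
            values, labels=basins, index=np.arange(1, n_basins + 1)
        )
    saddles = _basin_saddles(basins, values)
    neighbors: dict = {lab: {} for lab in range(1, n_basins + 1)}
    for (a, b), v in saddles.items():
        neighbors[a][b] = v
        neighbors[b][a] = v

    out, seen = [], set()
    for seed in seeds:
        r, c = int(round(seed[0])), int(round(seed[1]))
        if (
            not (0 <= r < basins.shape[0] and 0 <= c < basins.shape[1])
            or basins[r, c] == 0
        ):
            warnings.warn(f"seed {seed} lies outside the lung mask; skipped")
            continue
        cluster = {int(basins[r, c])}
        changed = True
        while changed:
            changed = False
            for member in list(cluster):
                for nb, saddle in neighbors[member].items():
                    if nb in cluster:
                        continue
                    if saddle >= merge_fraction * min(peaks[member], peaks[nb]):
                        cluster.add(nb)
                        changed = True
        key = frozenset(cluster)
        if key in seen:
            continue
        seen.add(key)
        region = np.isin(basins, list(cluster))
        wts = np.where(region, values, 0.0)
        total = wts.sum()
        if total > 0:
            rr, cc = np.mgrid[0 : region.shape[0], 0 : region.shape[1]]
            centroid = ((rr * wts).sum() / total, (cc * wts).sum() / total)
        else:
            rr, cc = np.nonzero(region)
            centroid = (float(rr.mean()), float(cc.mean()))
        out.append(
            Candidate(
                region=region,
                centroid=centroid,
                peak_likelihood=float(values[region].max()),
                basin_count=len(cluster),
                domain=domain,
                core_region=_core_region(region, values, core_fraction),
                basin_labels=key,
            )
        )
    return out


def detect_candidates(
    image: np.ndarray,
    mask: np.ndarray,
    config: DetectorConfig | None = None,
    domain: str = "soft-tissue",
):
    """Full candidate pipeline: enhance, find peaks, watershed, cluster, rank.

    Seeds are all regional maxima of the step-2 likelihood map whose value
    reaches ``likelihood_floor``; at most ``max_candidates_per_image``
    candidates are kept, ranked by peak likelihood.  Returns the candidate
    list (optionally with the two likelihood maps via ``detect_with_maps``).
    """
    cands, _maps = detect_with_maps(image, mask, config, domain)
    return cands


def detect_with_maps(
    image: np.ndarray,
    mask: np.ndarray,
    config: DetectorConfig | None = None,
    domain: str = "soft-tissue",
):
    cfg = config or DetectorConfig()
    mask_b = np.asarray(mask) > 0
    if not mask_b.any():
        return [], (None, None)
    step1, step2 = enhance_nodules(image, mask_b, cfg.scales)
    markers = _plateau_maxima(step2.values, mask_b)
    seeds = []
    for lab in range(1, markers.max() + 1):
        rr, cc = np.nonzero(markers == lab)
        order = np.lexsort((cc, rr))
        r, c = int(rr[order[0]]), int(cc[order[0]])
        if step2.values[r, c] >= cfg.likelihood_floor:
            seeds.append((r, c))
    if not seeds:
        return [], (step1, step2)
    basins = watershed_basins(step2, mask_b)
    cands = cluster_candidates(
        basins, step2, seeds, cfg.merge_fraction, cfg.core_fraction, domain
    )
    cands.sort(key=lambda cd: -cd.peak_likelihood)
    return cands[: cfg.max_candidates_per_image], (step1, step2)
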