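"""Synthetic chest phantoms with exact bone / soft-tissue ground truth.

A phantom emulates the aspects of a posteroanterior chest radiograph that the
detection pipeline actually exercises: two smooth bright lung fields,
quasi-periodic oblique rib bands and near-horizontal clavicle bands of
controllable contrast, and circular nodules (truncated Gaussian domes) of
controllable diameter and five-grade subtlety.  Image formation is strictly
additive,

    xray = soft_truth + bone + Gaussian noise,

so the bone-only teaching image and the soft-tissue target are known exactly
— the role real dual-energy bone images play when training the suppressor.
Intensities are arbitrary linear units.

Not emulated: attenuation physics, scatter, pose variation, mediastinal or
sub-diaphragmatic opacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "default_config",
    "generate_phantom",
    "generate_dataset",
]

#: Peak nodule contrast per subtlety grade, grade 1 ("tremendously subtle")
#: lowest.  Units are the phantom's linear intensity units (lung field
#: amplitude is 60, ribs default to 30).
DEFAULT_SUBTLETY_CONTRAST = {1: 4.0, 2: 8.0, 3: 12.0, 4: 18.0, 5: 25.0}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, contrast and noise settings for one phantom.

    Pixel-unit defaults refer to a 512 px image at 0.7 mm spacing (a 2048 px
    film at 0.175 mm, subsampled 4x).  Use :func:`default_config` to obtain a
    consistently rescaled config at another resolution.
    """

    image_size_px: int = 512
    pixel_spacing_mm: float = 0.7
    rib_count: int = 6
    rib_width_px: float = 14.0
    rib_period_px: float = 40.0
    rib_angle_deg: float = 35.0
    rib_contrast: float = 30.0
    clavicle_contrast: float = 25.0
    nodule_diameter_mm: float = 17.8
    nodule_contrast_by_subtlety: dict = field(
        default_factory=lambda: dict(DEFAULT_SUBTLETY_CONTRAST)
    )
    noise_sd: float = 2.0
    seed: int = 0
    n_nodules: int = 0
    subtlety_grades: tuple = ()
    nodules_under_ribs: bool = False
    lung_base: float = 100.0
    lung_amplitude: float = 60.0
    lobe_width_frac: float = 0.155
    lobe_height_frac: float = 0.34

    def __post_init__(self):
        if self.image_size_px < 64:
            raise ValueError("image_size_px must be >= 64")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.rib_width_px >= self.rib_period_px:
            raise ValueError("rib_width_px must be smaller than rib_period_px")
        if self.rib_contrast < 0 or self.clavicle_contrast < 0:
            raise ValueError("contrasts must be nonnegative")
        if self.nodule_diameter_mm <= 0:
            raise ValueError("nodule_diameter_mm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        grades = sorted(self.nodule_contrast_by_subtlety)
        contrasts = [self.nodule_contrast_by_subtlety[g] for g in grades]
        if any(c < 0 for c in contrasts):
            raise ValueError("nodule contrasts must be nonnegative")
        if any(b <= a for a, b in zip(contrasts, contrasts[1:])):
            raise ValueError(
                "subtlety grades must map to strictly increasing contrasts"
            )

    @property
    def nodule_radius_px(self) -> int:
        return int(round(self.nodule_diameter_mm / self.pixel_spacing_mm / 2.0))


def default_config(image_size_px: int = 512, **overrides) -> PhantomConfig:
    """A :class:`PhantomConfig` rescaled from the 512 px reference geometry.

    Pixel spacing is adjusted so the physical field of view (358.4 mm) stays
    constant; rib width and period scale with the image side.
    """
    s = image_size_px / 512.0
    cfg = PhantomConfig(
        image_size_px=image_size_px,
        pixel_spacing_mm=0.7 / s,
        rib_width_px=14.0 * s,
        rib_period_px=40.0 * s,
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class PhantomSample:
    """One phantom: x-ray, exact bone and soft-tissue truth, mask, annotations.

    ``nodules`` holds ``(center_row, center_col, radius_px, subtlety_grade)``
    tuples, 0-based pixel coordinates.
    """

    xray: np.ndarray
    bone: np.ndarray
    soft_truth: np.ndarray
    lung_mask: np.ndarray
    nodules: list
    config: PhantomConfig

    @property
    def pixel_spacing_mm(self) -> float:
        return self.config.pixel_spacing_mm


def _lobe_params(n: int, hf: float = 0.34, wf: float = 0.155):
    """Centers and semi-axes (row, col) of the two elliptical lobes."""
    # two symmetric elliptical lobes; semi-axes controllable for shape-model
    # experiments
    return [
        ((0.52 * n, 0.30 * n), (hf * n, wf * n)),
        ((0.52 * n, 0.70 * n), (hf * n, wf * n)),
    ]


def _lobe_fields(n: int, hf: float = 0.34, wf: float = 0.155):
    """Per-lobe signed 'inside-ness' fields (1 - normalized ellipse radius)."""
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    fields = []
    for (cr, ccen), (ar, ac) in _lobe_params(n, hf, wf):
        q = ((rr - cr) / ar) ** 2 + ((cc - ccen) / ac) ** 2
        fields.append(1.0 - np.sqrt(q))
    return fields


def _bone_image(cfg: PhantomConfig, lung_mask: np.ndarray):
    """Rib + clavicle bands, zero outside the lung mask.

    Returns the bone image and, for nodule placement, a per-pixel 'under a
    rib band center' score in [0, 1].
    """
    n = cfg.image_size_px
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    bone = np.zeros((n, n))
    under_rib = np.zeros((n, n))
    half = cfg.rib_width_px / 2.0
    lobes = _lobe_params(n, cfg.lobe_height_frac, cfg.lobe_width_frac)
    for lobe_idx, ((cr, ccen), (ar, ac)) in enumerate(lobes):
        in_lobe = (((rr - cr) / ar) ** 2 + ((cc - ccen) / ac) ** 2) <= 1.0
        # ribs run downward-oblique, mirrored between the two lobes
        theta = np.deg2rad(cfg.rib_angle_deg) * (1 if lobe_idx == 0 else -1)
        t = (rr - cr) * np.cos(theta) + (cc - ccen) * np.sin(theta)
        t_lo = t[in_lobe].min()
        span = (cfg.rib_count - 1) * cfg.rib_period_px
        t0 = t_lo + ((t[in_lobe].max() - t_lo) - span) / 2.0
        for k in range(cfg.rib_count):
            d = np.abs(t - (t0 + k * cfg.rib_period_px))
            band = np.where(
                d <= half, 0.5 * (1.0 + np.cos(np.pi * d / half)), 0.0
            )
            bone += cfg.rib_contrast * band * in_lobe
            under_rib = np.maximum(under_rib, band * in_lobe)
        # clavicle: one near-horizontal band across the lobe apex
        phi = np.deg2rad(8.0) * (1 if lobe_idx == 0 else -1)
        tc = (rr - (cr - 0.82 * ar)) * np.cos(phi) + (cc - ccen) * np.sin(phi)
        dc = np.abs(tc)
        chalf = half * 1.2
        band = np.where(
            dc <= chalf, 0.5 * (1.0 + np.cos(np.pi * dc / chalf)), 0.0
        )
        bone += cfg.clavicle_contrast * band * in_lobe
    bone *= lung_mask
    return bone, under_rib * lung_mask


def _nodule_dome(n: int, center: tuple, radius: float, contrast: float):
    """Truncated Gaussian dome: peak ``contrast`` at center, zero at radius."""
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    r2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    sigma = radius / 2.0
    g = np.exp(-r2 / (2.0 * sigma**2))
    g_edge = np.exp(-(radius**2) / (2.0 * sigma**2))
    dome = np.clip((g - g_edge) / (1.0 - g_edge), 0.0, None)
    dome[r2 > radius**2] = 0.0
    return contrast * dome


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Generate one phantom; deterministic for a fixed ``config.seed``."""
    cfg = config
    n = cfg.image_size_px
    rng = np.random.default_rng(cfg.seed)

    fields = _lobe_fields(n, cfg.lobe_height_frac, cfg.lobe_width_frac)
    lung_mask = ((fields[0] >= 0.0) | (fields[1] >= 0.0)).astype(np.uint8)

    # smooth bright lung fields on a darker body background, plus a gentle
    # planar trend so background correction has something to remove
    lungness = np.clip(np.maximum(fields[0], fields[1]), 0.0, 1.0)
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    soft = (
        cfg.lung_base
        + cfg.lung_amplitude * np.sqrt(lungness)
        + 4.0 * (rr / n)
        + 2.0 * (cc / n)
    )

    bone, under_rib = _bone_image(cfg, lung_mask)

    radius = cfg.nodule_radius_px
    lobe_width_px = 2 * cfg.lobe_width_frac * n
    if cfg.n_nodules > 0 and 2 * radius >= lobe_width_px:
        raise ValueError(
            f"nodule diameter {2 * radius} px exceeds the lung-lobe width "
            f"({lobe_width_px:.0f} px); shrink nodule_diameter_mm or enlarge "
            "the image"
        )

    grades = list(cfg.subtlety_grades)
    if cfg.n_nodules > 0 and not grades:
        grades = [3] * cfg.n_nodules
    if cfg.n_nodules > 0 and len(grades) != cfg.n_nodules:
        raise ValueError("subtlety_grades length must equal n_nodules")

    # admissible centers: the nodule disk must lie fully inside the mask
    margin = radius + 2
    interior = np.zeros_like(lung_mask, dtype=bool)
    for (cr, ccen), (ar, ac) in _lobe_params(
        n, cfg.lobe_height_frac, cfg.lobe_width_frac
    ):
        # shrink each lobe by the margin expressed as a radius fraction
        shrink = 1.0 - margin / min(ar, ac)
        if shrink > 0:
            q = ((rr - cr) / (ar * shrink)) ** 2 + ((cc - ccen) / (ac * shrink)) ** 2
            interior |= q <= 1.0
    nodules = []
    for i in range(cfg.n_nodules):
        cand = interior.copy()
        if cfg.nodules_under_ribs:
            cand &= under_rib > 0.85
        idx = np.flatnonzero(cand)
        if idx.size == 0:
            raise ValueError(
                "no admissible nodule position (nodule too large for the "
                "lung lobes, or no rib pixels available)"
            )
        pick = idx[rng.integers(idx.size)]
        center = (pick // n, pick % n)
        grade = int(grades[i])
        contrast = cfg.nodule_contrast_by_subtlety[grade]
        soft = soft + _nodule_dome(n, center, radius, contrast)
        nodules.append((int(center[0]), int(center[1]), int(radius), grade))

    noise = (
        rng.normal(0.0, cfg.noise_sd, size=(n, n)) if cfg.noise_sd > 0 else 0.0
    )
    xray = soft + bone + noise
    return PhantomSample(
        xray=xray,
        bone=bone,
        soft_truth=soft,
        lung_mask=lung_mask,
        nodules=nodules,
        config=cfg,
    )


def generate_dataset(
    n_normal: int,
    n_nodule: int,
    config: PhantomConfig,
    subtlety_mix: dict | None = None,
) -> list:
    """Generate ``n_normal`` clean and ``n_nodule`` single-nodule phantoms.

    ``subtlety_mix`` maps subtlety grade to sampling weight; grades are drawn
    under the generator seeded from ``config.seed``.  Every sample gets its
    own derived seed so noise realizations and nodule positions differ.
    """
    if n_normal < 0 or n_nodule < 0:
        raise ValueError("counts must be >= 0")
    if n_nodule > 0:
        if not subtlety_mix:
            raise ValueError("subtlety_mix must be nonempty when n_nodule > 0")
        grades = np.array(sorted(subtlety_mix))
        probs = np.array([subtlety_mix[g] for g in grades], dtype=np.float64)
        probs = probs / probs.sum()
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_normal + n_nodule)
    samples = []
    for i in range(n_normal):
        cfg = replace(config, seed=int(seeds[i]), n_nodules=0, subtlety_grades=())
        samples.append(generate_phantom(cfg))
    for i in range(n_nodule):
        grade = int(rng.choice(grades, p=probs))
        cfg = replace(
            config,
            seed=int(seeds[n_normal + i]),
            n_nodules=max(1, config.n_nodules),
            subtlety_grades=(grade,) * max(1, config.n_nodules),
        )
        samples.append(generate_phantom(cfg))
    return samples
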