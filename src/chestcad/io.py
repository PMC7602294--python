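"""Image and table I/O plus the subsampling resize.

Images travel as float64 arrays in memory and as 8/16-bit grayscale PNG or
TIFF on disk; pixel-spacing metadata rides in a JSON sidecar next to the
image (``<name>.meta.json``) because neither container carries physical
spacing reliably.  Phantom samples are written as a set of images plus a
JSON annotation sidecar, so a whole synthetic study is plain text and
re-readable.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .phantom import PhantomSample

__all__ = [
    "read_image",
    "write_image",
    "resize_subsample",
    "pad_to_multiple",
    "write_sample",
    "read_sample",
    "DEFAULT_SPACING_MM",
]

log = logging.getLogger("chestcad")

DEFAULT_SPACING_MM = 0.7


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def read_image(path) -> tuple[np.ndarray, float]:
    """Read a grayscale PNG/TIFF; returns ``(float64 array, spacing_mm)``.

    RGB input is rejected (convert to grayscale first).  A missing metadata
    sidecar defaults the spacing to 0.7 mm with a logged warning.
    """
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path} is a color image; convert to single-channel grayscale"
        )
    sidecar = _sidecar(path)
    if sidecar.exists():
        spacing = float(json.loads(sidecar.read_text())["pixel_spacing_mm"])
    else:
        spacing = DEFAULT_SPACING_MM
        log.warning(
            "%s: no metadata sidecar; assuming %.2f mm pixel spacing",
            path, spacing,
        )
    return arr.astype(np.float64), spacing


def write_image(
    image: np.ndarray,
    path,
    pixel_spacing_mm: float = DEFAULT_SPACING_MM,
    dtype=np.uint16,
) -> None:
    """Write as 8/16-bit grayscale with a JSON metadata sidecar.

    Values are rounded and clipped to the container range; 16-bit data
    round-trips losslessly when the input is already integral in range.
    """
    path = Path(path)
    info = np.iinfo(dtype)
    data = np.clip(np.round(np.asarray(image)), info.min, info.max).astype(dtype)
    iio.imwrite(path, data)
    _sidecar(path).write_text(
        json.dumps({"pixel_spacing_mm": pixel_spacing_mm})
    )


def resize_subsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean subsampling by an integer factor dividing both sides."""
    image = np.asarray(image, dtype=np.float64)
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return image.copy()
    h, w = image.shape
    if h % factor or w % factor:
        raise ValueError(f"factor {factor} does not divide shape {image.shape}")
    return image.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def pad_to_multiple(image: np.ndarray, multiple: int) -> np.ndarray:
    """Edge-replicate pad so both sides divide by ``multiple``."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return image.copy()
    return np.pad(image, ((0, ph), (0, pw)), mode="edge")


def write_sample(sample: PhantomSample, out_dir, stem: str = "sample") -> None:
    """Write one phantom: four 16-bit PNGs plus a JSON annotation sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spacing = sample.pixel_spacing_mm
    # phantom intensities are small floats; scale by 64 into the 16-bit range
    for name, img in (
        ("xray", sample.xray),
        ("bone", sample.bone),
        ("soft", sample.soft_truth),
    ):
        write_image(np.asarray(img) * 64.0, out / f"{stem}_{name}.png", spacing)
    write_image(
        sample.lung_mask * 255, out / f"{stem}_mask.png", spacing, dtype=np.uint8
    )
    (out / f"{stem}_annotations.json").write_text(json.dumps({
        "pixel_spacing_mm": spacing,
        "intensity_scale": 64.0,
        "nodules": [list(n) for n in sample.nodules],
        "seed": sample.config.seed,
        "image_size_px": sample.config.image_size_px,
    }, indent=2))


def read_sample(out_dir, stem: str = "sample") -> dict:
    """Read back a written phantom as arrays plus its annotations."""
    out = Path(out_dir)
    meta = json.loads((out / f"{stem}_annotations.json").read_text())
    scale = meta.get("intensity_scale", 1.0)
    result = {"annotations": meta}
    for name in ("xray", "bone", "soft"):
        arr, _sp = read_image(out / f"{stem}_{name}.png")
        result[name] = arr / scale
    mask, _sp = read_image(out / f"{stem}_mask.png")
    result["mask"] = (mask > 0).astype(np.uint8)
    return result
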