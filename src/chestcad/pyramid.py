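"""Lossless multi-resolution pyramid built on 2x2 block means.

The decomposition stores, at each level, the difference between an image and
the block-mean-downsampled-then-replicated version of itself.  Because the
upsampling operator is plain pixel replication (no smoothing kernel), the
transform is exactly invertible: adding the replicated low-resolution image
back to the difference image recovers the original to floating-point
round-off.  This is the representation the rib-suppression regressors operate
on, one regressor per difference level plus one for the residual base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Pyramid", "downsample", "upsample", "decompose", "reconstruct"]


def downsample(image: np.ndarray) -> np.ndarray:
    """Halve both sides by replacing each 2x2 block with its arithmetic mean.

    Parameters
    ----------
    image : ndarray
        2-D array with both sides even.

    Returns
    -------
    ndarray of shape ``(H/2, W/2)``, dtype float64.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={image.ndim}")
    h, w = image.shape
    if h % 2 or w % 2:
        raise ValueError(f"both sides must be even to downsample, got {image.shape}")
    return image.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def upsample(image: np.ndarray) -> np.ndarray:
    """Double both sides by replicating each pixel into a 2x2 block."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={image.ndim}")
    return np.repeat(np.repeat(image, 2, axis=0), 2, axis=1)


@dataclass
class Pyramid:
    """Difference images (finest first) plus the lowest-resolution base.

    ``levels[k]`` has exactly twice the side length of ``levels[k+1]``; the
    base has the same shape as a hypothetical ``levels[n_levels]`` would.
    """

    levels: list = field(default_factory=list)
    base: np.ndarray = None

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def __post_init__(self):
        for k in range(len(self.levels) - 1):
            a, b = self.levels[k].shape, self.levels[k + 1].shape
            if a != (2 * b[0], 2 * b[1]):
                raise ValueError(
                    f"level {k} shape {a} is not twice level {k + 1} shape {b}"
                )
        if self.levels:
            a, b = self.levels[-1].shape, self.base.shape
            if a != (2 * b[0], 2 * b[1]):
                raise ValueError(
                    f"finest-to-base shape chain broken: {a} vs base {b}"
                )


def decompose(image: np.ndarray, n_levels: int) -> Pyramid:
    """Split an image into ``n_levels`` difference images plus a base.

    Level ``k`` holds ``G_k - upsample(downsample(G_k))`` where ``G_0`` is the
    input and ``G_{k+1} = downsample(G_k)``; the base is ``G_{n_levels}``.
    Requires both sides divisible by ``2**n_levels``.
    """
    image = np.asarray(image, dtype=np.float64)
    if n_levels < 0:
        raise ValueError("n_levels must be >= 0")
    h, w = image.shape
    f = 2**n_levels
    if h % f or w % f:
        raise ValueError(
            f"image shape {image.shape} not divisible by 2**{n_levels} = {f}"
        )
    levels = []
    g = image
    for _ in range(n_levels):
        low = downsample(g)
        levels.append(g - upsample(low))
        g = low
    return Pyramid(levels=levels, base=g)


def reconstruct(pyramid: Pyramid) -> np.ndarray:
    """Invert :func:`decompose` exactly (up to float rounding)."""
    g = np.asarray(pyramid.base, dtype=np.float64)
    for diff in reversed(pyramid.levels):
        up = upsample(g)
        if up.shape != diff.shape:
            raise ValueError(
                f"level shape {diff.shape} inconsistent with base chain {up.shape}"
            )
        g = up + diff
    return g
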