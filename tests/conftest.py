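"""Shared fixtures: scaled phantom study conditions and a trained suppressor.

Experiments run at 256 px (1.4 mm pixels, half the 512 px reference
resolution) so the full train-suppress-detect-classify chain stays fast; the
nodule radius is 6 px and the enhancement disk radii scale to (3, 8).
"""

import numpy as np
import pytest
from dataclasses import replace

from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from chestcad import phantom as ph
from chestcad.detect import DetectorConfig
from chestcad.mann import SuppressorHyperparams, train_suppressor
from chestcad.pipeline import PipelineConfig

SIZE = 256
GRADE_MIX = {g: 1.0 for g in range(1, 6)}


@pytest.fixture(scope="session")
def base_config():
    return ph.default_config(SIZE, seed=7)


@pytest.fixture(scope="session")
def detector_config():
    return DetectorConfig(scales=(3.0, 8.0))


@pytest.fixture(scope="session")
def pipeline_config(detector_config):
    return PipelineConfig(detector=detector_config, w_c=0.8, seed=3)


@pytest.fixture(scope="session")
def training_samples(base_config):
    """The suppressor's training census: 1 normal + 3 nodule phantoms."""
    cfg = replace(base_config, seed=100, n_nodules=1, nodules_under_ribs=True)
    return ph.generate_dataset(1, 3, cfg, GRADE_MIX)


@pytest.fixture(scope="session")
def suppressor(training_samples):
    return train_suppressor(
        training_samples, n_levels=3, hyperparams=SuppressorHyperparams(seed=7)
    )


@pytest.fixture(scope="session")
def nodule_phantom(base_config):
    """One held-out phantom with a grade-4 nodule under a rib."""
    cfg = replace(
        base_config, seed=55, n_nodules=1, subtlety_grades=(4,),
        nodules_under_ribs=True,
    )
    return ph.generate_phantom(cfg)


def rib_band_amplitude(image, sample, exclude_top_frac=0.3):
    """Rib crest-minus-trough amplitude using the known band geometry.

    Crest pixels sit at rib-band centers (bone within 10% of one full rib
    contrast), trough pixels between bands (bone exactly zero); nodule
    neighborhoods and the clavicle zone are excluded.
    """
    bone = sample.bone
    m = sample.lung_mask > 0
    n = image.shape[0]
    rr, cc = np.mgrid[0:n, 0:n]
    excl = rr < exclude_top_frac * n
    for (r, c, rad, _g) in sample.nodules:
        excl |= (rr - r) ** 2 + (cc - c) ** 2 <= (2 * rad) ** 2
    rc = sample.config.rib_contrast
    crest = m & ~excl & (bone >= 0.9 * rc) & (bone <= 1.1 * rc)
    trough = m & ~excl & (bone == 0)
    return image[crest].mean() - image[trough].mean()


def nodule_peak_contrast(image, sample):
    """Nodule core mean minus local annular surround mean."""
    r, c, rad, _g = sample.nodules[0]
    n = image.shape[0]
    rr, cc = np.mgrid[0:n, 0:n]
    d2 = (rr - r) ** 2 + (cc - c) ** 2
    core = d2 <= (rad / 3.0) ** 2
    ann = (d2 > rad**2) & (d2 <= (1.6 * rad) ** 2) & (sample.lung_mask > 0)
    return image[core].mean() - image[ann].mean()
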