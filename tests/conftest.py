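import numpy as np
import pytest

from stereonir import CameraModel, StereoRig
from stereonir import phantom as ph
from stereonir.io import PipelineConfig


@pytest.fixture(scope="session")
def rig() -> StereoRig:
    """The modelled system: f=35 mm, 20 um pitch, b=40 mm, Z0=450 mm."""
    return StereoRig()


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_pair(config):
    """Noise-free compact tube-pair render shared by several suites."""
    scene = ph.make_tube_pair_scene(1.0)
    left, right, truth = ph.render_stereo_pair(
        scene, config.rig(), config.medium(), noise=None, shape=(256, 384)
    )
    return left, right, truth


def gaussian_ridge(shape=(64, 96), sigma_r=2.0, amplitude=1.0, axis=0, offset=0.0):
    """Bright 1D Gaussian ridge along rows (axis=0: ridge varies down rows)."""
    H, W = shape
    y = np.arange(H) - H / 2.0
    prof = amplitude * np.exp(-(y**2) / (2.0 * sigma_r**2)) + offset
    img = np.repeat(prof[:, None], W, axis=1)
    return img if axis == 0 else img.T
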