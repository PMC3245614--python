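import numpy as np
import pytest

from radialfish import SceneConfig


@pytest.fixture
def cfg2d():
    """Small, fast 2D scene used across unit tests."""
    return SceneConfig(
        image_shape=(100, 100),
        pixel_size_xy=0.2,
        nucleus_axes=(7.0, 5.0),
        territory_radius=2.0,
        n_nuclei=8,
        seed=42,
    )


@pytest.fixture
def cfg3d():
    """Small confocal-style z-stack scene (0.2 μm axial step)."""
    return SceneConfig(
        image_shape=(32, 96, 96),
        pixel_size_xy=0.1,
        z_step=0.2,
        nucleus_axes=(3.5, 2.8, 1.6),
        territory_radius=1.0,
        n_nuclei=4,
        seed=7,
    )


def random_mask(rng: np.random.Generator, shape=(64, 64)) -> np.ndarray:
    """A random perturbed-ellipse binary mask, independent of the generator.

    Used as a stress input for the shell partition; only validity (single
    region of >= 5 px, away from the border) matters, not realism.
    """
    h, w = shape
    cy, cx = (h - 1) / 2, (w - 1) / 2
    a = rng.uniform(0.25, 0.42) * w
    b = rng.uniform(0.25, 0.42) * h
    amps = rng.uniform(0, 0.12, 3)
    phases = rng.uniform(0, 2 * np.pi, 3)
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.arctan2((yy - cy) / b, (xx - cx) / a)
    factor = 1 + sum(
        amp * np.cos(k * theta + ph) for amp, ph, k in zip(amps, phases, (2, 3, 4))
    )
    rho = np.sqrt(((yy - cy) / b) ** 2 + ((xx - cx) / a) ** 2)
    return rho <= factor
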