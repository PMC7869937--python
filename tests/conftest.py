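import numpy as np
import pytest

from rugosa.cloud import ColoredPointCloud


def random_cloud(n: int, seed: int, scale: float = 1.0) -> ColoredPointCloud:
    rng = np.random.default_rng(seed)
    xyz = rng.uniform(-scale, scale, size=(n, 3))
    rgb = rng.integers(0, 256, size=(n, 3)).astype(np.uint8)
    return ColoredPointCloud(xyz, rgb)


def surface_cloud(n: int, seed: int, amplitude: float = 0.05,
                  wavelength: float = 0.4, extent: float = 2.0
                  ) -> ColoredPointCloud:
    """Points on a gently undulating canopy-like surface."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, extent, n)
    y = rng.uniform(0, extent, n)
    z = 0.6 + amplitude * np.sin(2 * np.pi * x / wavelength) \
        * np.sin(2 * np.pi * y / wavelength)
    rgb = rng.integers(0, 256, size=(n, 3)).astype(np.uint8)
    return ColoredPointCloud(np.column_stack([x, y, z]), rgb)


def grid_cloud(n: int, spacing: float = 0.1, z: float = 0.0
               ) -> ColoredPointCloud:
    xx, yy = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    xyz = np.column_stack([xx.ravel(), yy.ravel(),
                           np.full(n * n, float(z))])
    rgb = np.full((n * n, 3), 128, dtype=np.uint8)
    return ColoredPointCloud(xyz, rgb)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
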