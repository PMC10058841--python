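import numpy as np
import pytest

from treeclass import ComponentLabel, SceneConfig, SpectralPointCloud, generate_scene
from treeclass.grid import DEFAULT_GRID


def make_cloud(rng, n, kind="reflectance", labeled=False):
    """Random valid cloud: positive spectra, scattered coordinates."""
    coords = rng.uniform(-1.0, 1.0, size=(n, 3))
    spectra = rng.uniform(0.01, 0.9, size=(n, DEFAULT_GRID.n_channels))
    labels = rng.integers(1, 5, size=n) if labeled else None
    return SpectralPointCloud(
        coords=coords, spectra=spectra, spectra_kind=kind, labels=labels
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """A modest labeled scene shared by read-only tests."""
    config = SceneConfig(
        counts={
            ComponentLabel.UNRIPE_FRUIT: 150,
            ComponentLabel.RIPE_FRUIT: 150,
            ComponentLabel.WOOD: 300,
            ComponentLabel.LEAF: 400,
        },
        seed=42,
    )
    return generate_scene(config)
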