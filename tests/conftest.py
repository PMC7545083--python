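import numpy as np
import pytest

from pareidolia.stimuli import build_stimulus_set


@pytest.fixture(scope="session")
def full_stimulus_set():
    """The complete default stimulus set (128+128 signal composites, 256
    noise-only images), built once per session."""
    return build_stimulus_set(seed=20)


@pytest.fixture(scope="session")
def small_stimulus_set():
    """A reduced set (2 images per design cell, 96-px grid) for cheap
    structural tests."""
    from pareidolia.stimuli import FilterSpec, GeometryConfig

    geom = GeometryConfig(image_px=96, image_deg=4.2, signal_height_px=36)
    return build_stimulus_set(
        geometry=geom, filter_spec=FilterSpec(), seed=5, images_per_cell=2
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
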