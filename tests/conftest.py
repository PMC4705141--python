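import warnings

import pytest

from islandcarbon import synthetic
from islandcarbon.pipeline import run_demo


@pytest.fixture(scope="session")
def demo():
    """One full pipeline run on the default synthetic island (seed 0)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return run_demo(seed=0)


@pytest.fixture(scope="session")
def scene():
    """A default noisy scene, shared read-only across tests."""
    return synthetic.generate_scene(extent=(360.0, 360.0), seed=1)


@pytest.fixture(scope="session")
def oracle_scene():
    """Noise-free scene: canopy is an exact function of the predictor stack."""
    return synthetic.generate_scene(extent=(360.0, 360.0), seed=3, noise_sd=0.0)
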