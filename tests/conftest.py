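import numpy as np
import pytest

from redgepheno.hypercube_io import Hypercube, PanelRegion
from redgepheno.synthetic_scene import RedEdgeModel, SceneConfig, default_wavelengths


@pytest.fixture
def wavelengths():
    return default_wavelengths()  # 650..820 nm, 2.5 nm spacing, 69 bands


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """Desk-scale scene: 64×64 frame, panel in the top-left corner."""
    return SceneConfig(frame_rows=64, frame_cols=64, panel_roi=(0, 0, 12, 12), seed=11)


@pytest.fixture
def noiseless_model():
    return RedEdgeModel(noise_sd=0.0)


@pytest.fixture
def random_cube(wavelengths, rng):
    data = rng.random((len(wavelengths), 16, 16))
    return Hypercube(data, wavelengths, "radiance", "test cube")


@pytest.fixture
def panel():
    return PanelRegion((0, 0, 4, 4), 0.75)
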