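import numpy as np
import pytest
from scipy import ndimage

from stagescan import OpticsModel, make_nervenet_specimen


@pytest.fixture
def noise_free_optics():
    """Small-FOV optics with noise, vignette disabled: deterministic renders."""
    return OpticsModel(fov_px=96, photon_scale=0.0, read_noise=0.0, vignette_strength=0.0)


@pytest.fixture
def flat_specimen():
    """Specimen whose filaments all lie on one flat mid-depth plane."""
    return make_nervenet_specimen(
        (120.0, 120.0, 30.0), 20, seed=3, surface_amplitude_um=0.0
    )


@pytest.fixture
def curved_specimen():
    return make_nervenet_specimen((200.0, 200.0, 40.0), 15, seed=7)


@pytest.fixture
def textured_scene():
    """A smooth random uint16 scene with enough texture for registration."""
    rng = np.random.default_rng(1)
    scene = ndimage.gaussian_filter(rng.normal(size=(400, 500)), 1.5)
    scene = (scene - scene.min()) / np.ptp(scene)
    return (scene * 60000).astype(np.uint16)
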