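import numpy as np
import pytest

import nucleoflux as nf


@pytest.fixture(scope="session")
def default_scene():
    return nf.SceneConfig()


@pytest.fixture(scope="session")
def noise_free_scene():
    return nf.SceneConfig(poisson_gain=0.0, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def rendered_default(default_scene):
    """One default noisy scene at full level, with its detections."""
    stack, truth = nf.render_scene(default_scene, level=1.0, seed=7)
    records = nf.detect_units(stack)
    return stack, truth, records


@pytest.fixture(scope="session")
def rendered_noise_free(noise_free_scene):
    stack, truth = nf.render_scene(noise_free_scene, level=1.0, seed=3)
    records = nf.detect_units(stack)
    return stack, truth, records


@pytest.fixture()
def single_spot_stack():
    """Noise-free isolated Gaussian spot (sigma_xy=1.3, sigma_z=0.8)."""
    from nucleoflux.scene import _add_gaussian_spot

    voxels = np.zeros((21, 64, 64))
    _add_gaussian_spot(voxels, 32.0, 32.0, 10.0, 100.0, 1.3, 0.8)
    return nf.ImageStack(voxels, z_aspect=3.0)


@pytest.fixture(scope="session")
def hela_table():
    """Default synchronized simulation, seed 1."""
    return nf.simulate_traces(nf.hela_config(), nf.NucleoplasmConfig(), seed=1)
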