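import numpy as np
import pytest

import flimqc as fq


@pytest.fixture(scope="session")
def mono4_cloud():
    """Phasor cloud of a bright mono-exponential 4 ns cube (~1e6 photons)."""
    params = fq.DecayParams(tau1=4.0, frac1=1.0, n_photons=250)
    cube = fq.simulate_cube(params, 64, 64, 2024)
    return fq.phasor_transform(cube)


@pytest.fixture(scope="session")
def striped_mosaic():
    """Two-region striped mosaic with a dim region and one blank tile."""
    spec = fq.striped_two_region_spec(tile_shape=(32, 32), grid_shape=(4, 4), seed=7)
    intensity, lifetime, label = fq.generate_mosaic(spec)
    return spec, intensity, lifetime, label


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
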