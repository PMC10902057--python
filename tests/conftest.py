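import numpy as np
import pytest

from lipidseg.lipids import load_library
from lipidseg.phantom import build_phantom
from lipidseg.simulate import NOISELESS, NoiseModel, simulate_cube


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def phantom():
    return build_phantom(48, 48)


@pytest.fixture(scope="session")
def noiseless_cube(phantom):
    """Noiseless, drift-free rendering of the default phantom."""
    return simulate_cube(phantom, noise=NOISELESS)


@pytest.fixture(scope="session")
def noisy_cube(phantom):
    """Default-noise rendering (drift, TIC variation, peak noise, baseline)."""
    return simulate_cube(phantom, noise=NoiseModel(seed=5))


@pytest.fixture(scope="session")
def block_features():
    """Three well-separated fingerprint blocks of 30 pixels each."""
    rng = np.random.default_rng(7)
    centers = np.zeros((3, 12))
    centers[0, :4] = 1.0
    centers[1, 4:8] = 1.0
    centers[2, 8:] = 1.0
    X = np.vstack([c + rng.normal(0, 0.05, size=(30, 12)) for c in centers])
    X = np.abs(X)
    truth = np.repeat([0, 1, 2], 30)
    return X, truth
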