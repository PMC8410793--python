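import numpy as np
import pytest

from wgwr.mra import WaveletSpec
from wgwr.spectra import SpectralLibrary, to_absorbance
from wgwr.synthgen import benchmark_configs, generate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_library(rng):
    """Reflectance library: 5 samples on a short 128-point grid."""
    wl = np.arange(400.0, 528.0)
    spectra = np.clip(rng.uniform(0.1, 0.9, size=(5, wl.size)), 1e-3, 1.0)
    return SpectralLibrary(wl, spectra, [f"s{i}" for i in range(5)],
                           mode="reflectance",
                           x=rng.uniform(0, 100, 5), y=rng.uniform(0, 100, 5))


@pytest.fixture(scope="session")
def small_absorbance(small_library):
    return to_absorbance(small_library)


@pytest.fixture(scope="session")
def wspec3():
    return WaveletSpec(levels=3)


@pytest.fixture(scope="session")
def drift_dataset():
    """One spatially non-stationary synthetic dataset (seeded)."""
    return generate(benchmark_configs()["drift"], seed=42)
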