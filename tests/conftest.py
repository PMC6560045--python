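import numpy as np
import pytest

from vlmalign import DetectionParams, SpectraSet, Spectrum, SyntheticConfig, generate


def make_spectrum(id, mzs, intensity=5000.0, label=None):
    mzs = np.asarray(mzs, dtype=float)
    if np.isscalar(intensity):
        inten = np.full(mzs.size, float(intensity))
    else:
        inten = np.asarray(intensity, dtype=float)
    return Spectrum(id=id, mz=mzs, intensity=inten)


def make_set(peak_lists, intensities=None):
    spectra = []
    for i, mzs in enumerate(peak_lists):
        inten = 5000.0 if intensities is None else intensities[i]
        spectra.append(make_spectrum(f"s{i}", mzs, inten))
    return SpectraSet(tuple(spectra))


def random_instance(rng, m=None, n_range=(10, 30), shared=8, jitter=3e-6, noise=5):
    """A small realistic instance: shared compound masses with relative jitter
    plus scattered extra peaks, mixed intensities."""
    if m is None:
        m = int(rng.integers(2, 6))
    masses = np.sort(rng.uniform(100, 900, size=shared))
    spectra = []
    for s in range(m):
        mz = masses * (1.0 + rng.uniform(-jitter, jitter, size=shared))
        extra = rng.uniform(100, 900, size=noise)
        mz = np.sort(np.concatenate([mz, extra]))
        inten = rng.uniform(500.0, 50000.0, size=mz.size)
        spectra.append(Spectrum(id=f"s{s}", mz=mz, intensity=inten))
    return SpectraSet(tuple(spectra))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic batch shared across read-only tests."""
    return generate(SyntheticConfig(seed=3))


@pytest.fixture(scope="session")
def default_params():
    return DetectionParams.from_ppm(40.0)
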