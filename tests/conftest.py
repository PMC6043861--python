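import numpy as np
import pytest

from nirtraj.dataset import SpectralAxis, SpectralDataset
from nirtraj.synthetic import Band, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset(rng):
    """Small random dataset: 12 samples x 10 variables, axis 1..10 nm."""
    X = rng.normal(size=(12, 10))
    y = rng.normal(size=12)
    return SpectralDataset(
        spectra=X, axis=SpectralAxis(np.arange(1.0, 11.0), "nm"), reference=y
    )


def banded_spec(
    n_samples=60,
    n_variables=100,
    informative=(30.0,),
    noise_sd=0.0,
    seed=0,
    n_distractors=2,
):
    """Mixture spectra on axis 0..99 where component 0 (the analyte) owns
    the bands at the given centres and distractor components sit elsewhere."""
    bands = [Band(center=c, width=3.0, component=0, amplitude=1.0) for c in informative]
    distractor_centers = np.linspace(0.62, 0.95, n_distractors) * (n_variables - 1)
    ranges = [(0.5, 2.0)]
    for k, c in enumerate(distractor_centers, start=1):
        bands.append(Band(center=float(c), width=4.0, component=k, amplitude=1.0))
        ranges.append((0.5, 2.0))
    return SyntheticSpec(
        n_samples=n_samples,
        n_variables=n_variables,
        axis_lo=0.0,
        axis_hi=float(n_variables - 1),
        axis_unit="nm",
        bands=tuple(bands),
        concentration_ranges=tuple(ranges),
        baseline_amplitude=0.0,
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture
def banded_dataset():
    ds, C = generate(banded_spec(noise_sd=0.01, seed=7))
    return ds
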