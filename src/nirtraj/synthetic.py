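"""Synthetic NIR-like spectra with known ground truth.

Spectra follow a linear-mixture (Beer-Lambert) model: each chemical
component contributes one or more smooth Gaussian absorption bands on the
spectral axis; per-sample concentrations are drawn uniformly from stated
ranges; a random low-order polynomial baseline and additive i.i.d. Gaussian
noise complete the spectrum:

    X = C @ S + baseline + noise

Component 0 is the regressand analyte; its concentration column is the
dataset's reference vector. Two presets emulate the shapes of the study
datasets: a pharmaceutical-tablet transmittance set (310 x 404, 7,000 to
10,500 cm^-1, broad bands near 10,000 / 8,830 / 8,200 / 7,840 cm^-1) and a
botanical-extract process set (216 x 2,800, 1,100 to 2,500 nm, with strong
interfering absorption above 1,900 nm that motivates cropping to
1,100-1,900 nm).

Everything is driven by one integer seed; a fixed seed gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectralAxis, SpectralDataset

__all__ = ["Band", "SyntheticSpec", "generate", "tablet_like", "lonicera_like"]


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: centre (axis units), width (Gaussian
    sigma, axis units), owning component index, peak height per unit
    concentration."""

    center: float
    width: float
    component: int
    amplitude: float = 1.0


@dataclass(frozen=True)
class SyntheticSpec:
    n_samples: int
    n_variables: int
    axis_lo: float
    axis_hi: float
    axis_unit: str
    bands: tuple[Band, ...]
    concentration_ranges: tuple[tuple[float, float], ...]
    baseline_degree: int = 2
    baseline_amplitude: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    reference_unit: str = ""

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        n_comp = len(self.concentration_ranges)
        for b in self.bands:
            if not 0 <= b.component < n_comp:
                raise ValueError(f"band component {b.component} out of range")
            if not min(self.axis_lo, self.axis_hi) <= b.center <= max(self.axis_lo, self.axis_hi):
                raise ValueError(f"band centre {b.center} outside the axis")

    @property
    def n_components(self) -> int:
        return len(self.concentration_ranges)


def _pure_spectra(spec: SyntheticSpec, axis: np.ndarray) -> np.ndarray:
    S = np.zeros((spec.n_components, spec.n_variables))
    for b in spec.bands:
        S[b.component] += b.amplitude * np.exp(-0.5 * ((axis - b.center) / b.width) ** 2)
    return S


def generate(spec: SyntheticSpec) -> tuple[SpectralDataset, np.ndarray]:
    """Generate a dataset and the full ground-truth concentration matrix.

    Returns ``(dataset, C)`` where ``C`` is (n_samples, n_components) and
    ``dataset.reference == C[:, 0]``.
    """
    rng = np.random.default_rng(spec.seed)
    axis_values = np.linspace(spec.axis_lo, spec.axis_hi, spec.n_variables)
    S = _pure_spectra(spec, axis_values)
    lows = np.array([lo for lo, _ in spec.concentration_ranges])
    highs = np.array([hi for _, hi in spec.concentration_ranges])
    C = rng.uniform(lows, highs, size=(spec.n_samples, spec.n_components))
    X = C @ S
    if spec.baseline_amplitude > 0:
        u = np.linspace(-1.0, 1.0, spec.n_variables)
        powers = np.vstack([u**d for d in range(spec.baseline_degree + 1)])
        coeffs = rng.uniform(
            -spec.baseline_amplitude,
            spec.baseline_amplitude,
            size=(spec.n_samples, spec.baseline_degree + 1),
        )
        X = X + coeffs @ powers
    if spec.noise_sd > 0:
        X = X + rng.normal(0.0, spec.noise_sd, size=X.shape)
    ds = SpectralDataset(
        spectra=X,
        axis=SpectralAxis(axis_values, spec.axis_unit),
        reference=C[:, 0].copy(),
        reference_unit=spec.reference_unit,
    )
    return ds, C


def tablet_like(
    n_samples: int = 310,
    n_variables: int = 404,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> SyntheticSpec:
    """Pharmaceutical-tablet emulation: 310 x 404 transmittance spectra on
    7,000-10,500 cm^-1 with four broad bands; the analyte (API, % w/w,
    ~5-12%) owns the 8,830 cm^-1 band."""
    return SyntheticSpec(
        n_samples=n_samples,
        n_variables=n_variables,
        axis_lo=7000.0,
        axis_hi=10500.0,
        axis_unit="cm-1",
        bands=(
            Band(center=8830.0, width=180.0, component=0, amplitude=0.06),
            Band(center=10000.0, width=300.0, component=1, amplitude=0.45),
            Band(center=8200.0, width=220.0, component=2, amplitude=0.50),
            Band(center=7840.0, width=160.0, component=3, amplitude=0.40),
        ),
        concentration_ranges=((5.0, 12.0), (0.2, 1.0), (0.2, 1.0), (0.2, 1.0)),
        baseline_degree=2,
        baseline_amplitude=0.03,
        noise_sd=noise_sd,
        seed=seed,
        reference_unit="% w/w",
    )


def lonicera_like(
    n_samples: int = 216,
    n_variables: int = 2800,
    noise_sd: float = 0.004,
    seed: int = 0,
) -> SyntheticSpec:
    """Botanical-extract process emulation: 216 x 2,800 spectra on
    1,100-2,500 nm; the analyte (chlorogenic acid, mg/mL) absorbs near
    1,690 nm, with strong interfering bands above 1,900 nm (the region a
    practitioner crops away)."""
    return SyntheticSpec(
        n_samples=n_samples,
        n_variables=n_variables,
        axis_lo=1100.0,
        axis_hi=2500.0,
        axis_unit="nm",
        bands=(
            Band(center=1690.0, width=60.0, component=0, amplitude=0.35),
            Band(center=1450.0, width=80.0, component=1, amplitude=0.40),
            Band(center=1780.0, width=55.0, component=2, amplitude=0.30),
            Band(center=1940.0, width=70.0, component=3, amplitude=1.80),
            Band(center=2250.0, width=120.0, component=3, amplitude=1.20),
        ),
        concentration_ranges=((0.2, 1.5), (0.2, 1.0), (0.2, 1.0), (0.5, 1.5)),
        baseline_degree=2,
        baseline_amplitude=0.02,
        noise_sd=noise_sd,
        seed=seed,
        reference_unit="mg/mL",
    )
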