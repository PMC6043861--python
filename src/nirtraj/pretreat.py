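"""Spectral pretreatments: raw passthrough, Savitzky-Golay smoothing and
SG first/second derivatives.

All derivative filters are Savitzky-Golay least-squares polynomial filters
(default 9-point window, quadratic), not finite differences: the whole
pretreatment family then shares one consistent, noise-robust construction.
Derivatives are in index-spacing units (no rescaling by axis step), which
leaves relative model comparisons unchanged.

Edge handling preserves the variable count so interval indices stay stable
across pretreatments: boundary points are filled from the least-squares
polynomial fitted over the window anchored at the edge, evaluated at the
off-centre positions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter

__all__ = ["PretreatmentSpec", "sg_kernel", "apply_pretreatment", "RAW", "SG9", "D1", "D2"]

_METHODS = {"raw": 0, "sg_smooth": 0, "derivative_1": 1, "derivative_2": 2}


@dataclass(frozen=True)
class PretreatmentSpec:
    """One pretreatment: method name plus SG window / polynomial order."""

    method: str = "raw"
    window: int = 9
    poly_order: int = 2

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown pretreatment method {self.method!r}")
        if self.method == "raw":
            return
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.poly_order >= self.window:
            raise ValueError("poly_order must be smaller than window")
        if self.poly_order < self.deriv:
            raise ValueError(
                f"poly_order {self.poly_order} cannot support derivative order {self.deriv}"
            )

    @property
    def deriv(self) -> int:
        return _METHODS[self.method]

    @property
    def label(self) -> str:
        if self.method == "raw":
            return "raw"
        base = {"sg_smooth": f"sg{self.window}", "derivative_1": "d1", "derivative_2": "d2"}
        lab = base[self.method]
        if self.method != "sg_smooth" and (self.window, self.poly_order) != (9, 2):
            lab += f"(w{self.window},o{self.poly_order})"
        elif self.method == "sg_smooth" and self.poly_order != 2:
            lab += f"(o{self.poly_order})"
        return lab

    @classmethod
    def from_label(cls, label: str) -> "PretreatmentSpec":
        table = {
            "raw": cls("raw"),
            "d1": cls("derivative_1"),
            "d2": cls("derivative_2"),
            "sg9": cls("sg_smooth", window=9),
        }
        if label not in table:
            raise ValueError(f"unknown pretreatment label {label!r}; use {sorted(table)}")
        return table[label]


RAW = PretreatmentSpec("raw")
SG9 = PretreatmentSpec("sg_smooth", window=9, poly_order=2)
D1 = PretreatmentSpec("derivative_1", window=9, poly_order=2)
D2 = PretreatmentSpec("derivative_2", window=9, poly_order=2)


def sg_kernel(window: int, poly_order: int, deriv: int = 0) -> np.ndarray:
    """Savitzky-Golay convolution coefficients (dot-product orientation).

    The coefficients are those of the least-squares polynomial filter: dot
    the kernel with a window of samples to get the fitted value (deriv=0)
    or fitted derivative (deriv>=1, index-spacing units) at the centre.
    Smoothing kernels sum to 1; derivative kernels sum to 0.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if not 0 <= deriv <= poly_order < window:
        raise ValueError(
            f"need 0 <= deriv <= poly_order < window, got deriv={deriv}, "
            f"poly_order={poly_order}, window={window}"
        )
    return savgol_coeffs(window, poly_order, deriv=deriv, use="dot")


def apply_pretreatment(ds, spec: PretreatmentSpec):
    """Filter every spectrum independently; axis and reference unchanged.

    Output has the same number of variables as the input (edge points come
    from the boundary polynomial fit). ``raw`` is the identity.
    """
    if spec.method == "raw":
        return replace(ds, spectra=ds.spectra.copy())
    if ds.n_variables < spec.window:
        raise ValueError(
            f"window {spec.window} exceeds variable count {ds.n_variables}"
        )
    filtered = savgol_filter(
        ds.spectra, spec.window, spec.poly_order, deriv=spec.deriv, axis=1, mode="interp"
    )
    return replace(ds, spectra=filtered)
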