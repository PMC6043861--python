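"""Calibration quality metrics (RMSEP, RPD, R^2) and RPD-band model
classification.

RPD here is sd(y_validation, ddof=1) / RMSEP — the plain (not
bias-corrected SEP) convention, so the identity rpd * rmsep == sd(y) holds
exactly. Band edges: poor < 2 <= fair < 3 <= good < 3.5 <= very_good; the
two upper bands are the ones used to classify trajectory paths, the lower
split at 2 is a conventional reporting extrapolation. A value of exactly
3.5 classifies as very_good.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvaluationMetrics",
    "RPDClass",
    "RPD_BANDS",
    "rmsep",
    "rpd",
    "classify_rpd",
    "evaluate",
]

RPD_BANDS = (
    ("poor", 0.0, 2.0),
    ("fair", 2.0, 3.0),
    ("good", 3.0, 3.5),
    ("very_good", 3.5, np.inf),
)


@dataclass(frozen=True)
class RPDClass:
    label: str
    lower: float
    upper: float

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class EvaluationMetrics:
    """Validation-set metrics of one calibration model."""

    rmsep: float
    rpd: float
    r2: float
    n: int


def _check_pair(y_true, y_pred):
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError(
            f"y_true and y_pred must be equal-length vectors, "
            f"got shapes {y_true.shape} and {y_pred.shape}"
        )
    if y_true.size < 1:
        raise ValueError("need at least one sample")
    return y_true, y_pred


def rmsep(y_true, y_pred) -> float:
    """Root-mean-square error of prediction: sqrt(mean((y - yhat)^2))."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    r = y_true - y_pred
    return float(np.sqrt(np.mean(r * r)))


def rpd(y_true, y_pred) -> float:
    """sd(y_true, ddof=1) / rmsep.  Perfect predictions give +inf (flagged
    by the caller as off-scale); constant references raise."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    if y_true.size < 2:
        raise ValueError("RPD needs at least 2 samples")
    sd = float(np.std(y_true, ddof=1))
    if sd == 0.0:
        raise ValueError("reference values constant; RPD undefined")
    err = rmsep(y_true, y_pred)
    if err == 0.0:
        return float("inf")
    return sd / err


def classify_rpd(value: float) -> RPDClass:
    """Map an RPD value to its quality band (monotone in the value)."""
    if not value >= 0:
        raise ValueError(f"RPD must be >= 0, got {value}")
    for label, lo, hi in RPD_BANDS:
        if lo <= value < hi or (hi == np.inf and value >= lo):
            return RPDClass(label, lo, hi)
    raise AssertionError("unreachable")  # bands partition [0, inf)


def evaluate(y_true, y_pred) -> EvaluationMetrics:
    """All validation metrics at once."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    r = y_true - y_pred
    ss_res = float(r @ r)
    centered = y_true - y_true.mean()
    ss_tot = float(centered @ centered)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return EvaluationMetrics(
        rmsep=rmsep(y_true, y_pred),
        rpd=rpd(y_true, y_pred),
        r2=r2,
        n=y_true.size,
    )
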