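"""NIPALS PLS1 regression with mean centering, prediction and k-fold
cross-validation — the computational kernel every other module calls.

Model/Results split: :class:`PLS1` holds the data and latent-factor count,
``PLS1.fit()`` returns a :class:`PLS1Results` carrying the weights ``W``,
loadings ``P``, y-loadings ``q``, the regression vector in original
(centered) variable space and prediction/diagnostic methods.

Only mean centering is applied (no unit-variance scaling), the standard
choice for absorbance spectra whose variables share a physical unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLS1", "PLS1Results", "CVResult", "cross_validate", "CVConfig"]

_TINY = 1e-12


class PLS1:
    """PLS1 (single response) regression model, fitted by NIPALS.

    Parameters
    ----------
    X : (n_samples, n_variables) array
        Predictor matrix (absorbance spectra).
    y : (n_samples,) array
        Single regressand (analyte content).
    n_components : int
        Requested latent-factor count; must not exceed
        ``min(n_samples - 1, n_variables)``. Deflation may stop early on
        degenerate data, in which case the results carry fewer components
        and ``stopped_early`` is set instead of raising, so parameter grids
        never crash mid-run.
    """

    def __init__(self, X, y, n_components: int):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = self.X.shape
        if self.y.shape != (n,):
            raise ValueError(f"y must have shape ({n},)")
        if n < 2:
            raise ValueError("need at least 2 samples")
        if not 1 <= n_components <= min(n - 1, p):
            raise ValueError(
                f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
            )
        if np.ptp(self.y) == 0.0:
            raise ValueError("y has zero variance; nothing to regress on")
        self.n_components = int(n_components)

    def fit(self) -> "PLS1Results":
        X = self.X
        y = self.y
        x_mean = X.mean(axis=0)
        y_mean = y.mean()
        Xw = X - x_mean
        yw = y - y_mean
        scale = max(float(np.linalg.norm(Xw.T @ yw)), 1.0)
        W, P, T, q = [], [], [], []
        stopped = False
        for _ in range(self.n_components):
            w = Xw.T @ yw
            nw = float(np.linalg.norm(w))
            if nw <= _TINY * scale:
                stopped = True
                break
            w = w / nw
            t = Xw @ w
            tt = float(t @ t)
            if tt <= _TINY:
                stopped = True
                break
            p_a = (Xw.T @ t) / tt
            q_a = float(yw @ t) / tt
            Xw = Xw - np.outer(t, p_a)
            yw = yw - q_a * t
            W.append(w)
            P.append(p_a)
            T.append(t)
            q.append(q_a)
        if not W:
            raise ValueError("no PLS component could be extracted (X'y is zero)")
        return PLS1Results(
            model=self,
            x_mean=x_mean,
            y_mean=float(y_mean),
            weights=np.column_stack(W),
            loadings=np.column_stack(P),
            scores=np.column_stack(T),
            y_loadings=np.asarray(q),
            stopped_early=stopped,
        )


@dataclass
class PLS1Results:
    """Fitted NIPALS PLS1 model: latent structure plus regression vector."""

    model: PLS1
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # W, (p, a)
    loadings: np.ndarray  # P, (p, a)
    scores: np.ndarray  # T, (n, a)
    y_loadings: np.ndarray  # q, (a,)
    stopped_early: bool = False
    _coef_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def coef(self, n_components: int | None = None) -> np.ndarray:
        """Regression vector b with yhat = (x - x_mean)·b + y_mean.

        b = W (P'W)^{-1} q, truncated to the first ``n_components`` latent
        factors (default: all fitted).
        """
        a = self.n_components if n_components is None else int(n_components)
        if not 1 <= a <= self.n_components:
            raise ValueError(f"n_components must be in [1, {self.n_components}]")
        if a not in self._coef_cache:
            W = self.weights[:, :a]
            P = self.loadings[:, :a]
            q = self.y_loadings[:a]
            self._coef_cache[a] = W @ np.linalg.solve(P.T @ W, q)
        return self._coef_cache[a]

    @property
    def params(self) -> np.ndarray:
        return self.coef()

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"X has {X.shape[1]} variables, model was fit on {self.x_mean.size}"
            )
        return (X - self.x_mean) @ self.coef(n_components) + self.y_mean

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)

    @property
    def rmsec(self) -> float:
        """Root-mean-square error of calibration (training set)."""
        r = self.model.y - self.fittedvalues
        return float(np.sqrt(np.mean(r * r)))

    def summary(self) -> str:
        lines = [
            "PLS1 (NIPALS) regression results",
            "=" * 40,
            f"n_samples        {self.model.X.shape[0]}",
            f"n_variables      {self.model.X.shape[1]}",
            f"latent factors   {self.n_components}"
            + ("  (stopped early)" if self.stopped_early else ""),
            f"y mean           {self.y_mean:.6g}",
            f"RMSEC            {self.rmsec:.6g}",
            f"|coef| max       {np.abs(self.coef()).max():.6g}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation scheme: fold count (``folds == n`` gives
    leave-one-out), whether assignment is shuffled, and the shuffle seed."""

    folds: int = 5
    shuffle: bool = True
    seed: int = 0


@dataclass
class CVResult:
    rmsecv_by_lv: np.ndarray  # index a-1 -> RMSECV at a latent factors
    best_lv: int

    @property
    def best_rmsecv(self) -> float:
        return float(self.rmsecv_by_lv[self.best_lv - 1])


def _fold_assignment(n: int, cv: CVConfig) -> list[np.ndarray]:
    folds = int(cv.folds)
    if not 2 <= folds <= n:
        raise ValueError(f"folds must be in [2, {n}], got {folds}")
    order = (
        np.random.default_rng(cv.seed).permutation(n) if cv.shuffle else np.arange(n)
    )
    return [np.sort(chunk) for chunk in np.array_split(order, folds)]


def cross_validate(X, y, max_lv: int, cv: CVConfig = CVConfig()) -> CVResult:
    """K-fold cross-validated RMSE for 1..max_lv latent factors.

    Each fold is predicted by a model fit on the remaining samples; one
    NIPALS fit per fold at the largest feasible factor count serves every
    truncation. If a fold supports fewer factors than requested (narrow
    matrix, small fold, early deflation stop), its predictions at higher
    counts reuse its deepest available model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    folds = _fold_assignment(n, cv)
    if min(len(f) for f in folds) < 1:
        raise ValueError("a fold has no samples")
    pred = np.empty((n, max_lv))
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        Xtr, ytr = X[mask], y[mask]
        a_cap = min(max_lv, Xtr.shape[0] - 1, p)
        try:
            res = PLS1(Xtr, ytr, a_cap).fit()
        except ValueError as exc:
            if "X'y is zero" not in str(exc):
                raise
            # no extractable component (e.g. a signal-free interval):
            # the best available predictor is the training mean
            pred[test_idx, :] = ytr.mean()
            continue
        for a in range(1, max_lv + 1):
            pred[test_idx, a - 1] = res.predict(X[test_idx], min(a, res.n_components))
    resid = pred - y[:, None]
    rmsecv = np.sqrt(np.mean(resid * resid, axis=0))
    return CVResult(rmsecv_by_lv=rmsecv, best_lv=int(np.argmin(rmsecv)) + 1)
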