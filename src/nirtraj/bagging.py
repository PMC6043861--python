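"""Bagging-PLS: a bootstrap-aggregated ensemble of NIPALS PLS1 models.

``B`` bootstrap resamples (with replacement, seeded) of the training set
each yield one PLS1 member; the ensemble prediction is the per-sample mean
(or, via config, median) of the member predictions. Resamples whose
response collapses to a constant are redrawn up to a retry cap so the
member count is always exactly ``B``.

Variable selection, when used, happens once on the full training set
before bagging; members share the selected variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pls import PLS1, PLS1Results

__all__ = ["BaggingConfig", "BaggingPLS", "BaggingPLSResults"]

_REDRAW_CAP = 100


@dataclass(frozen=True)
class BaggingConfig:
    """Ensemble size ``n_models`` (B), bootstrap resample size (default:
    the training-set size) and the resampling seed."""

    n_models: int = 50
    resample_size: int | None = None
    seed: int = 0
    aggregate: str = "mean"

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.resample_size is not None and self.resample_size < 2:
            raise ValueError("resample_size must be >= 2")
        if self.aggregate not in ("mean", "median"):
            raise ValueError("aggregate must be 'mean' or 'median'")


class BaggingPLS:
    """Bagged PLS1 model; ``fit()`` returns :class:`BaggingPLSResults`.

    ``member_indices`` may be passed to ``fit`` to pin the bootstrap draws
    (e.g. the identity permutation, which makes B=1 bagging coincide with a
    single plain PLS1 fit); otherwise draws are generated from the config
    seed and are bit-reproducible.
    """

    def __init__(self, X, y, n_components: int, config: BaggingConfig = BaggingConfig()):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.n_components = int(n_components)
        self.config = config
        # validate shapes/params once, against the full training set
        PLS1(self.X, self.y, self.n_components)

    def fit(self, member_indices=None) -> "BaggingPLSResults":
        n = self.X.shape[0]
        size = self.config.resample_size or n
        rng = np.random.default_rng(self.config.seed)
        members: list[PLS1Results] = []
        drawn: list[np.ndarray] = []
        for b in range(self.config.n_models):
            if member_indices is not None:
                idx = np.asarray(member_indices[b], dtype=int)
                yb = self.y[idx]
                if np.ptp(yb) == 0.0:
                    raise ValueError(f"pinned resample {b} has constant y")
            else:
                for attempt in range(_REDRAW_CAP + 1):
                    idx = rng.integers(0, n, size=size)
                    yb = self.y[idx]
                    if np.ptp(yb) > 0.0:
                        break
                else:
                    raise ValueError(
                        f"member {b}: {_REDRAW_CAP} redraws all produced a "
                        "constant-y resample; y is (near-)degenerate"
                    )
            Xb = self.X[idx]
            a = min(self.n_components, Xb.shape[0] - 1, Xb.shape[1])
            members.append(PLS1(Xb, yb, a).fit())
            drawn.append(idx)
        return BaggingPLSResults(model=self, members=members, member_indices=drawn)


@dataclass
class BaggingPLSResults:
    """Fitted ensemble: member models plus their bootstrap indices."""

    model: BaggingPLS
    members: list[PLS1Results]
    member_indices: list[np.ndarray]

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member_predictions(self, X) -> np.ndarray:
        """(B, n_samples) matrix of per-member predictions."""
        return np.vstack([m.predict(X) for m in self.members])

    def predict(self, X) -> np.ndarray:
        preds = self.member_predictions(X)
        if self.model.config.aggregate == "median":
            return np.median(preds, axis=0)
        return preds.mean(axis=0)

    def summary(self) -> str:
        coefs = np.column_stack([m.coef() for m in self.members])
        lines = [
            "Bagging-PLS ensemble results",
            "=" * 40,
            f"members (B)        {self.n_members}",
            f"resample size      {self.member_indices[0].size}",
            f"latent factors     {self.model.n_components} (requested)",
            f"aggregation        {self.model.config.aggregate}",
            f"coef spread (sd)   {coefs.std(axis=1).mean():.6g}",
        ]
        return "\n".join(lines)
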