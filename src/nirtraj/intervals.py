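"""Interval-based variable selection: iPLS, BiPLS and SiPLS.

The spectrum is partitioned into contiguous, (near-)equal-width intervals;
each selector then searches interval subsets for the lowest cross-validated
RMSE of a PLS1 model restricted to the chosen variables:

- iPLS   — best single interval;
- BiPLS  — backward elimination of intervals, returning the set along the
  elimination path with the global RMSECV minimum;
- SiPLS  — exhaustive search over all combinations of a fixed number of
  intervals (with a combination-count cap to stay desk-scale).

Scoring at "up to lv" latent factors means the minimum RMSECV over
1..cap factors, where cap is the requested lv further limited by subset
width and fold size; the factor count that achieved the minimum is
recorded as ``lv_used``. Selection only ever sees training data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .pls import CVConfig, cross_validate

__all__ = [
    "IntervalGrid",
    "IntervalSet",
    "make_grid",
    "ipls_select",
    "bipls_select",
    "sipls_select",
]


@dataclass(frozen=True)
class IntervalGrid:
    """Equal-width contiguous partition of the variable axis.

    The first ``n_variables mod n_intervals`` intervals receive one extra
    variable; boundaries are half-open ``[start, end)`` index ranges.
    """

    n_variables: int
    boundaries: tuple[tuple[int, int], ...]

    @property
    def n_intervals(self) -> int:
        return len(self.boundaries)

    def columns(self, selected) -> np.ndarray:
        """Sorted variable indices of the union of the selected intervals."""
        idx = [np.arange(*self.boundaries[i]) for i in sorted(selected)]
        return np.concatenate(idx)

    def mask(self, selected) -> np.ndarray:
        m = np.zeros(self.n_variables, dtype=bool)
        m[self.columns(selected)] = True
        return m


def make_grid(n_variables: int, n_intervals: int) -> IntervalGrid:
    if not 1 <= n_intervals <= n_variables:
        raise ValueError(
            f"n_intervals must be in [1, {n_variables}], got {n_intervals}"
        )
    base, extra = divmod(n_variables, n_intervals)
    bounds = []
    start = 0
    for i in range(n_intervals):
        width = base + (1 if i < extra else 0)
        bounds.append((start, start + width))
        start += width
    return IntervalGrid(n_variables=n_variables, boundaries=tuple(bounds))


@dataclass(frozen=True)
class IntervalSet:
    """Result of one selector run: chosen intervals and their CV score."""

    grid: IntervalGrid
    selected: tuple[int, ...]
    score: float
    selector: str
    lv_used: int

    def __post_init__(self):
        if not self.selected:
            raise ValueError("an IntervalSet must select at least one interval")

    @property
    def variable_mask(self) -> np.ndarray:
        return self.grid.mask(self.selected)

    @property
    def columns(self) -> np.ndarray:
        return self.grid.columns(self.selected)

    @property
    def n_variables_selected(self) -> int:
        return int(self.columns.size)


def _score_subset(X, y, cols, lv: int, cv: CVConfig) -> tuple[float, int]:
    """(best RMSECV over 1..cap factors, factor count achieving it)."""
    Xs = X[:, cols]
    cap = max(1, min(lv, Xs.shape[1], Xs.shape[0] - 1))
    res = cross_validate(Xs, y, max_lv=cap, cv=cv)
    return res.best_rmsecv, res.best_lv


def ipls_select(X, y, grid: IntervalGrid, lv: int, cv: CVConfig = CVConfig()) -> IntervalSet:
    """Best single interval by RMSECV (ties -> lowest interval index)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    best = None
    for i in range(grid.n_intervals):
        score, lv_used = _score_subset(X, y, grid.columns([i]), lv, cv)
        if best is None or score < best[0]:
            best = (score, i, lv_used)
    score, i, lv_used = best
    return IntervalSet(grid=grid, selected=(i,), score=score, selector="ipls", lv_used=lv_used)


def bipls_select(
    X,
    y,
    grid: IntervalGrid,
    lv: int,
    cv: CVConfig = CVConfig(),
    min_intervals: int = 1,
) -> IntervalSet:
    """Backward elimination of intervals.

    From the full set, repeatedly drop the interval whose omission yields
    the lowest RMSECV of the remainder, recording the score after every
    removal down to ``min_intervals``; return the set along the elimination
    path with the global minimum (ties -> the earlier, larger set).
    """
    if grid.n_intervals < 2:
        raise ValueError("BiPLS needs a grid of at least 2 intervals")
    if not 1 <= min_intervals <= grid.n_intervals:
        raise ValueError(f"min_intervals must be in [1, {grid.n_intervals}]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    current = list(range(grid.n_intervals))
    path = []
    score, lv_used = _score_subset(X, y, grid.columns(current), lv, cv)
    path.append((tuple(current), score, lv_used))
    while len(current) > min_intervals:
        best = None
        for i in current:
            remaining = [j for j in current if j != i]
            s, a = _score_subset(X, y, grid.columns(remaining), lv, cv)
            if best is None or s < best[0]:
                best = (s, i, a)
        s, drop, a = best
        current = [j for j in current if j != drop]
        path.append((tuple(current), s, a))
    sel, score, lv_used = min(path, key=lambda rec: rec[1])
    return IntervalSet(grid=grid, selected=sel, score=score, selector="bipls", lv_used=lv_used)


def sipls_select(
    X,
    y,
    grid: IntervalGrid,
    lv: int,
    cv: CVConfig = CVConfig(),
    combo_size: int = 2,
    max_combinations: int = 10_000,
) -> IntervalSet:
    """Exhaustive search over all ``combo_size``-interval combinations.

    Ties -> lexicographically smallest index tuple (enumeration order).
    """
    if not 1 <= combo_size <= grid.n_intervals:
        raise ValueError(f"combo_size must be in [1, {grid.n_intervals}]")
    from math import comb

    n_combos = comb(grid.n_intervals, combo_size)
    if n_combos > max_combinations:
        raise ValueError(
            f"{n_combos} interval combinations exceed the cap of "
            f"{max_combinations}; use fewer intervals or a smaller combo_size"
        )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    best = None
    for combo in itertools.combinations(range(grid.n_intervals), combo_size):
        score, lv_used = _score_subset(X, y, grid.columns(combo), lv, cv)
        if best is None or score < best[0]:
            best = (score, combo, lv_used)
    score, combo, lv_used = best
    return IntervalSet(grid=grid, selected=combo, score=score, selector="sipls", lv_used=lv_used)
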