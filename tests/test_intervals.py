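"""Interval grid construction and the iPLS / BiPLS / SiPLS selectors."""

import itertools

import numpy as np
import pytest

from nirtraj.intervals import (
    bipls_select,
    ipls_select,
    make_grid,
    sipls_select,
)
from nirtraj.intervals import _score_subset
from nirtraj.pls import CVConfig

CV = CVConfig(folds=5, shuffle=True, seed=3)


def compact_band_data(n_samples, n_variables, analyte_cols, distractor_cols, seed):
    """Zero-noise mixture where the analyte's band has *compact support*
    (strictly zero outside ``analyte_cols``), so only those columns covary
    with y; a distractor component occupies ``distractor_cols``."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(0.5, 2.0, n_samples)
    X = np.zeros((n_samples, n_variables))
    for cols in analyte_cols:
        profile = np.hanning(len(cols) + 2)[1:-1]
        X[:, cols] += np.outer(y, profile)
    for cols in distractor_cols:
        d = rng.uniform(0.5, 2.0, n_samples)
        profile = np.hanning(len(cols) + 2)[1:-1]
        X[:, cols] += np.outer(d, profile)
    return X, y


def interval_of_variable(grid, var):
    for i, (s, e) in enumerate(grid.boundaries):
        if s <= var < e:
            return i
    raise AssertionError


class TestGrid:
    def test_404_variables_20_intervals(self):
        grid = make_grid(404, 20)
        widths = [e - s for s, e in grid.boundaries]
        assert widths == [21] * 4 + [20] * 16
        assert grid.boundaries[0] == (0, 21)
        assert grid.boundaries[-1] == (384, 404)

    def test_single_interval(self):
        assert make_grid(10, 1).boundaries == ((0, 10),)

    def test_singleton_intervals(self):
        grid = make_grid(5, 5)
        assert grid.boundaries == ((0, 1), (1, 2), (2, 3), (3, 4), (4, 5))

    def test_partition_covers_everything(self):
        for p, k in [(100, 7), (33, 4), (17, 17)]:
            grid = make_grid(p, k)
            np.testing.assert_array_equal(grid.columns(range(k)), np.arange(p))

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            make_grid(5, 6)
        with pytest.raises(ValueError):
            make_grid(5, 0)


class TestIPLS:
    def test_recovers_informative_band_zero_noise(self):
        # only interval 3 (columns 30..39) covaries with y
        X, y = compact_band_data(
            40, 100,
            analyte_cols=[range(30, 40)],
            distractor_cols=[range(70, 80)],
            seed=2,
        )
        grid = make_grid(100, 10)
        got = ipls_select(X, y, grid, lv=2, cv=CV)
        assert got.selected == (3,)
        assert got.score < 1e-8

    def test_matches_exhaustive_per_interval_oracle(self, rng):
        X = rng.normal(size=(25, 16))
        y = rng.normal(size=25)
        grid = make_grid(16, 4)
        got = ipls_select(X, y, grid, lv=3, cv=CV)
        scores = [
            _score_subset(X, y, grid.columns([i]), 3, CV)[0] for i in range(4)
        ]
        assert got.selected == (int(np.argmin(scores)),)
        assert got.score == pytest.approx(min(scores), abs=1e-12)

    def test_single_interval_grid_degenerates_to_full_spectrum(self, rng):
        X = rng.normal(size=(20, 12))
        y = rng.normal(size=20)
        grid = make_grid(12, 1)
        got = ipls_select(X, y, grid, lv=2, cv=CV)
        assert got.selected == (0,)
        assert got.score == pytest.approx(
            _score_subset(X, y, np.arange(12), 2, CV)[0], abs=1e-12
        )


class TestBiPLS:
    def test_removes_noise_intervals_keeps_informative(self):
        """Two signal intervals each carrying half the information (y is the
        sum of two latent concentrations) plus two pure-noise intervals:
        elimination must drop both noise intervals and keep both bands."""
        rng = np.random.default_rng(5)
        y1 = rng.uniform(0.5, 2.0, 40)
        y2 = rng.uniform(0.5, 2.0, 40)
        X = np.zeros((40, 100))
        X[:, 4:20] = np.outer(y1, np.hanning(16))
        X[:, 55:70] = np.outer(y2, np.hanning(15))
        X[:, 28:45] = rng.normal(0, 0.3, (40, 17))
        X[:, 80:95] = rng.normal(0, 0.3, (40, 15))
        grid = make_grid(100, 4)  # intervals of 25 variables
        got = bipls_select(X, y1 + y2, grid, lv=3, cv=CV)
        assert set(got.selected) == {0, 2}

    def test_two_interval_grid_considers_all_three_sets(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        grid = make_grid(10, 2)
        got = bipls_select(X, y, grid, lv=2, cv=CV)
        candidates = {
            (0, 1): _score_subset(X, y, grid.columns([0, 1]), 2, CV)[0],
            (0,): _score_subset(X, y, grid.columns([0]), 2, CV)[0],
            (1,): _score_subset(X, y, grid.columns([1]), 2, CV)[0],
        }
        # the greedy path visits the full set and the better single interval
        full = candidates[(0, 1)]
        best_single_key = min(((0,), (1,)), key=lambda k: candidates[k])
        expected = min(
            [((0, 1), full), (best_single_key, candidates[best_single_key])],
            key=lambda kv: kv[1],
        )
        assert got.selected == expected[0]
        assert got.score == pytest.approx(expected[1], abs=1e-12)

    def test_matches_step_by_step_greedy_oracle(self, rng):
        X = rng.normal(size=(22, 15))
        y = rng.normal(size=22)
        grid = make_grid(15, 5)
        got = bipls_select(X, y, grid, lv=2, cv=CV)

        # independent longhand reimplementation of the elimination path
        current = list(range(5))
        path = [(tuple(current), _score_subset(X, y, grid.columns(current), 2, CV)[0])]
        while len(current) > 1:
            options = []
            for drop in current:
                rest = [j for j in current if j != drop]
                options.append((_score_subset(X, y, grid.columns(rest), 2, CV)[0], drop))
            score, drop = min(options)
            current = [j for j in current if j != drop]
            path.append((tuple(current), score))
        sel, score = min(path, key=lambda kv: kv[1])
        assert got.selected == sel
        assert got.score == pytest.approx(score, abs=1e-12)

    def test_min_intervals_equal_to_grid_returns_full_set(self, rng):
        X = rng.normal(size=(15, 12))
        y = rng.normal(size=15)
        grid = make_grid(12, 3)
        got = bipls_select(X, y, grid, lv=2, cv=CV, min_intervals=3)
        assert got.selected == (0, 1, 2)


class TestSiPLS:
    def test_recovers_two_informative_bands(self):
        # y = y1 + y2, carried by compact bands in intervals 1 and 4 of 6
        rng = np.random.default_rng(9)
        y1 = rng.uniform(0.5, 2.0, 36)
        y2 = rng.uniform(0.5, 2.0, 36)
        X = rng.normal(0, 0.05, (36, 90))
        X[:, 17:28] += np.outer(y1, np.hanning(11))
        X[:, 62:73] += np.outer(y2, np.hanning(11))
        grid = make_grid(90, 6)
        got = sipls_select(X, y1 + y2, grid, lv=3, cv=CV, combo_size=2)
        assert set(got.selected) == {1, 4}

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        X = rng.normal(size=(24, 15))
        y = rng.normal(size=24)
        grid = make_grid(15, 5)
        got = sipls_select(X, y, grid, lv=2, cv=CV, combo_size=2)
        scored = {
            combo: _score_subset(X, y, grid.columns(combo), 2, CV)[0]
            for combo in itertools.combinations(range(5), 2)
        }
        best = min(scored, key=lambda c: (scored[c], c))
        assert got.selected == best
        assert got.score == pytest.approx(scored[best], abs=1e-12)

    def test_combo_size_full_grid_is_full_spectrum(self, rng):
        X = rng.normal(size=(18, 12))
        y = rng.normal(size=18)
        grid = make_grid(12, 3)
        got = sipls_select(X, y, grid, lv=2, cv=CV, combo_size=3)
        assert got.selected == (0, 1, 2)
        assert got.score == pytest.approx(
            _score_subset(X, y, np.arange(12), 2, CV)[0], abs=1e-12
        )

    def test_combination_cap_enforced(self, rng):
        X = rng.normal(size=(30, 24))
        y = rng.normal(size=30)
        grid = make_grid(24, 24)
        with pytest.raises(ValueError, match="exceed the cap"):
            sipls_select(X, y, grid, lv=1, cv=CV, combo_size=3, max_combinations=100)

    def test_combo_one_equals_ipls(self, rng):
        X = rng.normal(size=(20, 12))
        y = rng.normal(size=20)
        grid = make_grid(12, 4)
        a = sipls_select(X, y, grid, lv=2, cv=CV, combo_size=1)
        b = ipls_select(X, y, grid, lv=2, cv=CV)
        assert a.selected == b.selected
        assert a.score == pytest.approx(b.score, abs=1e-12)


class TestIntervalSetInvariants:
    def test_mask_matches_selected_widths(self, rng):
        X = rng.normal(size=(20, 17))
        y = rng.normal(size=20)
        grid = make_grid(17, 5)
        got = sipls_select(X, y, grid, lv=2, cv=CV, combo_size=2)
        widths = [e - s for s, e in grid.boundaries]
        assert got.variable_mask.sum() == sum(widths[i] for i in got.selected)
        assert got.n_variables_selected == got.columns.size

    def test_scores_nonnegative_and_deterministic(self, rng):
        X = rng.normal(size=(20, 12))
        y = rng.normal(size=20)
        grid = make_grid(12, 4)
        for select in (
            lambda: ipls_select(X, y, grid, 2, CV),
            lambda: bipls_select(X, y, grid, 2, CV),
            lambda: sipls_select(X, y, grid, 2, CV, combo_size=2),
        ):
            a, b = select(), select()
            assert a.score >= 0
            assert a.selected == b.selected and a.score == b.score
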