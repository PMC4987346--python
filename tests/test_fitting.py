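"""MSD scoring, the exhaustive grid search, and top-fraction analysis."""

import math

import numpy as np
import pytest

import igtpu
from igtpu.fitting import (
    GridSpec,
    compute_msd,
    default_grid,
    grid_search,
    top_fraction_counts,
)


def msd_oracle(pred, obs):
    """Naive elementwise double loop, kept independent of the implementation."""
    total = 0.0
    n = 0
    for t in range(len(pred)):
        for j in range(4):
            total += (pred[t][j] - obs[t][j]) ** 2
            n += 1
    return total / n


class TestComputeMsd:
    def test_perfect_fit_is_zero(self):
        m = np.random.default_rng(0).random((10, 4))
        assert compute_msd(m, m) == 0.0

    def test_uniform_vs_onehot(self):
        """Chance rows against one-hot choices: (0.75^2 + 3*0.25^2)/4."""
        uniform = np.full((25, 4), 0.25)
        onehot = np.zeros((25, 4))
        onehot[:, 2] = 1.0
        assert compute_msd(uniform, onehot) == pytest.approx(0.1875)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            pred, obs = rng.random((10, 4)), rng.random((10, 4))
            assert compute_msd(pred, obs) == pytest.approx(msd_oracle(pred, obs), abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_msd(np.zeros((10, 4)), np.zeros((9, 4)))


class TestDefaultGrid:
    def test_lattice_shape(self):
        grid = default_grid()
        assert len(grid) == 1936
        assert len(grid.points()) == 1936
        assert grid.lams == tuple(np.round(np.arange(1.0, 2.55, 0.1), 10))
        assert grid.alphas == grid.As == tuple(np.round(np.arange(0, 1.05, 0.1), 10))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(alphas=(), lams=(1.0,), As=(0.1,))


class TestGridSearch:
    def test_full_grid_yields_1936_entries(self, canonical_grid_result):
        assert len(canonical_grid_result) == 1936

    def test_single_point_grid_is_argmin(self, schedule, simplified):
        records, _ = igtpu.simulate_game(simplified, schedule, n_trials=20, seed=4)
        bench = np.full((20, 4), 0.25)
        grid = GridSpec(alphas=(0.5,), lams=(1.2,), As=(0.3,))
        res = grid_search(bench, grid, engine="one_step_ahead", trials=records)
        best, msd = res.best()
        assert (best.alpha, best.lam, best.A) == (0.5, 1.2, 0.3)
        assert msd >= 0

    def test_ties_break_lexicographically(self, schedule):
        """All-zero updating rate makes every point predict chance, so MSDs
        tie and the smallest (alpha, lam, A) must win."""
        bench = np.full((15, 4), 0.25)
        grid = GridSpec(alphas=(0.7, 0.3), lams=(1.4, 1.1), As=(0.0,))
        res = grid_search(bench, grid, rule="DEL", schedule=schedule, n_reps=3, seed=0)
        assert res.table["msd"].nunique() == 1
        best, _ = res.best()
        assert (best.alpha, best.lam, best.A) == (0.3, 1.1, 0.0)

    def test_reproducible_given_seed(self, schedule, simplified):
        bench = np.full((20, 4), 0.25)
        grid = GridSpec(alphas=(0.0, 0.5), lams=(1.3,), As=(0.1, 0.6))
        kw = dict(rule="DEL", schedule=schedule, n_reps=5, seed=99)
        t1 = grid_search(bench, grid, **kw).table
        t2 = grid_search(bench, grid, **kw).table
        np.testing.assert_array_equal(t1["msd"], t2["msd"])

    def test_missing_inputs_rejected(self, schedule):
        bench = np.full((10, 4), 0.25)
        grid = GridSpec(alphas=(0.0,), lams=(1.3,), As=(0.1,))
        with pytest.raises(ValueError, match="schedule"):
            grid_search(bench, grid, engine="simulation", schedule=None)
        with pytest.raises(ValueError, match="trial data"):
            grid_search(bench, grid, engine="one_step_ahead", trials=None)
        with pytest.raises(ValueError, match="rows must sum"):
            grid_search(np.full((10, 4), 0.3), grid, schedule=schedule)


class TestTopFractionCounts:
    def test_ten_percent_of_canonical_grid_is_194(self, canonical_grid_result):
        counts = top_fraction_counts(canonical_grid_result, 0.10, "alpha")
        assert counts.sum() == 194 == math.ceil(0.10 * 1936)

    def test_full_fraction_recovers_marginals(self, canonical_grid_result):
        counts = top_fraction_counts(canonical_grid_result, 1.0, "alpha")
        assert (counts == 176).all()  # 16 lambdas x 11 As per alpha value
        assert top_fraction_counts(canonical_grid_result, 1.0, "lambda").sum() == 1936

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, canonical_grid_result, fraction):
        with pytest.raises(ValueError, match="fraction"):
            top_fraction_counts(canonical_grid_result, fraction, "alpha")

    def test_unknown_parameter_rejected(self, canonical_grid_result):
        with pytest.raises(ValueError, match="parameter"):
            top_fraction_counts(canonical_grid_result, 0.1, "theta")


class TestCompareRules:
    def test_one_entry_per_rule_and_reproducible(self, schedule):
        bench = np.full((15, 4), 0.25)
        grid = GridSpec(alphas=(0.0, 0.4), lams=(1.3,), As=(0.0, 0.2))
        kw = dict(schedule=schedule, n_reps=4, seed=5)
        r1 = igtpu.compare_rules(bench, grid, **kw)
        r2 = igtpu.compare_rules(bench, grid, **kw)
        assert set(r1) == {"DEL", "DRI"}
        for rule in r1:
            assert r1[rule][0] == r2[rule][0]
            assert r1[rule][1] == pytest.approx(r2[rule][1])


class TestRecoverParameters:
    def test_small_scale_experiment_structure(self, schedule):
        grid = GridSpec(alphas=(0.0, 0.5), lams=(1.3,), As=(0.1, 0.5))
        res = igtpu.recover_parameters(
            seed=3, schedule=schedule, n_subjects=6, n_trials=20, grid=grid, n_reps=5
        )
        assert len(res) == 4
        assert res.meta["experiment"] == "parameter_recovery"
        best, msd = res.best()
        assert 0 <= msd <= 2
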