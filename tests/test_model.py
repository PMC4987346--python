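"""Prospect utility, the two learning rules, and the softmax choice rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igtpu.model import (
    ParameterSet,
    choice_probabilities,
    simplified_model,
    del_update,
    dri_update,
    pu_utility,
)

finite = st.floats(min_value=-2000, max_value=2000, allow_nan=False)
alphas = st.floats(min_value=0.0, max_value=1.0)
lams = st.floats(min_value=1.0, max_value=2.5)


class TestPuUtility:
    @pytest.mark.parametrize(
        "x, alpha, lam, expected",
        [
            (-1250, 0.0, 1.3, -1.3),  # the step function's loss branch
            (100, 0.0, 2.5, 1.0),  # any gain maps to +1 at alpha=0
            (-100, 1.0, 1.5, -150.0),  # linear case
            (0, 0.5, 2.0, 0.0),  # |0|^alpha = 0 for alpha > 0
            (0, 0.0, 1.3, 1.0),  # 0^0 := 1 (net-zero cards count as gains)
            (50, 0.5, 1.0, 50**0.5),
        ],
    )
    def test_known_values(self, x, alpha, lam, expected):
        assert pu_utility(x, alpha, lam) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(x1=finite, x2=finite, alpha=alphas, lam=lams)
    def test_nondecreasing_in_net(self, x1, x2, alpha, lam):
        lo, hi = sorted([x1, x2])
        assert pu_utility(lo, alpha, lam) <= pu_utility(hi, alpha, lam) + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(x=finite.filter(lambda v: v != 0), lam=lams)
    def test_alpha_zero_is_step_function(self, x, lam):
        u = pu_utility(x, 0.0, lam)
        assert u == (1.0 if x > 0 else pytest.approx(-lam))

    def test_broadcasts_over_parameter_vectors(self):
        u = pu_utility(-100.0, np.array([0.0, 1.0]), np.array([1.3, 2.0]))
        np.testing.assert_allclose(u, [-1.3, -200.0])


class TestLearningRules:
    def test_del_single_step_from_zero(self):
        E = del_update(np.zeros(4), "B", u=1.0, A=0.1)
        np.testing.assert_allclose(E, [0.0, 0.1, 0.0, 0.0])

    def test_del_zero_rate_is_identity(self):
        E0 = np.array([0.3, -0.2, 0.9, 0.0])
        np.testing.assert_array_equal(del_update(E0, "C", u=5.0, A=0.0), E0)

    def test_del_full_rate_jumps_to_utility(self):
        E = del_update(np.array([0.4, 0.0, 0.0, 0.0]), "A", u=-1.3, A=1.0)
        assert E[0] == pytest.approx(-1.3)

    def test_del_repeated_updates_follow_geometric_series(self):
        E = np.zeros(4)
        for _ in range(50):
            E = del_update(E, "A", u=1.0, A=0.1)
        assert E[0] == pytest.approx(1 - 0.9**50)

    def test_dri_no_decay_at_unit_a(self):
        E = dri_update(np.array([0.5, 0.0, 0.0, 0.0]), "A", u=1.0, A=1.0)
        np.testing.assert_allclose(E, [1.5, 0.0, 0.0, 0.0])

    def test_dri_full_decay_keeps_only_current_utility(self):
        E = dri_update(np.array([3.0, -1.0, 2.0, 0.7]), "B", u=-1.3, A=0.0)
        np.testing.assert_allclose(E, [0.0, -1.3, 0.0, 0.0])

    def test_dri_decays_unchosen_decks(self):
        E = dri_update(np.ones(4), "A", u=0.0, A=0.5)
        np.testing.assert_allclose(E[1:], 0.5)

    @pytest.mark.parametrize("update", [del_update, dri_update])
    def test_unknown_deck_rejected(self, update):
        with pytest.raises(ValueError, match="deck"):
            update(np.zeros(4), "X", u=1.0, A=0.5)

    @settings(derandomize=True, max_examples=50)
    @given(st.data())
    def test_del_expectancies_stay_in_utility_hull(self, data):
        """From E=0, each delta-rule expectancy stays between the smallest
        and largest utility presented so far (and 0)."""
        n = data.draw(st.integers(min_value=1, max_value=30))
        us = data.draw(st.lists(st.floats(-3, 3), min_size=n, max_size=n))
        decks = data.draw(st.lists(st.sampled_from("ABCD"), min_size=n, max_size=n))
        A = data.draw(st.floats(0.0, 1.0))
        E = np.zeros(4)
        for u, d in zip(us, decks):
            E = del_update(E, d, u, A)
        lo, hi = min(0.0, min(us)), max(0.0, max(us))
        assert np.all(E >= lo - 1e-9) and np.all(E <= hi + 1e-9)


class TestChoiceProbabilities:
    def test_equal_expectancies_give_chance_level(self):
        np.testing.assert_allclose(choice_probabilities(np.zeros(4)), 0.25)
        np.testing.assert_allclose(choice_probabilities(np.full(4, 7.3)), 0.25)

    def test_vanishing_sensitivity_approaches_uniform(self):
        P = choice_probabilities(np.array([3.0, -1.0, 0.0, 2.0]), theta=1e-9)
        np.testing.assert_allclose(P, 0.25, atol=1e-8)

    def test_single_advantage_matches_closed_form(self):
        P = choice_probabilities(np.array([1.0, 0.0, 0.0, 0.0]), theta=1.0)
        e = np.e
        np.testing.assert_allclose(P, [e / (e + 3), 1 / (e + 3), 1 / (e + 3), 1 / (e + 3)])

    @settings(derandomize=True, max_examples=100)
    @given(
        E=st.lists(st.floats(-50, 50), min_size=4, max_size=4),
        shift=st.floats(-100, 100),
        theta=st.floats(0.01, 10),
    )
    def test_normalized_and_shift_invariant(self, E, shift, theta):
        E = np.array(E)
        P = choice_probabilities(E, theta)
        assert abs(P.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(P, choice_probabilities(E + shift, theta), atol=1e-9)

    def test_stable_for_extreme_expectancies(self):
        P = choice_probabilities(np.array([1e6, 0.0, -1e6, 0.0]))
        assert np.all(np.isfinite(P)) and P.sum() == pytest.approx(1.0)
        assert P[0] == pytest.approx(1.0)

    def test_nonfinite_expectancy_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            choice_probabilities(np.array([np.nan, 0, 0, 0]))


class TestParameterSet:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(alpha=-0.1, lam=1.3, A=0.1),
            dict(alpha=0.0, lam=0.9, A=0.1),
            dict(alpha=0.0, lam=1.3, A=1.1),
            dict(alpha=0.0, lam=1.3, A=0.1, rule="XYZ"),
            dict(alpha=0.0, lam=1.3, A=0.1, theta=0.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ParameterSet(**kwargs)

    def test_simplified_model_constants(self):
        p = simplified_model()
        assert (p.alpha, p.lam, p.A, p.rule, p.theta) == (0.0, 1.3, 0.1, "DEL", 1.0)
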