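"""Unit and property tests for the chain core: types, transition matrices,
stationary solves, and predictive-ability computations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smchain import (
    Cell,
    CellPattern,
    ConfusionMatrix,
    DecisionProfile,
    DegenerateChainError,
    build_ring_chain,
    effective_usage,
    forward_probability,
    linear_predictive_ability,
    nonlinear_predictive_ability,
    predictive_ability_from_confusion,
    sm_linear_benefit_condition,
    stationary_distribution,
)
from smchain.core import ring_chain_from_forward

from conftest import lazy_power_iteration

probs = st.floats(min_value=0.01, max_value=0.99)


class TestDomainTypes:
    def test_profile_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            DecisionProfile(p_r=1.2, p_e1=0.1)
        with pytest.raises(ValueError):
            DecisionProfile(p_r=0.8, p_e1=-0.1)

    def test_beta_requires_p_e2(self):
        with pytest.raises(ValueError):
            DecisionProfile(p_r=0.8, p_e1=0.1, beta=0.5)
        DecisionProfile(p_r=0.8, p_e1=0.1, p_e2=0.5, beta=0.5)  # fine

    def test_pattern_parsing_and_alpha(self):
        pat = CellPattern.from_string("lLd")
        assert pat.cells == (Cell.LIGHT, Cell.LIGHT, Cell.DARK)
        assert pat.alpha == pytest.approx(2 / 3)
        assert str(pat) == "LLD"
        with pytest.raises(ValueError):
            CellPattern.from_string("LXD")
        with pytest.raises(ValueError):
            CellPattern.from_string("")

    def test_confusion_rates_normalize(self):
        cm = ConfusionMatrix(a=3, b=1, c=2, d=4)
        assert cm.a_star + cm.b_star + cm.c_star + cm.d_star == pytest.approx(1.0)
        with pytest.raises(ValueError):
            ConfusionMatrix(a=0, b=0, c=0, d=0).a_star


class TestForwardProbability:
    @pytest.mark.parametrize(
        "cell, profile, use_sm, expected",
        [
            (Cell.LIGHT, DecisionProfile(0.8, 0.1), False, 0.8),
            (Cell.DARK, DecisionProfile(0.8, 0.1), False, 0.1),
            (Cell.DARK, DecisionProfile(0.8, 0.05, p_e2=0.475, beta=0.5), True, 0.2625),
            (Cell.LIGHT, DecisionProfile(0.8, 0.05, p_e2=0.475, beta=0.5), True, 0.6375),
        ],
    )
    def test_examples(self, cell, profile, use_sm, expected):
        assert forward_probability(cell, profile, use_sm) == pytest.approx(expected, abs=1e-12)

    def test_sm_without_p_e2_is_an_error(self):
        with pytest.raises(ValueError):
            forward_probability(Cell.DARK, DecisionProfile(0.8, 0.1), use_sm=True)


class TestRingChain:
    def test_lld_rows(self, lld, walker):
        chain = build_ring_chain(lld, walker)
        expected = np.array([[0.0, 0.8, 0.2], [0.2, 0.0, 0.8], [0.1, 0.9, 0.0]])
        np.testing.assert_allclose(chain.transition, expected, atol=1e-15)

    def test_homogeneous_rows(self):
        pat = CellPattern.from_string("LLL")
        chain = build_ring_chain(pat, DecisionProfile(0.7, 0.2))
        np.testing.assert_allclose(chain.forward_prob, 0.7)

    def test_short_pattern_rejected(self):
        with pytest.raises(ValueError, match="length >= 3"):
            build_ring_chain(CellPattern.from_string("LD"), DecisionProfile(0.8, 0.1))

    def test_subcell_mode_doubles_the_ring(self, lld):
        profile = DecisionProfile(0.8, 0.1, p_e2=0.45, beta=0.5)
        chain = build_ring_chain(lld, profile, use_sm=True, sm_mode="subcell")
        assert chain.size == 6
        np.testing.assert_allclose(chain.forward_prob, [0.8, 0.45, 0.8, 0.45, 0.1, 0.45])
        with pytest.raises(ValueError, match="beta"):
            build_ring_chain(lld, DecisionProfile(0.8, 0.1, p_e2=0.45, beta=0.3),
                             use_sm=True, sm_mode="subcell")

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(q=st.lists(probs, min_size=3, max_size=12))
    def test_rows_sum_to_one(self, q):
        chain = ring_chain_from_forward(np.array(q))
        np.testing.assert_allclose(chain.transition.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((chain.transition > 0).sum(axis=1) == 2)


class TestStationaryDistribution:
    def test_worked_example_exact(self, lld, walker):
        pi = stationary_distribution(build_ring_chain(lld, walker))
        np.testing.assert_allclose(pi.pi, [2 / 15, 7 / 15, 6 / 15], atol=1e-10)

    def test_homogeneous_is_uniform(self):
        chain = ring_chain_from_forward([0.5, 0.5, 0.5])
        np.testing.assert_allclose(stationary_distribution(chain).pi, 1 / 3, atol=1e-12)

    def test_matches_power_iteration_oracle(self):
        chain = ring_chain_from_forward([0.7, 0.3, 0.9])
        pi = stationary_distribution(chain)
        oracle = lazy_power_iteration(chain.transition)
        np.testing.assert_allclose(pi.pi, oracle, atol=1e-8)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(q=st.lists(probs, min_size=3, max_size=12))
    def test_oracle_equivalence_any_ring(self, q):
        """Linear solve agrees with lazy power iteration on rings of any size,
        including even rings where the raw walk is periodic."""
        chain = ring_chain_from_forward(np.array(q))
        pi = stationary_distribution(chain)
        assert abs(pi.pi.sum() - 1.0) < 1e-10
        np.testing.assert_allclose(pi.pi, lazy_power_iteration(chain.transition), atol=1e-8)
        residual = np.abs(pi.pi @ chain.transition - pi.pi).max()
        assert residual < 1e-10

    def test_degenerate_forward_probability_raises(self):
        with pytest.raises(DegenerateChainError):
            stationary_distribution(ring_chain_from_forward([1.0, 0.5, 0.5]))
        with pytest.raises(DegenerateChainError):
            stationary_distribution(ring_chain_from_forward([0.5, 0.0, 0.5]))


class TestPredictiveAbility:
    def test_effective_usage_worked_example(self, lld, walker):
        pi = stationary_distribution(build_ring_chain(lld, walker))
        usage = effective_usage(pi, lld)
        assert usage["R"] == pytest.approx(0.6, abs=1e-10)
        assert usage["E1"] == pytest.approx(0.4, abs=1e-10)

    def test_effective_usage_flat_occupancy_equals_alpha(self, lld):
        from smchain import StationaryOccupancy

        usage = effective_usage(StationaryOccupancy(np.full(3, 1 / 3)), lld)
        assert usage["R"] == pytest.approx(2 / 3)
        assert usage["E1"] == pytest.approx(1 / 3)

    def test_effective_usage_trapped_example(self, lld):
        # forward probs (0.8, 0.8, 0.05): deeper trapping in the dark cell
        chain = ring_chain_from_forward([0.8, 0.8, 0.05])
        pi = stationary_distribution(chain)
        oracle = lazy_power_iteration(chain.transition)
        usage = effective_usage(pi, lld)
        assert usage["R"] == pytest.approx(oracle[0] + oracle[1], abs=1e-8)
        assert usage["R"] == pytest.approx(0.5942, abs=5e-4)

    def test_usage_dimension_mismatch(self, walker):
        pat4 = CellPattern.from_string("LLDD")
        pi = stationary_distribution(build_ring_chain(pat4, walker))
        with pytest.raises(ValueError, match="states"):
            effective_usage(pi, CellPattern.from_string("LLD"))

    def test_nonlinear_px_worked_example(self, lld, walker):
        chain = build_ring_chain(lld, walker)
        pi = stationary_distribution(chain)
        assert nonlinear_predictive_ability(pi, chain) == pytest.approx(7.8 / 15, abs=1e-10)

    def test_nonlinear_px_derived_case(self, lld):
        chain = build_ring_chain(lld, DecisionProfile(0.8, 0.05))
        pi = stationary_distribution(chain)
        oracle = lazy_power_iteration(chain.transition) @ chain.forward_prob
        px = nonlinear_predictive_ability(pi, chain)
        assert px == pytest.approx(oracle, abs=1e-8)
        assert px == pytest.approx(0.495652, abs=1e-6)

    def test_linear_px_examples(self):
        assert linear_predictive_ability(2 / 3, DecisionProfile(0.8, 0.1)) == pytest.approx(17 / 30)
        prof = DecisionProfile(0.55, 0.05, p_e2=0.6, beta=0.5)
        assert linear_predictive_ability(2 / 3, prof, use_sm=True) == pytest.approx(
            0.491667, abs=1e-6
        )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(p=probs, alpha=st.floats(min_value=0, max_value=1))
    def test_linear_px_of_equal_abilities_is_that_ability(self, p, alpha):
        assert linear_predictive_ability(alpha, DecisionProfile(p, p)) == pytest.approx(p)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(p=probs, n=st.integers(min_value=3, max_value=9))
    def test_homogeneous_limit(self, p, n):
        """Equal abilities: uniform occupancy, usage equals cell fractions,
        and the non-linear ability collapses onto the linear one."""
        pat = CellPattern.from_string("LLD"[:1] * (n - 1) + "D")
        chain = build_ring_chain(pat, DecisionProfile(p, p))
        pi = stationary_distribution(chain)
        np.testing.assert_allclose(pi.pi, 1 / n, atol=1e-10)
        usage = effective_usage(pi, pat)
        assert usage["R"] == pytest.approx(pat.alpha, abs=1e-10)
        assert nonlinear_predictive_ability(pi, chain) == pytest.approx(p, abs=1e-10)
        assert linear_predictive_ability(pat.alpha, DecisionProfile(p, p)) == pytest.approx(p)

    def test_trapping_monotone_in_p_e1(self, lld):
        """Dark-cell occupancy shrinks as primary emotions get bolder, down to
        the flat 1/3 when they match deliberation."""
        occupancies = []
        for p_e1 in np.arange(0.05, 0.8001, 0.05):
            chain = build_ring_chain(lld, DecisionProfile(0.8, round(p_e1, 4)))
            occupancies.append(stationary_distribution(chain).pi[2])
        diffs = np.diff(occupancies)
        assert np.all(diffs <= 1e-12)
        assert occupancies[-1] == pytest.approx(1 / 3, abs=1e-10)

    @pytest.mark.parametrize(
        "p_e2, expected",
        [(0.6, True), (0.475, False), (17 / 30, False)],  # ties count as no benefit
    )
    def test_sm_linear_benefit_condition(self, p_e2, expected):
        prof = DecisionProfile(0.8, 0.1, p_e2=p_e2, beta=0.5)
        assert sm_linear_benefit_condition(prof, 2 / 3) is expected

    @pytest.mark.parametrize(
        "cm, expected",
        [
            (ConfusionMatrix(5, 0, 0, 5), 1.0),
            (ConfusionMatrix(3, 4, 3, 4), 0.5),  # correct == incorrect: baseline
            (ConfusionMatrix(3, 1, 2, 4), 0.7),
        ],
    )
    def test_predictive_ability_from_confusion(self, cm, expected):
        assert predictive_ability_from_confusion(cm) == pytest.approx(expected)
        assert cm.b_star + cm.c_star == pytest.approx(1 - expected)
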