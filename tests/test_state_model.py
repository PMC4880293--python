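"""Transition-matrix construction and hidden-state propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dyadhmm import (
    EfficiencyModel,
    division_matrix,
    hydroxylation_matrix,
    methylation_matrix,
    propagate,
    transition_matrix,
)
from dyadhmm.states import H_STATES, STATES, SWAP, swap_state

from conftest import STATE_INDEX, point_mass

probs = st.floats(0.0, 1.0)


def row_of(matrix, state):
    return {STATES[j]: matrix[STATE_INDEX[state], j]
            for j in range(9) if matrix[STATE_INDEX[state], j] > 0}


class TestDivisionMatrix:
    @pytest.mark.parametrize("state,expected", [
        ("mm", {"um": 0.5, "mu": 0.5}),
        ("hh", {"uh": 0.5, "hu": 0.5}),
        ("uu", {"uu": 1.0}),
        ("hm", {"hu": 0.5, "um": 0.5}),
        ("uh", {"uu": 0.5, "uh": 0.5}),
    ])
    def test_replaced_strand_resets_to_unmodified(self, state, expected):
        assert row_of(division_matrix(), state) == pytest.approx(expected)

    def test_rows_sum_to_one(self):
        assert division_matrix().sum(axis=1) == pytest.approx(np.ones(9), abs=1e-12)


class TestMethylationMatrix:
    def test_hemimethylated_site_gains_with_total_efficiency(self):
        # lam = 0.5 + 0.2 - 0.1 = 0.6
        M = methylation_matrix(0.5, 0.2, 0.0)
        assert row_of(M, "um") == pytest.approx({"mm": 0.6, "um": 0.4})

    def test_unmethylated_site_two_independent_de_novo_events(self):
        M = methylation_matrix(0.0, 0.5, 0.0)
        assert row_of(M, "uu") == pytest.approx(
            {"uu": 0.25, "um": 0.25, "mu": 0.25, "mm": 0.25})

    def test_full_blocking_leaves_only_de_novo_opposite_5hmC(self):
        M = methylation_matrix(0.9, 0.3, 1.0)
        assert row_of(M, "hu") == pytest.approx({"hm": 0.3, "hu": 0.7})

    @pytest.mark.parametrize("state", ["mm", "mh", "hm", "hh"])
    def test_dnmts_do_not_touch_modified_dyads(self, state):
        M = methylation_matrix(0.7, 0.3, 0.4)
        assert row_of(M, state) == {state: 1.0}

    def test_partial_blocking_mixture(self):
        # q = p*mu_d + (1-p)*lam
        mu_m, mu_d, p = 0.6, 0.2, 0.25
        lam = mu_m + mu_d - mu_m * mu_d
        q = p * mu_d + (1 - p) * lam
        M = methylation_matrix(mu_m, mu_d, p)
        assert row_of(M, "uh") == pytest.approx({"mh": q, "uh": 1 - q})

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_rejects_out_of_range_probabilities(self, bad):
        with pytest.raises(ValueError):
            methylation_matrix(bad, 0.5, 0.5)


class TestHydroxylationMatrix:
    def test_zero_rate_is_identity(self):
        assert hydroxylation_matrix(0.0) == pytest.approx(np.eye(9))

    def test_two_independent_oxidation_events(self):
        H = hydroxylation_matrix(0.5)
        assert row_of(H, "mm") == pytest.approx(
            {"mm": 0.25, "mh": 0.25, "hm": 0.25, "hh": 0.25})

    def test_single_methylated_strand(self):
        H = hydroxylation_matrix(0.1)
        assert row_of(H, "um") == pytest.approx({"uh": 0.1, "um": 0.9})

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            hydroxylation_matrix(1.5)


class TestTransitionMatrix:
    def test_perfect_maintenance_keeps_full_methylation(self):
        model = EfficiencyModel(mu_m_intercept=1.0)
        P = transition_matrix(1, model)
        assert row_of(P, "mm") == pytest.approx({"mm": 1.0})

    def test_pure_division_without_enzymes(self):
        P = transition_matrix(1, EfficiencyModel())
        assert row_of(P, "mm") == pytest.approx({"um": 0.5, "mu": 0.5})

    def test_certain_de_novo_fully_methylates(self):
        model = EfficiencyModel(mu_d_intercept=1.0)
        P = transition_matrix(1, model)
        assert row_of(P, "uu") == pytest.approx({"mm": 1.0})

    def test_rejects_efficiency_outside_unit_interval_at_t(self):
        model = EfficiencyModel(mu_m_intercept=0.5, mu_m_slope=0.2)
        with pytest.raises(ValueError):
            transition_matrix(4, model)  # mu_m(4) = 1.3


@settings(max_examples=50, deadline=None)
@given(mu_m=probs, mu_d=probs, eta=probs, p=probs)
def test_matrices_are_row_stochastic_and_swap_symmetric(mu_m, mu_d, eta, p):
    """All four matrices keep probability mass and respect strand exchange."""
    D = division_matrix()
    M = methylation_matrix(mu_m, mu_d, p)
    H = hydroxylation_matrix(eta)
    P = D @ M @ H
    for A in (D, M, H, P):
        assert np.all(A >= -1e-15) and np.all(A <= 1 + 1e-15)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(A, A[np.ix_(SWAP, SWAP)], atol=1e-14)


def test_swap_is_a_bijection():
    assert sorted(swap_state(s) for s in STATES) == sorted(STATES)
    assert all(swap_state(swap_state(s)) == s for s in STATES)


class TestPropagate:
    def test_zero_divisions_returns_initial(self):
        pi0 = np.full(9, 1 / 9)
        np.testing.assert_array_equal(propagate(pi0, EfficiencyModel(), 0), pi0)

    def test_5hmC_halves_per_division_without_hydroxylation(self):
        model = EfficiencyModel(p=1.0, mu_m_intercept=0.4)
        pi1 = propagate(point_mass("hh"), model, 1)
        expected = {"uh": 0.5, "hu": 0.5}
        got = {STATES[j]: pi1[j] for j in range(9) if pi1[j] > 0}
        assert got == pytest.approx(expected)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 8), probs, probs, probs, probs, st.integers(0, 6))
    def test_mass_is_conserved(self, start, mu_m, mu_d, eta, p, t):
        model = EfficiencyModel(mu_m_intercept=mu_m, mu_d_intercept=mu_d,
                                eta_intercept=eta, p=p)
        pi = propagate(point_mass(STATES[start]), model, t)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(pi >= -1e-15)

    def test_h_states_unreachable_without_hydroxylation(self):
        model = EfficiencyModel(mu_m_intercept=0.6, mu_d_intercept=0.3, p=0.5)
        pi = propagate(point_mass("mm"), model, 5)
        assert pi[list(H_STATES)] == pytest.approx(np.zeros(len(H_STATES)), abs=0)

    def test_passive_dilution_absorbs_into_unmodified(self):
        pi = propagate(point_mass("mm"), EfficiencyModel(), 40)
        assert pi[STATE_INDEX["uu"]] == pytest.approx(1.0, abs=1e-9)


def test_lambda_coefficients_match_direct_expansion():
    model = EfficiencyModel(mu_m_intercept=0.7, mu_m_slope=-0.03,
                            mu_d_intercept=0.2, mu_d_slope=0.01)
    b0, b1, b2 = model.lambda_coefficients()
    for t in (0, 1, 2, 5):
        assert b0 + b1 * t + b2 * t**2 == pytest.approx(model.lam(t), abs=1e-14)
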