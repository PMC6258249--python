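"""Randomized alternation, restart loop, augmentation and exact backtrack."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kekulize import (
    KekulizeConfig,
    alternate_once,
    backtrack_exact,
    extract_pi_system,
    generate_fullerene,
    kekulize,
    substitute_aza,
    validate_assignment,
)

from _helpers import (
    brute_force_feasible,
    chain_molecule,
    random_pi_molecule,
    ring_molecule,
)


class TestAlternateOnce:
    @pytest.mark.parametrize("seed", range(5))
    def test_benzene_any_order_fully_matches(self, benzene, seed):
        pis = extract_pi_system(benzene)
        order = list(np.random.default_rng(seed).permutation(pis.members))
        assignment, unmatched = alternate_once(pis, order)
        assert unmatched == []
        assert sorted(assignment.values()) == [0, 0, 0, 1, 1, 1]

    @pytest.mark.parametrize("seed", range(5))
    def test_five_ring_leaves_exactly_one(self, five_ring, seed):
        pis = extract_pi_system(five_ring)
        order = list(np.random.default_rng(seed).permutation(pis.members))
        _, unmatched = alternate_once(pis, order)
        assert len(unmatched) == 1

    def test_two_atom_path(self):
        g = chain_molecule([1, 1])
        pis = extract_pi_system(g)
        assignment, unmatched = alternate_once(pis, [0, 1])
        assert unmatched == []
        assert assignment == {0: 1}

    def test_triple_bond_preferred_for_sp_pair(self):
        # acetylene: both atoms have remaining demand 2, so the edge
        # receives pi-order 2 (a triple bond) in one step
        g = chain_molecule([2, 2])
        pis = extract_pi_system(g)
        assignment, unmatched = alternate_once(pis, [0, 1])
        assert unmatched == []
        assert assignment == {0: 2}

    def test_cumulene_chain_resolves(self):
        # d-values (1,2,2,1) admit only the cumulene (1,1,1) assignment
        g = chain_molecule([1, 2, 2, 1])
        pis = extract_pi_system(g)
        assignment, unmatched = alternate_once(pis, [0, 1, 2, 3])
        assert unmatched == []
        assert assignment == {0: 1, 1: 1, 2: 1}

    def test_deterministic_given_permutation(self, benzene):
        pis = extract_pi_system(benzene)
        order = [3, 0, 5, 1, 4, 2]
        first = alternate_once(pis, order, edge_priority=[5, 4, 3, 2, 1, 0])
        second = alternate_once(pis, order, edge_priority=[5, 4, 3, 2, 1, 0])
        assert first == second

    def test_rejects_non_permutation(self, benzene):
        pis = extract_pi_system(benzene)
        with pytest.raises(ValueError):
            alternate_once(pis, [0, 1, 2])


class TestKekulize:
    def test_c20_succeeds(self):
        result = kekulize(generate_fullerene("C20"), KekulizeConfig(seed=1))
        assert result.success

    def test_c60_succeeds_with_30_matched_edges(self):
        g = generate_fullerene("C60")
        result = kekulize(g, KekulizeConfig(seed=1))
        assert result.success
        assert validate_assignment(g, result.assignment)
        # 60 atoms of deficiency 1 force exactly 30 pi-order-1 edges
        assert sorted(result.assignment.values()).count(1) == 30
        assert 2 not in result.assignment.values()

    def test_odd_aza_fails_by_parity(self):
        g = generate_fullerene("C20")
        with pytest.warns(UserWarning):
            g3 = substitute_aza(g, 3, seed=11)
        result = kekulize(g3, KekulizeConfig(seed=2))
        assert result.success is False
        assert result.used_backtrack is False
        assert result.iterations == 0
        assert result.unmatched_first_pass % 2 == 1

    def test_determinism(self):
        g = substitute_aza(generate_fullerene("C60"), 8, seed=3)
        config = KekulizeConfig(seed=42)
        r1 = kekulize(g, config)
        r2 = kekulize(g, config)
        assert r1 == r2

    def test_augment_matches_plain_verdict(self):
        g = generate_fullerene("C60")
        plain = kekulize(g, KekulizeConfig(seed=9))
        repaired = kekulize(g, KekulizeConfig(seed=9, augment=True))
        assert plain.success and repaired.success
        assert validate_assignment(g, repaired.assignment)

    def test_restart_monotonicity(self):
        """Success rate is non-decreasing in the shuffle budget.

        Tetraaza-C60-like instances under a fresh placement per trial:
        a single pass succeeds sometimes; 300 shuffles succeed at least
        as often.
        """
        base = generate_fullerene("C60")
        wins = {1: 0, 300: 0}
        n_trials = 1000
        for t in range(n_trials):
            g = substitute_aza(base, 4, seed=t)
            for budget in wins:
                cfg = KekulizeConfig(
                    max_iterations=budget, seed=t, exact_fallback=False
                )
                if kekulize(g, cfg).success:
                    wins[budget] += 1
        assert wins[300] >= wins[1]
        assert wins[300] > 0


class TestBacktrackExact:
    def test_five_ring_infeasible(self, five_ring):
        exists, assignment = backtrack_exact(extract_pi_system(five_ring))
        assert exists is False and assignment is None

    def test_benzene_feasible_with_witness(self, benzene):
        exists, assignment = backtrack_exact(extract_pi_system(benzene))
        assert exists is True
        assert validate_assignment(benzene, assignment)

    @pytest.mark.parametrize("seed", range(30))
    def test_random_cubic_graphs_match_enumeration(self, seed):
        """Verdict equals exhaustive enumeration on random 12-atom graphs."""
        rng = np.random.default_rng(seed)
        g = random_pi_molecule(rng, max_atoms=12, max_edges=12)
        pis = extract_pi_system(g)
        exists, assignment = backtrack_exact(pis)
        assert exists == brute_force_feasible(pis)
        if exists:
            assert validate_assignment(g, assignment)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_property_kekulize_sound_and_complete(seed):
    """kekulize-with-fallback is sound (validated witness) and agrees
    with exhaustive enumeration on feasibility."""
    rng = np.random.default_rng(seed)
    g = random_pi_molecule(rng, max_atoms=10, max_edges=10)
    pis = extract_pi_system(g)
    result = kekulize(g, KekulizeConfig(max_iterations=20, seed=seed))
    assert result.success == brute_force_feasible(pis)
    if result.success:
        assert validate_assignment(g, result.assignment)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_property_first_pass_parity(seed):
    """For all-deficiency-1 systems the first-pass unmatched count has
    the parity of the total deficiency."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 12))
    g = ring_molecule(n)
    result = kekulize(g, KekulizeConfig(max_iterations=5, seed=seed,
                                        exact_fallback=False))
    assert result.unmatched_first_pass % 2 == n % 2
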