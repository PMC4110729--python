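import numpy as np
import pytest

from switchscape import (
    attractor_mfpt_matrix,
    find_attractors,
    first_passage_probability,
    mfpt_monte_carlo,
    mfpt_series_oracle,
    mfpt_states,
    transition_matrix,
)
from switchscape.errors import CapacityError, DomainError

from conftest import random_network


def brute_force_matrix(net, p_e):
    """Independent oracle: enumerate every flip pattern explicitly.

    With probability (1-p_e)^n no gene flips and the deterministic update
    runs; a nonzero flip pattern (each gene flipping independently with
    probability p_e) moves the state to the flipped state directly.
    """
    n = net.n
    size = 1 << n
    P = np.zeros((size, size))
    for x in range(size):
        for pattern in range(size):
            prob = 1.0
            for b in range(n):
                prob *= p_e if (pattern >> b) & 1 else (1 - p_e)
            y = net.step_int(x) if pattern == 0 else x ^ pattern
            P[x, y] += prob
    return P


class TestTransitionMatrix:
    def test_identity_net_rows(self, identity_net):
        tm = transition_matrix(identity_net, 0.1)
        assert np.allclose(tm.p, [[0.9, 0.1], [0.1, 0.9]], atol=1e-15)

    @pytest.mark.parametrize("p_e", [0.3, 0.05, 0.01])
    def test_toggle_matches_brute_force_enumeration(self, toggle, p_e):
        tm = transition_matrix(toggle, p_e)
        assert np.allclose(tm.p, brute_force_matrix(toggle, p_e), atol=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_nets_match_brute_force(self, seed):
        net = random_network(np.random.default_rng(seed), n=4)
        tm = transition_matrix(net, 0.07)
        assert np.allclose(tm.p, brute_force_matrix(net, 0.07), atol=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_sum_to_one(self, seed):
        net = random_network(np.random.default_rng(50 + seed), n=6)
        tm = transition_matrix(net, 0.02)
        assert np.all(np.abs(tm.p.sum(axis=1) - 1.0) < 1e-12)
        assert np.all(tm.p >= 0)

    @pytest.mark.parametrize("p_e", [0.0, 1.0, -0.2, 1.4])
    def test_noise_domain_checked(self, toggle, p_e):
        with pytest.raises(DomainError):
            transition_matrix(toggle, p_e)

    def test_dense_cap(self, toggle):
        with pytest.raises(CapacityError):
            transition_matrix(toggle, 0.1, max_n=1)


class TestFirstPassage:
    def test_base_case_is_transition_probability(self, identity_net):
        tm = transition_matrix(identity_net, 0.1)
        assert first_passage_probability(tm, 0, 1, 1) == tm.p[0, 1] == 0.1

    def test_second_step(self, identity_net):
        tm = transition_matrix(identity_net, 0.1)
        assert first_passage_probability(tm, 0, 1, 2) == pytest.approx(0.09, rel=1e-12)

    def test_distribution_normalizes(self, toggle):
        tm = transition_matrix(toggle, 0.2)
        mass, prev = 0.0, 0.0
        for k in range(1, 200):
            f = first_passage_probability(tm, 1, 2, k)
            assert f >= 0
            mass += f
            assert mass >= prev and mass <= 1 + 1e-12
            prev = mass
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_invalid_arguments(self, toggle):
        tm = transition_matrix(toggle, 0.1)
        with pytest.raises(DomainError):
            first_passage_probability(tm, 0, 1, 0)
        with pytest.raises(DomainError):
            first_passage_probability(tm, 1, 1, 2)


class TestMfpt:
    def test_identity_closed_form(self, identity_net):
        for p_e in (0.1, 0.01, 0.003):
            tm = transition_matrix(identity_net, p_e)
            assert mfpt_states(tm, [0], [1]) == pytest.approx(1 / p_e, rel=1e-12)

    def test_disjointness_required(self, toggle):
        tm = transition_matrix(toggle, 0.1)
        with pytest.raises(DomainError):
            mfpt_states(tm, [0, 1], [1])

    def test_series_oracle_identity(self, identity_net):
        tm = transition_matrix(identity_net, 0.1)
        assert mfpt_series_oracle(tm, 0, [1], K=500) == pytest.approx(10.0, abs=1e-6)

    def test_series_matches_linear_solve_on_toggle(self, toggle):
        tm = transition_matrix(toggle, 0.1)
        exact = mfpt_states(tm, [2], [1])
        series = mfpt_series_oracle(tm, 2, [1], K=100_000, tol=1e-12)
        assert series == pytest.approx(exact, abs=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_correctness_triangle_small_nets(self, seed):
        """Linear solve, truncated series and simulation agree."""
        rng = np.random.default_rng(1000 + seed)
        net = random_network(rng, n=int(rng.integers(4, 7)))
        atts = find_attractors(net)
        source = atts.attractors[0].states[0]
        target = (1 << net.n) - 1 - source  # complement state, never the source
        tm = transition_matrix(net, 0.1)
        exact = mfpt_states(tm, [source], [target])
        series = mfpt_series_oracle(tm, source, [target], K=100_000, tol=1e-12)
        assert series == pytest.approx(exact, abs=1e-6)
        mc, se = mfpt_monte_carlo(net, 0.1, source, [target], 3000, rng)
        assert abs(mc - exact) < 3 * se

    def test_monte_carlo_reproducible(self, toggle):
        a = mfpt_monte_carlo(toggle, 0.1, 0, [2], 500, np.random.default_rng(7))
        b = mfpt_monte_carlo(toggle, 0.1, 0, [2], 500, np.random.default_rng(7))
        assert a == b


class TestAttractorMatrix:
    def test_toggle_contract(self, toggle):
        atts = find_attractors(toggle)
        m = attractor_mfpt_matrix(toggle, 0.05, atts)
        assert m.values.shape == (3, 3)
        assert np.all(np.diag(m.values) == 0)
        off = m.values[~np.eye(3, dtype=bool)]
        assert np.all(off > 0) and np.all(np.isfinite(off))

    def test_generally_asymmetric(self):
        for seed in range(10):
            net = random_network(np.random.default_rng(2000 + seed), n=5)
            atts = find_attractors(net)
            if len(atts) < 2:
                continue
            m = attractor_mfpt_matrix(net, 0.05, atts).values
            if not np.allclose(m, m.T):
                return  # found the expected asymmetry
        pytest.fail("all sampled MFPT matrices were symmetric")

    @pytest.mark.parametrize("seed", [4, 6, 7])  # seeds drawing >= 2 attractors
    def test_lower_noise_never_shortens_passages(self, seed):
        net = random_network(np.random.default_rng(3000 + seed), n=5)
        atts = find_attractors(net)
        assert len(atts) >= 2
        hi = attractor_mfpt_matrix(net, 0.05, atts).values
        lo = attractor_mfpt_matrix(net, 0.01, atts).values
        mask = ~np.eye(len(atts), dtype=bool)
        assert np.all(lo[mask] >= hi[mask])

    def test_needs_two_attractors(self):
        from switchscape import BooleanNetwork

        net = BooleanNetwork(("a", "b"), ((1,), (0,)), ((0, 0), (0, 0)))
        atts = find_attractors(net)  # constant map: single attractor {00}
        with pytest.raises(DomainError):
            attractor_mfpt_matrix(net, 0.05, atts)
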