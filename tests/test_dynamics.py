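"""Hebbian couplings, asynchronous dynamics, overlaps and error rates."""

import math

import numpy as np
import pytest

from sfhopfield import (NetworkSpec, WeightedGraph, energy, error_rate,
                        hebbian_couplings, run_retrieval, sample_graph,
                        sample_patterns, update_finite_T, update_zero_T,
                        weighted_overlap)


def brute_force_couplings(edges, patterns, K):
    """Independent oracle: direct double loop over Hebb's rule."""
    out = {}
    for i, j in edges:
        out[(i, j)] = sum(int(patterns[mu, i]) * int(patterns[mu, j])
                          for mu in range(patterns.shape[0])) / K
    return out


class TestCouplings:
    def test_single_pattern_signs(self, nine_node_graph):
        pats = sample_patterns(9, 1, seed=0)
        J = hebbian_couplings(nine_node_graph, pats)
        K = nine_node_graph.spec.K
        for (i, j), val in zip(J.edges, J.J):
            assert val == pytest.approx(pats[0, i] * pats[0, j] / K)

    def test_two_identical_patterns_add(self, nine_node_graph):
        pat = sample_patterns(9, 1, seed=1)
        pats = np.vstack([pat, pat])
        J = hebbian_couplings(nine_node_graph, pats)
        K = nine_node_graph.spec.K
        assert np.allclose(np.abs(J.J), 2.0 / K)

    def test_against_brute_force(self, nine_node_graph):
        pats = sample_patterns(9, 2, seed=5)
        J = hebbian_couplings(nine_node_graph, pats)
        oracle = brute_force_couplings(nine_node_graph.edges, pats, nine_node_graph.spec.K)
        for (i, j), val in zip(J.edges, J.J):
            assert val == pytest.approx(oracle[(i, j)], rel=1e-14)
        # symmetry through the CSR representation
        for i, j in nine_node_graph.edges:
            sl = slice(J.indptr[i], J.indptr[i + 1])
            val_ij = J.data[sl][list(J.indices[sl]).index(j)]
            sl = slice(J.indptr[j], J.indptr[j + 1])
            val_ji = J.data[sl][list(J.indices[sl]).index(i)]
            assert val_ij == val_ji

    def test_quantization(self, er_graph_300):
        p = 4
        pats = sample_patterns(300, p, seed=2)
        J = hebbian_couplings(er_graph_300, pats)
        K = er_graph_300.spec.K
        levels = np.arange(-p, p + 1, 2) / K
        assert np.all(np.isclose(J.J[:, None], levels[None, :]).any(axis=1))

    def test_shape_error(self, nine_node_graph):
        with pytest.raises(ValueError):
            hebbian_couplings(nine_node_graph, sample_patterns(8, 1, seed=0))


class TestEnergy:
    def test_pattern_energy_minus_L_over_K(self, er_graph_300):
        pats = sample_patterns(300, 1, seed=3)
        J = hebbian_couplings(er_graph_300, pats)
        L = er_graph_300.n_edges
        assert energy(pats[0], J) == pytest.approx(-L / er_graph_300.spec.K)

    def test_global_flip_invariance(self, er_graph_300, rng):
        pats = sample_patterns(300, 3, seed=4)
        J = hebbian_couplings(er_graph_300, pats)
        S = (2 * rng.integers(0, 2, 300) - 1).astype(np.int8)
        assert energy(S, J) == pytest.approx(energy(-S, J))

    def test_empty_graph(self):
        spec = NetworkSpec("er", 5, K=1.0)
        g = WeightedGraph(spec=spec, w=np.full(5, 0.2),
                          edges=np.zeros((0, 2), dtype=int), degrees=np.zeros(5, int))
        J = hebbian_couplings(g, sample_patterns(5, 1, seed=0))
        assert energy(np.ones(5, dtype=np.int8), J) == 0.0


class TestZeroTUpdate:
    def test_stored_pattern_is_fixed_point(self, er_graph_300):
        pats = sample_patterns(300, 1, seed=6)
        J = hebbian_couplings(er_graph_300, pats)
        S = update_zero_T(pats[0].copy(), J, np.arange(300))
        live = er_graph_300.degrees > 0
        assert np.array_equal(S[live], pats[0][live])

    def test_isolated_node_goes_up(self):
        spec = NetworkSpec("er", 3, K=2 / 3)
        g = WeightedGraph(spec=spec, w=np.full(3, 1 / 3),
                          edges=np.array([[0, 1]]), degrees=np.array([1, 1, 0]))
        pats = np.array([[1, 1, -1]], dtype=np.int8)
        J = hebbian_couplings(g, pats)
        S = update_zero_T(np.array([1, 1, -1], dtype=np.int8), J, np.arange(3))
        assert S[2] == 1      # zero local field forces +1

    def test_energy_never_increases(self, rng):
        for trial in range(100):
            N = int(rng.integers(6, 25))
            g = sample_graph(NetworkSpec("er", N, K=min(4.0, N - 2)), seed=trial)
            pats = sample_patterns(N, int(rng.integers(1, 4)), seed=trial + 500)
            J = hebbian_couplings(g, pats)
            S = (2 * rng.integers(0, 2, N) - 1).astype(np.int8)
            e = energy(S, J)
            for _ in range(4):
                S = update_zero_T(S, J, rng.permutation(N))
                e2 = energy(S, J)
                assert e2 <= e + 1e-12
                e = e2

    def test_nine_node_converges_to_stored_or_mixture(self, nine_node_graph, rng):
        pats = sample_patterns(9, 2, seed=7)
        for seed in range(10):
            res = run_retrieval(nine_node_graph, pats, target=0, T=0.0,
                                init_overlap=0.0, max_sweeps=9 * 10, seed=seed)
            assert res.converged
            # fixed point: one more sweep changes nothing
            J = hebbian_couplings(nine_node_graph, pats)
            again = update_zero_T(res.final_state, J, np.arange(9))
            assert np.array_equal(again, res.final_state)


class TestFiniteTUpdate:
    def test_infinite_temperature_coin_flips(self, er_graph_300, rng):
        pats = sample_patterns(300, 1, seed=8)
        J = hebbian_couplings(er_graph_300, pats)
        S = pats[0].copy()
        means = []
        for _ in range(60):
            S = update_finite_T(S, J, T=1e12, rng=rng)
            means.append(S.mean())
        assert abs(np.mean(means)) < 4 / math.sqrt(300 * 60 / 3)

    def test_zero_T_reduction(self, er_graph_300, rng):
        pats = sample_patterns(300, 2, seed=9)
        J = hebbian_couplings(er_graph_300, pats)
        S = (2 * rng.integers(0, 2, 300) - 1).astype(np.int8)
        order = rng.permutation(300)
        assert np.array_equal(update_finite_T(S, J, 0.0, rng, order),
                              update_zero_T(S, J, order))

    def test_negative_temperature_rejected(self, er_graph_300, rng):
        pats = sample_patterns(300, 1, seed=0)
        J = hebbian_couplings(er_graph_300, pats)
        with pytest.raises(ValueError):
            update_finite_T(pats[0], J, -0.1, rng)

    def test_two_spin_boltzmann(self, rng):
        # single ferromagnetic bond J = 1: exact 4-state Gibbs measure
        spec = NetworkSpec("er", 2, K=1.0)
        g = WeightedGraph(spec=spec, w=np.array([0.5, 0.5]),
                          edges=np.array([[0, 1]]), degrees=np.array([1, 1]))
        J = hebbian_couplings(g, np.array([[1, 1]], dtype=np.int8))
        T = 1.0
        S = np.array([1, -1], dtype=np.int8)
        counts = {}
        n_sweeps = 30_000
        for _ in range(n_sweeps):
            S = update_finite_T(S, J, T, rng)
            counts[tuple(S)] = counts.get(tuple(S), 0) + 1
        z = {(s0, s1): math.exp(s0 * s1 / T) for s0 in (1, -1) for s1 in (1, -1)}
        Z = sum(z.values())
        for state, c in counts.items():
            p = z[state] / Z
            se = math.sqrt(p * (1 - p) / n_sweeps)
            # Markov-chain samples are correlated; allow a generous factor
            assert abs(c / n_sweeps - p) < 8 * se


class TestOverlapAndErrorRate:
    def test_perfect_and_flipped(self, rng):
        w = np.full(20, 0.05)
        xi = (2 * rng.integers(0, 2, 20) - 1).astype(np.int8)
        assert weighted_overlap(xi, xi, w) == pytest.approx(1.0)
        assert weighted_overlap(-xi, xi, w) == pytest.approx(-1.0)

    def test_random_state_clt(self, rng):
        N = 10_000
        w = np.full(N, 1 / N)
        xi = (2 * rng.integers(0, 2, N) - 1).astype(np.int8)
        S = (2 * rng.integers(0, 2, N) - 1).astype(np.int8)
        assert abs(weighted_overlap(S, xi, w)) < 4 / math.sqrt(N)

    def test_equals_plain_overlap_for_uniform_w(self, rng):
        N = 100
        xi = (2 * rng.integers(0, 2, N) - 1).astype(np.int8)
        S = (2 * rng.integers(0, 2, N) - 1).astype(np.int8)
        assert weighted_overlap(S, xi, np.full(N, 1 / N)) == pytest.approx(
            float(np.mean(xi * S)))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_overlap(np.ones(3), np.ones(4), np.ones(4) / 4)

    @pytest.mark.parametrize("m,ne", [(1.0, 0.0), (0.0, 0.5), (0.4, 0.3), (-1.0, 1.0)])
    def test_error_rate_values(self, m, ne):
        assert error_rate(m) == pytest.approx(ne)

    def test_error_rate_domain(self):
        with pytest.raises(ValueError):
            error_rate(1.5)


class TestRunRetrieval:
    def test_perfect_init_single_pattern(self, er_graph_300):
        pats = sample_patterns(300, 1, seed=11)
        res = run_retrieval(er_graph_300, pats, T=0.0, init_overlap=1.0, seed=1)
        # isolated nodes relax to +1 in the first sweep; everything else is fixed
        assert res.converged and res.sweeps <= 2
        live = er_graph_300.degrees > 0
        assert np.array_equal(res.final_state[live], pats[0][live])
        n_iso = int((~live).sum())
        assert res.m_trace[-1] >= 1.0 - 2.0 * n_iso / 300 - 1e-12

    def test_overload_is_confused(self, er_graph_300):
        # far beyond capacity the quenched sparse graph cannot retrieve
        pats = sample_patterns(300, 150, seed=12)
        res = run_retrieval(er_graph_300, pats, T=0.0, init_overlap=1.0,
                            max_sweeps=80, seed=2)
        assert error_rate(res.m_trace[-1]) > 0.2

    def test_energy_trace_monotone_at_zero_T(self, er_graph_300):
        pats = sample_patterns(300, 10, seed=13)
        res = run_retrieval(er_graph_300, pats, T=0.0, init_overlap=0.5,
                            max_sweeps=50, seed=3)
        assert np.all(np.diff(res.energy_trace) <= 1e-12)
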