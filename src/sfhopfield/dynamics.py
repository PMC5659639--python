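"""Hopfield dynamics on a given graph.

Ising spins S_i = +-1 sit on the nodes; p stored patterns xi^mu enter the
couplings through the Hebbian rule J_ij = (1/K) sum_mu xi_i^mu xi_j^mu,
defined on the edges of the graph only.  The energy is
H = - sum_{(i,j) in G} J_ij S_i S_j.

Zero-temperature retrieval runs asynchronous sign updates,
S_i <- sgn(sum_j J_ij S_j), with the convention that an exactly zero local
field sets S_i = +1.  The finite-temperature sampler is asynchronous
heat-bath (Glauber): S_i <- +1 with probability 1/(1 + exp(-2 h_i / T)),
which satisfies detailed balance w.r.t. exp(-H/T) and reduces to the sign
rule (including the tie convention) at T = 0.

Retrieval quality is measured by the weighted overlap
m = sum_i w_i xi_i S_i and the error rate n_e = (1 - m)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix

from .networks import WeightedGraph

__all__ = [
    "CouplingMap",
    "RetrievalResult",
    "hebbian_couplings",
    "energy",
    "update_zero_T",
    "update_finite_T",
    "weighted_overlap",
    "error_rate",
    "run_retrieval",
]


@dataclass
class CouplingMap:
    """Sparse symmetric couplings J_ij on the edges of a graph."""

    edges: np.ndarray       # (L, 2), i < j
    J: np.ndarray           # (L,) coupling per edge
    K: float                # mean-degree normalizer used in the Hebbian rule
    N: int
    # CSR adjacency for fast local fields (both directions of each edge)
    indptr: np.ndarray
    indices: np.ndarray
    data: np.ndarray

    def local_field(self, S: np.ndarray, i: int) -> float:
        sl = slice(self.indptr[i], self.indptr[i + 1])
        return float(self.data[sl] @ S[self.indices[sl]])

    def fields(self, S: np.ndarray) -> np.ndarray:
        return csr_matrix((self.data, self.indices, self.indptr), shape=(self.N, self.N)) @ S


@dataclass
class RetrievalResult:
    m_trace: np.ndarray
    energy_trace: np.ndarray
    final_state: np.ndarray
    converged: bool
    sweeps: int


def hebbian_couplings(graph: WeightedGraph, patterns: np.ndarray) -> CouplingMap:
    """J_ij = (1/K) sum_mu xi_i^mu xi_j^mu on the edges of the graph."""
    patterns = np.atleast_2d(np.asarray(patterns))
    N = graph.spec.N
    if patterns.shape[1] != N:
        raise ValueError(f"pattern length {patterns.shape[1]} != graph size {N}")
    edges = graph.edges
    K = graph.spec.K
    if len(edges):
        J = np.einsum("me,me->e", patterns[:, edges[:, 0]], patterns[:, edges[:, 1]]) / K
    else:
        J = np.zeros(0)
    # symmetric CSR with both (i,j) and (j,i)
    rows = np.concatenate([edges[:, 0], edges[:, 1]]) if len(edges) else np.zeros(0, int)
    cols = np.concatenate([edges[:, 1], edges[:, 0]]) if len(edges) else np.zeros(0, int)
    vals = np.concatenate([J, J])
    A = csr_matrix((vals, (rows, cols)), shape=(N, N))
    A.sum_duplicates()
    return CouplingMap(edges=edges, J=J, K=K, N=N,
                       indptr=A.indptr, indices=A.indices, data=A.data)


def energy(S: np.ndarray, J: CouplingMap) -> float:
    """H = - sum over undirected edges of J_ij S_i S_j (each edge once)."""
    if len(J.edges) == 0:
        return 0.0
    return float(-np.sum(J.J * S[J.edges[:, 0]] * S[J.edges[:, 1]]))


def update_zero_T(S: np.ndarray, J: CouplingMap, order: np.ndarray) -> np.ndarray:
    """One asynchronous zero-T sweep in the given node order (in place copy).

    Each update sees the latest state; a local field of exactly zero forces
    S_i = +1 (isolated nodes therefore relax to +1).
    """
    S = S.copy()
    for i in order:
        h = J.local_field(S, i)
        S[i] = 1 if h >= 0.0 else -1
    return S


def update_finite_T(S: np.ndarray, J: CouplingMap, T: float, rng,
                    order: np.ndarray | None = None) -> np.ndarray:
    """One asynchronous heat-bath sweep at temperature T >= 0."""
    if T < 0:
        raise ValueError("temperature must be non-negative")
    if order is None:
        order = rng.permutation(J.N)
    if T == 0.0:
        return update_zero_T(S, J, order)
    S = S.copy()
    u = rng.random(len(order))
    for k, i in enumerate(order):
        h = J.local_field(S, i)
        p_up = 1.0 / (1.0 + np.exp(-2.0 * h / T))
        S[i] = 1 if u[k] < p_up else -1
    return S


def weighted_overlap(S: np.ndarray, pattern: np.ndarray, w: np.ndarray) -> float:
    """m = sum_i w_i xi_i S_i; equals the plain overlap for uniform w."""
    if not (len(S) == len(pattern) == len(w)):
        raise ValueError("state, pattern and weights must have equal length")
    return float(np.sum(w * pattern * S))


def error_rate(m: float) -> float:
    """n_e = (1 - m)/2: 0 at perfect retrieval, 1/2 at complete confusion."""
    if abs(m) > 1.0 + 1e-12:
        raise ValueError("overlap must lie in [-1, 1]")
    return (1.0 - min(max(m, -1.0), 1.0)) / 2.0


def run_retrieval(graph: WeightedGraph, patterns: np.ndarray, target: int = 0,
                  T: float = 0.0, init_overlap: float = 1.0,
                  max_sweeps: int | None = None, seed: int = 0) -> RetrievalResult:
    """Run asynchronous retrieval dynamics toward pattern ``target``.

    The initial state copies the target pattern on the first
    ceil(init_overlap * N) nodes and is i.i.d. +-1 elsewhere.  At T = 0 the
    run stops when a full sweep flips no spin (2-cycles are reported as
    non-converged via the sweep cap, default 10 N).
    """
    patterns = np.atleast_2d(np.asarray(patterns))
    p, N = patterns.shape
    if not 0 <= target < p:
        raise ValueError("target pattern index out of range")
    rng = np.random.default_rng(seed)
    J = hebbian_couplings(graph, patterns)
    xi = patterns[target].astype(np.int8)

    n_copy = int(np.ceil(init_overlap * N))
    S = (2 * rng.integers(0, 2, size=N) - 1).astype(np.int8)
    S[:n_copy] = xi[:n_copy]

    if max_sweeps is None:
        max_sweeps = 10 * N
    w = graph.w
    m_trace = [weighted_overlap(S, xi, w)]
    e_trace = [energy(S, J)]
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        order = rng.permutation(N)
        S_new = (update_zero_T(S, J, order) if T == 0.0
                 else update_finite_T(S, J, T, rng, order))
        m_trace.append(weighted_overlap(S_new, xi, w))
        e_trace.append(energy(S_new, J))
        if T == 0.0 and np.array_equal(S_new, S):
            converged = True
            S = S_new
            break
        S = S_new
    return RetrievalResult(m_trace=np.array(m_trace), energy_trace=np.array(e_trace),
                           final_state=S, converged=converged, sweeps=sweeps)
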