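"""Scale-free network ensembles and random memory patterns.

The ensembles here are defined through a node-weight vector ``w`` with
``sum(w) == 1``.  A graph is drawn by repeatedly picking an unordered pair of
distinct nodes, node ``i`` with probability ``w_i``, and connecting it unless
the pair is already connected; after ``N K / 2`` repetitions the probability
that a pair (i, j) carries an edge is ``f_ij = 1 - exp(-N K w_i w_j)``.

Two weight families are supported:

* Chung-Lu: ``w_i ∝ (i + i0 - 1)^(-nu)`` with an offset ``i0`` that enforces
  the natural degree cutoff for ``1/2 < nu < 1`` (degree exponent
  ``gamma = 1 + 1/nu < 3``),
* static model: the same with ``i0 = 1`` for every ``nu`` (disassortative
  degree correlations for ``2 < gamma < 3``).

``nu = 0`` gives uniform weights, i.e. the Erdos-Renyi graph; ``K -> N``
saturates every pair and gives the complete graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "NetworkSpec",
    "WeightedGraph",
    "compute_i0",
    "compute_weights",
    "connection_probability",
    "sample_graph",
    "sample_patterns",
    "read_edge_list",
    "write_edge_list",
    "write_weights_csv",
]

_MODELS = ("chung_lu", "static", "er", "fully_connected")


@dataclass(frozen=True)
class NetworkSpec:
    """Ensemble parameters (model kind, size N, mean degree K, exponent).

    Exactly one of ``gamma`` (> 2) or ``nu`` (in [0, 1)) fixes the degree
    exponent through ``gamma = 1 + 1/nu``; ``nu = 0`` (``gamma`` infinite)
    means uniform weights.
    """

    model: str
    N: int
    K: float
    gamma: float = math.inf
    nu: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {_MODELS}")
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if not self.K > 0:
            raise ValueError("K must be positive")
        if self.nu is None:
            nu = 0.0 if math.isinf(self.gamma) else 1.0 / (self.gamma - 1.0)
            object.__setattr__(self, "nu", nu)
        else:
            gamma = math.inf if self.nu == 0 else 1.0 + 1.0 / self.nu
            if not math.isinf(self.gamma) and abs(gamma - self.gamma) > 1e-9:
                raise ValueError("gamma and nu are inconsistent (gamma = 1 + 1/nu)")
            object.__setattr__(self, "gamma", gamma)
        if not 0.0 <= self.nu < 1.0:
            raise ValueError("nu must lie in [0, 1), i.e. gamma > 2")
        if self.model in ("er", "fully_connected") and self.nu != 0.0:
            raise ValueError(f"{self.model} requires uniform weights (nu = 0)")
        if self.model == "fully_connected" and abs(self.K - self.N) > 1e-9:
            raise ValueError("fully_connected means K = N")


@dataclass
class WeightedGraph:
    """A simple undirected graph together with the weights that generated it."""

    spec: NetworkSpec
    w: np.ndarray
    edges: np.ndarray  # (L, 2) int array, each row i < j, unique
    degrees: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.spec.N


def compute_i0(nu: float, N: int) -> float:
    """Offset constant of the Chung-Lu weights.

    ``i0 = [10 sqrt(2) (1 - nu)]^(1/nu) * N^(1 - 1/(2 nu))`` for
    ``1/2 < nu < 1`` (it enforces the natural cutoff of the degree sequence
    when gamma < 3) and ``i0 = 1`` for ``0 <= nu <= 1/2``.
    """
    if not 0.0 <= nu < 1.0:
        raise ValueError("nu must lie in [0, 1)")
    if nu <= 0.5:
        return 1.0
    return (10.0 * math.sqrt(2.0) * (1.0 - nu)) ** (1.0 / nu) * N ** (1.0 - 1.0 / (2.0 * nu))


def compute_weights(spec: NetworkSpec) -> np.ndarray:
    """Normalized node weights for the ensemble: sum(w) = 1, non-increasing."""
    N = spec.N
    if spec.model in ("er", "fully_connected") or spec.nu == 0.0:
        return np.full(N, 1.0 / N)
    nu = spec.nu
    i0 = compute_i0(nu, N) if spec.model == "chung_lu" else 1.0
    i = np.arange(1, N + 1, dtype=float)
    w = (i + i0 - 1.0) ** (-nu)
    return w / w.sum()


def connection_probability(w: np.ndarray, spec: NetworkSpec, i: int, j: int) -> float:
    """Edge probability f_ij = 1 - exp(-N K w_i w_j) of the ensemble."""
    if i == j:
        raise ValueError("self-pairs carry no edge (i must differ from j)")
    if spec.model == "fully_connected":
        return 1.0
    ww = float(w[i]) * float(w[j])      # product first: exactly symmetric in (i, j)
    return -math.expm1(-spec.N * spec.K * ww)


def sample_graph(spec: NetworkSpec, seed: int) -> WeightedGraph:
    """Draw one graph: NK/2 weighted pair choices, duplicates discarded.

    A repetition whose two draws coincide (i == j) is redrawn; a repetition
    that hits an existing edge is consumed without adding an edge, so the
    realized mean degree falls slightly below K for dense specs.
    """
    w = compute_weights(spec)
    N = spec.N
    if spec.model == "fully_connected":
        iu, ju = np.triu_indices(N, k=1)
        edges = np.column_stack([iu, ju])
    else:
        rng = np.random.default_rng(seed)
        n_rep = int(round(N * spec.K / 2.0))
        seen: set[tuple[int, int]] = set()
        done = 0
        while done < n_rep:
            batch = max(n_rep - done, 64)
            pair = rng.choice(N, size=(batch, 2), p=w)
            for a, b in pair:
                if a == b:
                    continue  # redrawn: does not consume a repetition
                if done >= n_rep:
                    break
                done += 1
                e = (a, b) if a < b else (b, a)
                seen.add(e)
        edges = np.array(sorted(seen), dtype=int).reshape(-1, 2)
    degrees = np.zeros(N, dtype=int)
    if len(edges):
        np.add.at(degrees, edges[:, 0], 1)
        np.add.at(degrees, edges[:, 1], 1)
    return WeightedGraph(spec=spec, w=w, edges=edges, degrees=degrees)


def sample_patterns(N: int, p: int, seed: int) -> np.ndarray:
    """p x N matrix of i.i.d. +-1 memory patterns (each sign probability 1/2)."""
    if N < 1 or p < 1:
        raise ValueError("need N >= 1 and p >= 1")
    rng = np.random.default_rng(seed)
    return (2 * rng.integers(0, 2, size=(p, N)) - 1).astype(np.int8)


# ----------------------------------------------------------------------------
# plain-text I/O

def write_edge_list(graph_or_edges, path) -> None:
    edges = graph_or_edges.edges if isinstance(graph_or_edges, WeightedGraph) else np.asarray(graph_or_edges)
    with open(path, "w") as fh:
        fh.write("# i j (0-based, i < j)\n")
        for i, j in edges:
            fh.write(f"{int(i)} {int(j)}\n")


def read_edge_list(path) -> np.ndarray:
    """Read "i j" lines (whitespace or comma separated); returns (L, 2) array.

    Directed or repeated pairs are symmetrized and collapsed; self-loops are
    rejected.
    """
    edges = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two node indices, got {line!r}")
        try:
            i, j = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer node index in {line!r}") from exc
        if i == j:
            raise ValueError(f"{path}:{lineno}: self-loop {i}-{j} not allowed")
        edges.add((min(i, j), max(i, j)))
    return np.array(sorted(edges), dtype=int).reshape(-1, 2)


def write_weights_csv(w: Iterable[float], path) -> None:
    with open(path, "w") as fh:
        fh.write("w\n")
        for x in w:
            fh.write(f"{float(x)!r}\n")
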