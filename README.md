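# sfhopfield

Associative-memory storage in Hopfield networks whose connectivity is
scale-free rather than all-to-all.  The package is aimed at researchers in
neural-network theory and network science who want to reproduce, probe or
extend the replica-symmetric analysis of Hebbian memory on heterogeneous
graphs: how many random ±1 patterns a network of `N` Ising neurons with
mean degree `K` and degree exponent γ can retrieve, and with how much error.

The core objects are the replica-symmetric order parameters — retrieval
overlap `m`, spin-glass overlap `q` and interference noise `r` — at storage
rate `a = p/N` and noise level `T`.  With node weights `w_i` (∝ expected
degree, `Σ w_i = 1`, `λ_i = N w_i`) the zero-temperature self-consistency
is

    m = Σ_i w_i erf( √(λ_i / (2 a r)) · m )
    χ = Σ_i w_i √(2 / (π λ_i a r)) · exp(−λ_i m² / (2 a r))
    r = (1 − χ/K) / (1 − χ)²

whose uniform-weight, `K → N` limit is the classic fully connected theory
(capacity `a_c ≈ 0.138`).  Finite-temperature forms, a free-energy
comparison of branches (retrieval vs spin glass → phases P / SG / M / R),
error-rate curves `n_e(a) = (1 − m)/2`, phase diagrams and the critical
degree exponents of the heterogeneity-enhanced regime are built on top,
together with the quenched counterpart: weighted random-graph sampling
(Chung-Lu, static model, ER, complete), Hebbian couplings and asynchronous
zero-/finite-temperature dynamics on actual graph samples.

## Worked example

```python
import numpy as np
from sfhopfield import weights_for, find_capacity_T0, error_curve_T0

K = 5.0
w_er = weights_for("er", 1000, K)          # uniform weights, gamma -> inf
a_m, a_c = find_capacity_T0(w_er, K)
print(f"a_c = {a_c:.4f}, a_m = {a_m:.4f}")

w_sf = weights_for("chung_lu", 1000, K, gamma=2.01)
curve = error_curve_T0(w_sf, K, np.arange(0.005, 1.0, 0.005))
print(f"gamma=2.01: max n_e = {curve.n_e.max():.3f}, jump: {curve.a_c}")
```

prints

```
a_c = 0.1435, a_m = 0.0585
gamma=2.01: max n_e = 0.292, jump: None
```

Read: on the ER-limit network the retrieval branch exists up to
`a_c = 0.1435` (beyond it the error rate jumps to 1/2, complete confusion)
but is the thermodynamic ground state only below `a_m = 0.0585` (between
the two lies the mixed phase).  On the strongly heterogeneous network
(γ = 2.01) the jump is gone: every storage rate up to `a = 1` retrieves
with an error that never exceeds 0.29 — hubs trade a modest, graded error
for an enormously extended storage range.

The numbered drivers under `analysis/` run the full study (ensemble
sampling, quenched dynamics vs theory, capacities, error curves, phase
diagrams, critical exponents) and write their tables to `results/`.  A CLI
exposes the same operations (`sfhopfield generate-network / simulate /
solve / phase-diagram / error-curve / critical`); see `--help`.

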