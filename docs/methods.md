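# Methods

## Model

Each node `i` of a network `G` carries an Ising spin `S_i = ±1` (neuron
firing / silent).  Storing `p` random ±1 patterns `ξ^μ` by the Hebbian rule
gives couplings on the edges of `G`,

    J_ij = (1/K) Σ_μ ξ_i^μ ξ_j^μ ,        H = − Σ_{(i,j)∈G} J_ij S_i S_j ,

with `K` the mean degree.  Retrieval quality of pattern `μ` is the weighted
overlap `m = Σ_i w_i ξ_i^μ ⟨S_i⟩` and the error rate `n_e = (1 − m)/2`.
The storage rate is `a = p/N`; temperature `T` is noise strength, not a
physical temperature.

## Network ensembles

Graphs are drawn from weight-based ensembles: node `i` has weight

    Chung-Lu:  w_i ∝ (i + i0 − 1)^(−ν),   i0 = [10√2(1−ν)]^{1/ν} N^{1−1/(2ν)}  (ν > 1/2), else 1
    static:    w_i ∝ i^(−ν)               (i0 ≡ 1; disassortative for 2 < γ < 3)

with degree exponent `γ = 1 + 1/ν`; `ν = 0` is Erdős–Rényi, and `K → N`
the complete graph.  `N K / 2` node pairs are drawn with probabilities
`(w_i, w_j)` and connected unless already connected (self-pairs are
redrawn), so the pairwise edge probability is `f_ij = 1 − exp(−N K w_i w_j)`
and the realized mean degree sits slightly below `K` for dense specs.  The
`i0` offset enforces the natural degree cutoff for `γ < 3`; its bracket
constant is transcribed from a low-fidelity source, and the package treats
the form above as definitive (the error-ceiling result below is insensitive
to moderate changes, the critical-exponent locations shift by a few
hundredths).

## Replica-symmetric equations

Averaging over graphs and patterns and taking the replica-symmetric ansatz
reduces the thermodynamics to three order parameters `(m, q, r)`; with
`λ_i = N w_i` the condensed local field of node `i` is
`h_i = λ_i m + √(λ_i a r) · z`, `z ~ N(0,1)` — the signal and the
interference variance both scale with the node's connectivity — and

    m = Σ_i w_i ∫Dz tanh(β h_i)
    q = Σ_i w_i ∫Dz tanh²(β h_i)
    r = q (1 − χ/K) / (1 − χ)²,     χ = β(1 − q).

The factor `(1 − χ/K)` is the finite-connectivity correction; `K → ∞`
recovers the classic fully connected storage equations.  At `T = 0` the
averages close in `erf`/Gaussian form and `χ` stays finite:

    m = Σ_i w_i erf( √(λ_i/(2 a r)) · m )
    χ = Σ_i w_i √(2/(π λ_i a r)) · exp(−λ_i m²/(2 a r))
    r = (1 − χ/K) / (1 − χ)².

This per-node noise scaling is the only closure that is variationally
consistent with the weighted definitions of both `m` and `q`, and it
reproduces the rise of the paramagnetic boundary with heterogeneity
(`T_g ≈ 1 + √(a·N Σ w_i²)` at small q, which diverges as γ → 2).

The finite-temperature forms reduce to the zero-temperature ones exactly as
`T → 0`; the zero-temperature solver reports the `q` of the closed
zero-temperature system (`1 − χ/K`), the finite-temperature solver the
thermal `q`.

## Free energy and phases

Branches are compared with the replica-symmetric free-energy functional
whose stationarity conditions are exactly the equations above:

    βf = (β/2)m² + (a/2)G_K(q) + (aβ²r/2)(1−q) − (1/N) Σ_i ∫Dz ln 2cosh(β h_i)
    G_K(q) = ln|1−χ| − βq/(1−χ) − (1/K)[(2−β)ln|1−χ| + (1−β)/(1−χ) + χ].

In the fully connected limit this is the classic functional (it places the
retrieval/spin-glass crossing at `a ≈ 0.051` there).  Phase labels:
P (`m = q = 0`), SG (`m = 0, q > 0`), R (retrieval branch exists and is the
global minimum), M (retrieval exists but the SG branch lies lower).  The
spin-glass branch solved here is the root with `χ < 1`, the one continuously
connected to the paramagnet; an `m = 0` root with `χ > 1` also exists at low
temperature but never minimizes the free energy.

Known limitation: with the finite-connectivity correction at `K = 5` this
functional puts the zero-temperature R/M crossing at `a_m = 0.0585`.  The
stationarity conditions do not determine the functional uniquely (any
q-dependent rescaling of the `G_K`/coupling split preserves them), and a
scan over that family moves the crossing only within ≈ 0.03–0.07, so the
choice above — the unique member with the AGS structure and the exact
fully-connected limit — is used throughout.

## Replica-symmetry stability

The stability margin implemented is the standard replicon condition
weighted like the q-equation, `(1−χ)² − a β² N Σ_i w_i² ⟨sech⁴(β h_i)⟩`;
it is positive (stable) everywhere except a strip hugging `T = 0`, where
`β²⟨sech⁴⟩` diverges.  The `1/K` correction to the replicon is neglected.

## Numerics

* Thermal Gaussian averages develop boundary layers of width `O(T)` as
  `T → 0`, which plain Gauss–Hermite cannot resolve.  Each site is
  integrated either in the field variable (80-node Gauss–Hermite, used when
  `β d_i < 2`, `d_i = √(λ_i a r)`) or after substituting `u = βh` (40-node
  Legendre rule against the smooth `sech²`-type kernels on `(0, 18]`, used
  when `β d_i ≥ 2`); the second form reduces analytically to the
  zero-temperature expressions, so the `T → 0` limit is exact by
  construction.  Sites with `d_i < 10⁻¹²` use the deterministic-field
  formulas.
* Solvers: the retrieval branch runs a damped fixed-point iteration on
  `(m, r)` (damping 0.5, halved when the residual stalls; residual tolerance
  `10⁻¹¹`, cap `10⁵` iterations; a transient `χ ≥ 1` grows `r` instead of
  failing).  An iteration whose overlap decays below `10⁻⁵` and keeps
  shrinking has collapsed onto the `m = 0` branch (retrieval absent).  The
  spin-glass branch is a bracketed scalar root (`brentq`) in `r` (or in `χ`
  at `T = 0`).  Finite-temperature cold starts are seeded from the
  zero-temperature solution.  `m > 10⁻⁶` / `q > 10⁻⁶` are the numerical
  zeros for labels; `r` is floored at `10⁻³⁰⁰`; `a = 0` is handled
  analytically (`m = 1` at `T = 0`, weighted Curie–Weiss at `T > 0`).
* Capacities: bisection to `5·10⁻⁴` on retrieval existence (`a_c`) and on
  the free-energy gap (`a_m`).
* Error curves follow the retrieval branch by continuation in `a` (each
  solve seeded with the previous solution); a step `≥ 0.2` in `n_e` between
  adjacent grid points (step 0.005) is a jump.
* SG-collapse exponents: bisection on γ (to 0.02) of "no grid point with
  `T ≥ 0.01`, `a ∈ (0, 1]` classifies SG", scanned on `a` step 0.025 and a
  low-T-densified temperature grid up to `T = 2`; the cheap lowest-row scan
  drives the bisection and the full grid certifies the no-SG side.  These
  grid sizes keep a full exponent bisection at minutes on one core; halving
  the steps moves γ_c by less than the quoted tolerance.

## Simulation module

The dynamics module implements the quenched model on one sampled graph:
asynchronous sign updates at `T = 0` (exact zero field → `+1`), asynchronous
heat-bath at `T > 0` (detailed balance w.r.t. `exp(−H/T)`, reducing to the
sign rule at `T = 0`), fresh random update permutation per sweep,
convergence declared when a sweep flips nothing (cap `10 N` sweeps;
2-cycles report non-converged).  Initial states copy the target pattern on
the first `⌈init_overlap·N⌉` sites.

What the simulations do and do not validate: on *dense* graphs the quenched
dynamics agrees with the solver, and the toy 9-node example retrieves its
two stored patterns.  On *sparse* graphs (`K = 5`, `N = 1000`) a quenched
sample stores only `O(K)` patterns — the local-field signal-to-crosstalk
ratio is `k_i/√(k_i p)` — so simulated error rates at `p = aN` patterns sit
far above the ensemble-averaged theory; the annealed equations describe the
weight ensemble, not a single sparse realization.  Passing mean-field tests
therefore says nothing about single sparse graphs, and vice versa.

## Synthetic data

All inputs are generated internally: graphs from the weight ensembles
(study conditions `N = 1000`, `K = 5.0` throughout), patterns i.i.d. ±1
with probability 1/2, scan grids as above.  The generator reproduces the
heavy-tailed degree distributions of the ensembles; it does not emulate
degree correlations beyond the static model's intrinsic ones, modularity,
weighted synapses or any temporal structure of real neural data — empirical
networks enter only through the degree-proportional weight path
(`w_i = k_i/2L`, `K = 2L/N`), with directed or duplicate edge-list entries
symmetrized and collapsed.
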