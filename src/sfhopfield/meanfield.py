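"""Replica-symmetric self-consistent equations for the weighted Hopfield model.

Thermodynamics of the model on a weight-defined ensemble is reduced, in the
replica-symmetric ansatz, to three order parameters at storage rate
``a = p/N`` and temperature ``T = 1/beta``:

* ``m``: weighted overlap with the condensed pattern,
* ``q``: weighted spin-glass (Edwards-Anderson) overlap,
* ``r``: interference noise from the p - 1 non-condensed patterns.

With ``lam_i = N w_i`` the local field of node ``i`` condenses to
``h_i = lam_i m + sqrt(lam_i a r) z`` (z standard normal; the noise variance
is proportional to the node's connectivity), and the equations are::

    m   = sum_i w_i Int Dz tanh(beta h_i)
    q   = sum_i w_i Int Dz tanh^2(beta h_i)
    r   = q (1 - chi/K) / (1 - chi)^2,      chi = beta (1 - q)

At ``T = 0`` the Gaussian averages close in terms of erf, and ``chi`` stays
finite::

    m   = sum_i w_i erf( sqrt(lam_i / (2 a r)) m )
    chi = sum_i w_i sqrt(2 / (pi lam_i a r)) exp(-lam_i m^2 / (2 a r))
    r   = (1 - chi/K) / (1 - chi)^2

Uniform weights (lam_i = 1) recover the classic fully-connected storage
equations when the 1/K correction is dropped (capacity a_c ~ 0.138); with the
1/K term and K = 5 the capacity moves to a_c ~ 0.143.

The free energy is the replica-symmetric functional whose stationarity
conditions are exactly these equations; comparing the retrieval and
spin-glass branches separates the retrieval (R) from the mixed (M) phase.

Numerics: the thermal Gaussian integrals develop O(T)-wide boundary layers
as T -> 0, which defeats plain Gauss-Hermite quadrature.  Each site is
therefore integrated either in the field variable (Gauss-Hermite, accurate
when ``beta * d_i`` is small) or after the substitution ``u = beta h``
(fixed Legendre rule against the smooth sech^2-type kernels, uniformly
accurate at low T and reducing exactly to the T = 0 closed forms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq
from scipy.special import erf

__all__ = [
    "OrderParameters",
    "SolutionBranch",
    "rhs_T0",
    "solve_T0",
    "rhs_finite_T",
    "solve_finite_T",
    "free_energy",
    "at_line",
    "solve_fully_connected_T0",
]

M_EPS = 1e-6       # numerical zero for "m > 0" / "q > 0" labels
R_FLOOR = 1e-300
_TOL = 1e-11
_ITMAX = 100_000

# --- quadrature tables -------------------------------------------------------

# u-rule: integrals of smooth-decaying even/odd kernels over u in (0, 18]
_UX, _UW = leggauss(40)
_UX = 9.0 * (_UX + 1.0)          # nodes in (0, 18)
_UW = 9.0 * _UW
_SECH2_U = 1.0 / np.cosh(_UX) ** 2
_SECH4_U = _SECH2_U ** 2
_TANH_M1_U = np.tanh(_UX) - 1.0                  # tanh(u) - sign(u), u > 0
_LOG1PE_U = np.log1p(np.exp(-2.0 * _UX))

# z-rule: Gauss-Hermite (probabilists') for Int Dz f(z)
from numpy.polynomial.hermite_e import hermegauss

_ZX, _ZW = hermegauss(80)
_ZW = _ZW / math.sqrt(2.0 * math.pi)

_SPLIT = 2.0      # beta*d above which the u-rule takes over


@dataclass
class OrderParameters:
    m: float
    q: float
    r: float
    residual: float = math.nan


@dataclass
class SolutionBranch:
    label: str                    # "retrieval" | "spin_glass" | "paramagnetic"
    params: OrderParameters
    free_energy: float
    converged: bool = True


def _phi(x):
    return np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)


# --- zero-temperature map ----------------------------------------------------

def _t0_sums(m: float, r: float, w: np.ndarray, a: float):
    """Return (m_hat, chi) of the zero-T map at (m, r).

    Zero-weight entries (isolated nodes of an empirical network) carry no
    weight in the order parameters and are skipped; ``lam`` keeps the full N.
    """
    pos = w > 0
    lam = len(w) * w[pos]
    wp = w[pos]
    ar = max(a * r, R_FLOOR)
    s = np.sqrt(lam / (2.0 * ar))
    m_hat = float(np.sum(wp * erf(s * m)))
    chi = float(np.sum(wp * np.sqrt(2.0 / (np.pi * lam * ar)) * np.exp(-(s * m) ** 2)))
    return m_hat, chi


def rhs_T0(params: OrderParameters, w: np.ndarray, K: float, a: float) -> OrderParameters:
    """One application of the zero-temperature self-consistency map."""
    if a <= 0:
        raise ValueError("a must be positive (a = 0 is the exact m = 1 solution)")
    m_hat, chi = _t0_sums(params.m, params.r, w, a)
    q_hat = 1.0 - chi / K
    r_hat = q_hat / (1.0 - chi) ** 2 if chi != 1.0 else math.inf
    return OrderParameters(m=m_hat, q=q_hat, r=r_hat)


def _iterate(step, m0: float, r0: float, damp: float = 0.5,
             tol: float = _TOL, itmax: int = _ITMAX):
    """Damped fixed-point iteration on (m, r); ``step(m, r) -> (m_hat, r_hat)``.

    Halves the damping when the residual stops shrinking.  Returns
    (m, r, residual, converged).  An iteration whose overlap collapses below
    numerical zero exits early: the m = 0 branch has been reached.
    """
    m, r = m0, max(r0, R_FLOOR)
    res_prev = math.inf
    stall = 0
    for _ in range(itmax):
        m_hat, r_hat = step(m, r)
        if not (math.isfinite(m_hat) and math.isfinite(r_hat)):
            return m, r, math.inf, False
        res = max(abs(m_hat - m), abs(r_hat - r) / max(1.0, abs(r)))
        if res < tol:
            return m_hat, r_hat, res, True
        if res > res_prev:
            stall += 1
            if stall >= 10:
                damp = max(damp * 0.5, 0.02)
                stall = 0
        res_prev = res
        m += damp * (m_hat - m)
        r = max(r + damp * (r_hat - r), R_FLOOR)
        if m0 > 0 and m < 1e-5 and m_hat < 0.95 * m:
            return 0.0, r, res, True     # collapsing onto the m = 0 branch
    return m, r, res_prev, False


def _sg_chi_T0(w: np.ndarray, K: float, a: float) -> float:
    """chi of the zero-T spin-glass branch (the root with chi < 1).

    At m = 0 the zero-T equations close to a single scalar condition:
    chi = W_h sqrt(2/(pi a r)), r = (1 - chi/K)/(1 - chi)^2, with
    W_h = sum_i w_i / sqrt(N w_i).  The branch continuously connected to the
    paramagnet has chi in (0, 1).
    """
    wp = w[w > 0]
    W_h = float(np.sum(wp / np.sqrt(len(w) * wp)))

    def g(chi):
        r = (1.0 - chi / K) / (1.0 - chi) ** 2
        return 2.0 * W_h ** 2 / (math.pi * chi ** 2 * r) - a

    return brentq(g, 1e-12, 1.0 - 1e-12, xtol=1e-15)


def solve_T0(w: np.ndarray, K: float, a: float,
             init: OrderParameters | None = None,
             branch: str = "retrieval") -> SolutionBranch:
    """Solve the zero-temperature equations on one branch.

    ``branch="retrieval"`` runs the damped iteration from (m, r) = (1, 1e-6)
    (or ``init``); if the overlap collapses, the retrieval solution does not
    exist at this ``a`` and the spin-glass branch is returned instead.
    ``branch="sg"`` solves the m = 0 branch directly.
    """
    w = np.asarray(w, dtype=float)
    if a < 0:
        raise ValueError("a must be non-negative")
    if a == 0:
        return SolutionBranch("retrieval", OrderParameters(1.0, 1.0, 0.0, 0.0),
                              free_energy=free_energy_T0(1.0, 0.0, 0.0, w, K, a))
    if branch == "sg":
        chi = _sg_chi_T0(w, K, a)
        q = 1.0 - chi / K
        r = q / (1.0 - chi) ** 2
        return SolutionBranch("spin_glass", OrderParameters(0.0, q, r, 0.0),
                              free_energy=free_energy_T0(0.0, chi, r, w, K, a))

    m0, r0 = (1.0, 1e-6) if init is None else (init.m, max(init.r, R_FLOOR))

    def step(m, r):
        m_hat, chi = _t0_sums(m, r, w, a)
        if chi >= 1.0 or chi >= K:
            return m_hat, 4.0 * r    # transient: grow the noise, chi falls back
        return m_hat, (1.0 - chi / K) / (1.0 - chi) ** 2

    m, r, res, ok = _iterate(step, m0, r0)
    if ok and m > M_EPS:
        _, chi = _t0_sums(m, r, w, a)
        q = 1.0 - chi / K
        return SolutionBranch("retrieval", OrderParameters(m, q, r, res),
                              free_energy=free_energy_T0(m, chi, r, w, K, a),
                              converged=True)
    sg = solve_T0(w, K, a, branch="sg")
    sg.converged = ok
    return sg


# --- finite-temperature site averages ---------------------------------------

def _site_averages(c: np.ndarray, d: np.ndarray, beta: float, want_extras=False):
    """Per-site Gaussian averages of tanh, beta*sech^2 (= chi_i) and extras.

    Returns arrays (t1, chi_i[, s4_i, lncosh_i]) where
    t1_i     = Int Dz tanh(beta(c_i + d_i z))
    chi_i    = beta Int Dz sech^2(beta(c_i + d_i z))
    s4_i     = beta^2 Int Dz sech^4(beta(c_i + d_i z))
    lncosh_i = Int Dz ln 2 cosh(beta(c_i + d_i z))
    """
    n = len(c)
    t1 = np.empty(n)
    chi = np.empty(n)
    s4 = np.empty(n) if want_extras else None
    lnc = np.empty(n) if want_extras else None

    x = beta * d
    det = d < 1e-12                 # effectively deterministic field
    low = (~det) & (x < _SPLIT)     # smooth in z: Gauss-Hermite
    high = (~det) & ~low            # boundary layer: u-rule

    if det.any():
        bc = beta * c[det]
        t1[det] = np.tanh(bc)
        chi[det] = beta / np.cosh(np.clip(bc, -300, 300)) ** 2
        if want_extras:
            s4[det] = beta ** 2 / np.cosh(np.clip(bc, -300, 300)) ** 4
            ab = np.abs(bc)
            lnc[det] = ab + np.log1p(np.exp(-2 * ab))

    if low.any():
        h = beta * (c[low, None] + d[low, None] * _ZX[None, :])
        th = np.tanh(h)
        sech2 = 1.0 - th * th
        t1[low] = (th * _ZW).sum(axis=1)
        chi[low] = beta * (sech2 * _ZW).sum(axis=1)
        if want_extras:
            s4[low] = beta ** 2 * (sech2 * sech2 * _ZW).sum(axis=1)
            ah = np.abs(h)
            lnc[low] = ((ah + np.log1p(np.exp(-2 * ah))) * _ZW).sum(axis=1)

    if high.any():
        ch, dh = c[high, None], d[high, None]
        # phi((u/beta -+ c)/d) at the positive/negative u-nodes
        pp = _phi((_UX[None, :] / beta - ch) / dh)
        pm = _phi((-_UX[None, :] / beta - ch) / dh)
        t1[high] = (erf(c[high] / (math.sqrt(2.0) * d[high]))
                    + ((pp - pm) * (_TANH_M1_U * _UW)).sum(axis=1) / (beta * d[high]))
        chi[high] = ((pp + pm) * (_SECH2_U * _UW)).sum(axis=1) / d[high]
        if want_extras:
            s4[high] = beta * ((pp + pm) * (_SECH4_U * _UW)).sum(axis=1) / d[high]
            e_abs = (c[high] * erf(c[high] / (math.sqrt(2.0) * d[high]))
                     + d[high] * math.sqrt(2.0 / math.pi)
                     * np.exp(-c[high] ** 2 / (2 * d[high] ** 2)))
            lnc[high] = beta * e_abs + ((pp + pm) * (_LOG1PE_U * _UW)).sum(axis=1) / (beta * d[high])

    if want_extras:
        return t1, chi, s4, lnc
    return t1, chi


def _finite_T_sums(m: float, r: float, w: np.ndarray, a: float, beta: float,
                   want_extras=False):
    pos = w > 0
    wp = w[pos]
    lam = len(w) * wp
    c = lam * m
    d = np.sqrt(np.maximum(lam * a * r, 0.0))
    out = _site_averages(c, d, beta, want_extras)
    m_hat = float(np.sum(wp * out[0]))
    chi = float(np.sum(wp * out[1]))
    if want_extras:
        return m_hat, chi, out[2], out[3]
    return m_hat, chi


def rhs_finite_T(params: OrderParameters, w: np.ndarray, K: float, a: float,
                 T: float) -> OrderParameters:
    """One application of the finite-temperature map (T -> 0 gives rhs_T0)."""
    if T <= 0:
        return rhs_T0(params, w, K, a)
    beta = 1.0 / T
    m_hat, chi = _finite_T_sums(params.m, params.r, np.asarray(w, float), a, beta)
    q_hat = 1.0 - chi / beta
    r_hat = q_hat * (1.0 - chi / K) / (1.0 - chi) ** 2 if chi != 1.0 else math.inf
    return OrderParameters(m=m_hat, q=q_hat, r=r_hat)


def solve_finite_T(w: np.ndarray, K: float, a: float, T: float,
                   init: OrderParameters | None = None,
                   branch: str = "retrieval") -> SolutionBranch:
    """Solve the finite-temperature equations on one branch.

    The retrieval branch runs the damped (m, r) iteration; the spin-glass
    branch is a bracketed scalar root in r at m = 0 (the solution with
    chi < 1, continuously connected to the paramagnet).  A point where even
    the m = 0 branch only admits q = 0 is paramagnetic.
    """
    w = np.asarray(w, dtype=float)
    if T <= 0:
        return solve_T0(w, K, a, init=init, branch=branch)
    beta = 1.0 / T

    if a == 0:
        # weighted Curie-Weiss equation, no interference noise
        def step(m, r):
            m_hat, _ = _finite_T_sums(m, 0.0, w, a, beta)
            return m_hat, 0.0
        m, _, res, ok = _iterate(step, 1.0, 0.0) if branch == "retrieval" else (0.0, 0.0, 0.0, True)
        label = "retrieval" if m > M_EPS else "paramagnetic"
        q = _q_of(m, 0.0, w, a, beta)
        return SolutionBranch(label, OrderParameters(m, q, 0.0, res),
                              free_energy=free_energy(OrderParameters(m, q, 0.0), w, K, a, T),
                              converged=ok)

    if branch == "sg":
        return _solve_sg_finite_T(w, K, a, beta, T)

    if init is None:
        # cold start: seed from the zero-temperature retrieval solution
        t0 = solve_T0(w, K, a, branch="retrieval")
        init = t0.params if t0.label == "retrieval" else OrderParameters(1.0, 1.0, 1.0)
    m0, r0 = init.m, max(init.r, R_FLOOR)

    def step(m, r):
        m_hat, chi = _finite_T_sums(m, r, w, a, beta)
        if chi >= 1.0 or chi >= K:
            return m_hat, 4.0 * r    # transient: grow the noise, chi falls back
        q_hat = 1.0 - chi / beta
        return m_hat, q_hat * (1.0 - chi / K) / (1.0 - chi) ** 2

    m, r, res, ok = _iterate(step, m0, r0)
    if ok and m > M_EPS:
        q = _q_of(m, r, w, a, beta)
        return SolutionBranch("retrieval", OrderParameters(m, q, r, res),
                              free_energy=free_energy(OrderParameters(m, q, r), w, K, a, T),
                              converged=True)
    sg = _solve_sg_finite_T(w, K, a, beta, T)
    sg.converged = ok
    return sg


def _q_of(m: float, r: float, w: np.ndarray, a: float, beta: float) -> float:
    _, chi = _finite_T_sums(m, r, w, a, beta)
    return 1.0 - chi / beta


def _solve_sg_finite_T(w: np.ndarray, K: float, a: float, beta: float, T: float) -> SolutionBranch:
    def chi_of(r):
        _, chi = _finite_T_sums(0.0, r, w, a, beta)
        return chi

    def g(r):
        chi = chi_of(r)
        q = 1.0 - chi / beta
        return r - q * (1.0 - chi / K) / (1.0 - chi) ** 2

    # chi(r) decreases from beta (r -> 0) toward 0; restrict to chi < 1.
    r_lo = 1e-12
    if beta > 1.0:
        lo, hi = 1e-12, 1.0
        while chi_of(hi) >= 1.0:
            hi *= 2.0
            if hi > 1e12:
                break
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if chi_of(mid) >= 1.0:
                lo = mid
            else:
                hi = mid
        r_lo = hi
    if g(r_lo) >= 0.0:
        q = 0.0
        return SolutionBranch("paramagnetic", OrderParameters(0.0, 0.0, 0.0, 0.0),
                              free_energy=free_energy(OrderParameters(0.0, 0.0, 0.0), w, K, a, T))
    r_hi = max(2.0 * r_lo, 1.0)
    while g(r_hi) < 0.0:
        r_hi *= 2.0
        if r_hi > 1e14:
            raise RuntimeError("spin-glass branch bracketing failed")
    r = brentq(g, r_lo, r_hi, xtol=1e-14, rtol=1e-14)
    q = 1.0 - chi_of(r) / beta
    label = "spin_glass" if q > M_EPS else "paramagnetic"
    return SolutionBranch(label, OrderParameters(0.0, q, r, abs(g(r))),
                          free_energy=free_energy(OrderParameters(0.0, q, r), w, K, a, T))


# --- free energy -------------------------------------------------------------

def _G_K(q: float, chi: float, beta: float, K: float) -> float:
    """Noncondensed-pattern term whose q-derivative yields the r-equation."""
    one = 1.0 - chi
    base = math.log(abs(one)) - beta * q / one
    corr = (2.0 - beta) * math.log(abs(one)) + (1.0 - beta) / one + chi
    return base - corr / K


def free_energy_T0(m: float, chi: float, r: float, w: np.ndarray, K: float, a: float) -> float:
    """Zero-temperature limit of the replica-symmetric free energy per node."""
    if a == 0:
        return 0.5 * m * m - abs(m)      # -(1/N) sum_i |lam_i m| = -|m|
    N = len(w)
    lam = N * w[w > 0]
    ar = max(a * r, R_FLOOR)
    c = lam * m
    d = np.sqrt(lam * ar)
    e_abs = c * erf(c / (math.sqrt(2.0) * d)) + d * math.sqrt(2.0 / math.pi) * np.exp(-c * c / (2 * d * d))
    one = 1.0 - chi
    return (0.5 * m * m
            - 0.5 * a / one
            + 0.5 * a * (math.log(abs(one)) + 1.0 / one) / K
            + 0.5 * a * r * chi
            - float(np.sum(e_abs)) / N)         # (1/N) sum_i E|h_i|


def free_energy(params: OrderParameters, w: np.ndarray, K: float, a: float, T: float) -> float:
    """Replica-symmetric free energy per node of a solved point."""
    w = np.asarray(w, dtype=float)
    m, q, r = params.m, params.q, params.r
    if T <= 0:
        chi = _t0_sums(m, r, w, a)[1] if a > 0 else 0.0
        return free_energy_T0(m, chi, r, w, K, a)
    beta = 1.0 / T
    _, chi, _, lnc = _finite_T_sums(m, r, w, a, beta, want_extras=True)
    site = float(np.sum(lnc)) / len(w)           # (1/N) sum_i <ln 2 cosh beta h_i>
    if a == 0:
        return 0.5 * m * m - site / beta
    bf = (0.5 * beta * m * m
          + 0.5 * a * _G_K(q, chi, beta, K)
          + 0.5 * a * beta ** 2 * r * (1.0 - q)
          - site)
    return bf / beta


# --- replica-symmetry stability ----------------------------------------------

def at_line(w: np.ndarray, K: float, a: float, T: float) -> float:
    """Signed replicon margin of the equilibrium branch at (a, T).

    Positive where the replica-symmetric solution is stable; the margin is
    ``(1 - chi)^2 - a sum_i w_i lam_i beta^2 <sech^4(beta h_i)>`` (the
    standard Almeida-Thouless condition, weighted like the q-equation).  The
    unstable region hugs T = 0.
    """
    w = np.asarray(w, dtype=float)
    if T <= 0:
        return -math.inf          # beta^2 <sech^4> diverges at T = 0
    sol = solve_finite_T(w, K, a, T, branch="retrieval")
    p = sol.params
    beta = 1.0 / T
    _, chi, s4, _ = _finite_T_sums(p.m, p.r, w, a, beta, want_extras=True)
    wp = w[w > 0]
    return (1.0 - chi) ** 2 - a * float(np.sum(wp * (len(w) * wp) * s4))


# --- fully connected limit ----------------------------------------------------

def solve_fully_connected_T0(a: float, init: OrderParameters | None = None) -> SolutionBranch:
    """Classic replica-symmetric storage equations (uniform weights, K -> N).

    m = erf(m / sqrt(2 a r)), chi = sqrt(2/(pi a r)) exp(-m^2/(2 a r)),
    r = 1/(1 - chi)^2.  The retrieval branch exists up to a_c ~ 0.138.
    """
    if a <= 0:
        return SolutionBranch("retrieval", OrderParameters(1.0, 1.0, 0.0, 0.0), free_energy=-0.5)
    m0, r0 = (1.0, 1e-6) if init is None else (init.m, max(init.r, R_FLOOR))

    def step(m, r):
        ar = max(a * r, R_FLOOR)
        m_hat = float(erf(m / math.sqrt(2.0 * ar)))
        chi = math.sqrt(2.0 / (math.pi * ar)) * math.exp(-m * m / (2.0 * ar))
        if chi >= 1.0:
            return m_hat, math.inf
        return m_hat, 1.0 / (1.0 - chi) ** 2

    m, r, res, ok = _iterate(step, m0, r0)
    if ok and m > M_EPS:
        return SolutionBranch("retrieval", OrderParameters(m, 1.0, r, res), free_energy=math.nan)
    # m = 0 branch: chi = sqrt(2/(pi a)) |1 - chi|, the chi < 1 root
    s = math.sqrt(2.0 / (math.pi * a))
    chi = s / (1.0 + s)
    r = 1.0 / (1.0 - chi) ** 2
    return SolutionBranch("spin_glass", OrderParameters(0.0, 1.0, r, 0.0),
                          free_energy=math.nan, converged=ok)
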