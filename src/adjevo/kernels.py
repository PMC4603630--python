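"""Transition kernels of the two-state adjacency gain/loss process.

An adjacency between two genes is a binary character: present (1) or absent
(0).  Along a species-tree branch it evolves under a birth/death (gain/loss)
continuous-time Markov chain whose single shape parameter ``kappa`` is the
ratio of the gain rate to the loss rate.  The generator is normalised so that
one unit of branch length corresponds to one expected gain-or-loss event per
adjacency at stationarity:

    q01 = (kappa + 1) / 2          (gain,  0 -> 1)
    q10 = (kappa + 1) / (2 kappa)  (loss,  1 -> 0)

which gives the total rate ``lam = q01 + q10 = (kappa + 1)^2 / (2 kappa)``
and stationary distribution ``(pi0, pi1) = (1, kappa) / (kappa + 1)``.

Gene duplications complicate the kernel: when a gene carrying an adjacency is
duplicated, the adjacency is transmitted to exactly one of the two copies and
the other copy starts in state 0.  The duplication date is unknown within its
species branch, so the kernel for a duplication-born lineage is the transition
matrix averaged uniformly over the possible dates (``dup1_kernel``).  When
both genes of an adjacency duplicate on the same branch, the two dates are
independent uniforms and the three non-inheriting lineages evolve for the
order statistics of the residual times; the resulting joint table over the
four descendant adjacencies is ``dup2_kernel``.

All closed forms follow from the spectral split ``P(t) = S + E exp(-lam t)``
with ``S`` the rank-one stationary projector and ``E = I - S``.  Nested
Gauss-Legendre quadrature evaluators of the defining integrals are provided
as independent cross-checks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rate_matrix",
    "stationary_distribution",
    "total_rate",
    "transition_matrix",
    "dup1_kernel",
    "dup11_row",
    "dup2_kernel",
    "dup1_kernel_quad",
    "dup11_row_quad",
]

#: below this branch length the exact t -> 0 limits are returned
T_EPS = 1e-9


def _check_kappa(kappa: float) -> float:
    kappa = float(kappa)
    if not np.isfinite(kappa) or kappa <= 0.0:
        raise ValueError(f"kappa must be a positive real, got {kappa!r}")
    return kappa


def total_rate(kappa: float) -> float:
    """Total jump rate ``lam = (kappa+1)^2 / (2 kappa)`` of the chain."""
    kappa = _check_kappa(kappa)
    return (kappa + 1.0) ** 2 / (2.0 * kappa)


def rate_matrix(kappa: float) -> np.ndarray:
    """2x2 generator of the gain/loss process.

    Rows sum to zero, ``q01/q10 == kappa`` and the stationary event flux
    ``pi0*q01 + pi1*q10`` equals one, so branch lengths are expected numbers
    of adjacency events per adjacency.
    """
    kappa = _check_kappa(kappa)
    q01 = (kappa + 1.0) / 2.0
    q10 = (kappa + 1.0) / (2.0 * kappa)
    return np.array([[-q01, q01], [q10, -q10]])


def stationary_distribution(kappa: float) -> np.ndarray:
    """Stationary distribution ``(1, kappa) / (kappa + 1)``."""
    kappa = _check_kappa(kappa)
    return np.array([1.0, kappa]) / (kappa + 1.0)


def _split(kappa: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Spectral split P(t) = S + E exp(-lam t)."""
    pi = stationary_distribution(kappa)
    S = np.tile(pi, (2, 1))
    E = np.eye(2) - S
    return S, E, total_rate(kappa)


def _check_t(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("durations must be finite and non-negative")
    return t


def transition_matrix(kappa: float, t) -> np.ndarray:
    """Transition probabilities ``P(t) = exp(Q t)``.

    ``t`` may be a scalar or an array; the result has shape ``t.shape+(2,2)``
    and each 2x2 table is row-stochastic.
    """
    t = _check_t(t)
    S, E, lam = _split(kappa)
    decay = np.exp(-lam * t)
    return S + decay[..., None, None] * E


def dup1_kernel(kappa: float, t) -> np.ndarray:
    """Date-averaged kernel ``N1(t) = (1/t) int_0^t P(tau) dtau``, row 0.

    Returns ``(N1_00, N1_01)`` (shape ``t.shape+(2,)``): the distribution of
    the state of a duplication-born adjacency at the end of the branch, given
    that it starts absent at the (uniformly distributed) duplication date.
    The ``t -> 0`` limit is ``(1, 0)``.
    """
    t = _check_t(t)
    S, E, lam = _split(kappa)
    x = lam * t
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(x < T_EPS, 1.0, -np.expm1(-x) / np.where(x == 0, 1.0, x))
    N1 = S + phi[..., None, None] * E
    return N1[..., 0, :]


def dup11_row(kappa: float, t: float) -> np.ndarray:
    """Joint kernel of the three non-inheriting lineages of a double duplication.

    When both genes of an adjacency duplicate on the same branch of length
    ``t``, three new adjacency lineages appear, all starting in state 0: one
    at the first duplication (evolving for the larger residual time ``u``)
    and two at the second (each evolving independently for the smaller
    residual time ``v``), where ``(u, v)`` are the decreasing order statistics
    of two independent uniforms on ``(0, t)``.  This returns the (0,0,0)
    source row of

        N11(t) = (2/t^2) int_0^t P(u) (x) int_0^u P(v) (x) P(v) dv du

    as a ``(2, 2, 2)`` tensor over the end states (first-born, second-born,
    second-born), summing to one.  The ``t -> 0`` limit is a point mass on
    (0, 0, 0).
    """
    t = float(_check_t(t))
    if t < T_EPS:
        out = np.zeros((2, 2, 2))
        out[0, 0, 0] = 1.0
        return out
    S, E, lam = _split(kappa)
    if lam * t < 1e-3:
        # the closed form divides O((lam t)^2) differences by t^2: use the
        # cancellation-free quadrature of the positive integrand instead
        return dup11_row_quad(kappa, t)
    A = np.kron(S, S)
    B = (np.kron(S, E) + np.kron(E, S)) / lam
    C = np.kron(E, E) / (2.0 * lam)
    e1 = -np.expm1(-lam * t)          # 1 - exp(-lam t)
    e2 = -np.expm1(-2.0 * lam * t)
    e3 = -np.expm1(-3.0 * lam * t)
    I1 = t * t / 2.0
    I2 = t - e1 / lam
    I3 = t - e2 / (2.0 * lam)
    I4 = (e1 - lam * t * np.exp(-lam * t)) / lam**2
    I5 = e1 / lam - e2 / (2.0 * lam)
    I6 = e1 / lam - e3 / (3.0 * lam)
    N11 = (2.0 / t**2) * (
        np.kron(S, A * I1 + B * I2 + C * I3)
        + np.kron(E, A * I4 + B * I5 + C * I6)
    )
    return N11[0].reshape(2, 2, 2)


def dup2_kernel(kappa: float, t: float) -> np.ndarray:
    """Full slot-ordered table of a double-duplication branch.

    ``out[x, y0, y1, y2, y3]`` is the probability that, starting from
    adjacency state ``x`` at the top of a branch of length ``t`` on which
    both genes duplicate once, the inheriting lineage ends in ``y0``, the
    lineage born at the first duplication ends in ``y1`` and the two lineages
    born at the second duplication end in ``y2`` and ``y3``.  For each ``x``
    the 16 outcome probabilities sum to one.  ``t == 0`` gives a point mass
    on ``(x, 0, 0, 0)``.
    """
    t = float(_check_t(t))
    if t < T_EPS:
        out = np.zeros((2, 2, 2, 2, 2))
        out[0, 0, 0, 0, 0] = 1.0
        out[1, 1, 0, 0, 0] = 1.0
        return out
    P = transition_matrix(kappa, t)
    row = dup11_row(kappa, t)
    return np.einsum("xa,buv->xabuv", P, row)


# ---------------------------------------------------------------------------
# quadrature cross-checks of the defining integrals
# ---------------------------------------------------------------------------

def dup1_kernel_quad(kappa: float, t: float, order: int = 32) -> np.ndarray:
    """Row 0 of ``(1/t) int_0^t P`` by Gauss-Legendre quadrature."""
    t = float(_check_t(t))
    if t < T_EPS:
        return np.array([1.0, 0.0])
    nodes, weights = np.polynomial.legendre.leggauss(order)
    tau = 0.5 * t * (nodes + 1.0)
    P = transition_matrix(kappa, tau)           # (order, 2, 2)
    avg = 0.5 * np.einsum("q,qij->ij", weights, P)
    return avg[0]


def dup11_row_quad(kappa: float, t: float, order: int = 32) -> np.ndarray:
    """(0,0,0) row of ``N11(t)`` by nested Gauss-Legendre quadrature."""
    t = float(_check_t(t))
    if t < T_EPS:
        out = np.zeros((2, 2, 2))
        out[0, 0, 0] = 1.0
        return out
    nodes, weights = np.polynomial.legendre.leggauss(order)
    acc = np.zeros(8)
    for nu, wu in zip(nodes, weights):
        u = 0.5 * t * (nu + 1.0)
        Pu = transition_matrix(kappa, u)
        v = 0.5 * u * (nodes + 1.0)
        Pv = transition_matrix(kappa, v)        # (order, 2, 2)
        PvPv = np.einsum("qij,qkl->qikjl", Pv, Pv).reshape(order, 4, 4)
        inner = 0.5 * u * np.einsum("q,qij->ij", weights, PvPv)
        acc += 0.5 * t * wu * np.kron(Pu, inner)[0]
    return (2.0 / t**2) * acc.reshape(2, 2, 2)
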