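"""Maximum-entropy model selection for compartmental systems.

Two closed-form constructions and one numerical identification procedure:

* Given only the input vector and the mean transit time, the maximum-
  path-entropy system is fully symmetric: all internal rates equal 1, every
  pool's total rate ``lam = d - 1 + 1/ET``, exit rates ``1/ET``.  For
  ``d = 1`` this reduces to the classic result that the exponential
  distribution maximizes entropy at fixed mean.
* Additionally fixing the steady-state stocks breaks the symmetry: the
  maximizer has rates ``B_ij = x*_i / x*_j`` and exit rates ``1 / x*_j``,
  and its path entropy can only be lower.

* When a tracer experiment determines only the transfer-function
  coefficients of a two-pool system — three polynomial constraints on four
  nonnegative parameters ``(B12, B21, z1, z2)`` — the model class is a
  curve of observationally equivalent systems (equifinality).  MaxEnt picks
  the member maximizing the entropy rate per unit time ``theta`` via
  multi-start SLSQP with the three coefficient residuals as equality
  constraints.  (Maximizing the path entropy instead would be unbounded:
  slowing a system down inflates it indefinitely.)
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .system import CompartmentalSystem, validate_system

__all__ = [
    "TransferConstraints",
    "IdentificationResult",
    "maxent_given_input_and_transit",
    "maxent_given_steady_state",
    "gammas_from_parameters",
    "system_from_parameters",
    "identify_max_theta",
]


def maxent_given_input_and_transit(u, ET: float, d: int) -> CompartmentalSystem:
    """Maximum-path-entropy system with given input vector and mean transit time.

    Returns the fully symmetric system: unit internal rates everywhere and
    diagonal ``-lam`` with ``lam = d - 1 + 1/ET``, so each pool's exit rate
    to the environment is ``1/ET`` and the mean transit time is exactly
    ``ET``.
    """
    if ET <= 0:
        raise ValueError("mean transit time must be positive")
    if d < 1:
        raise ValueError("dimension must be >= 1")
    lam = d - 1 + 1.0 / ET
    B = np.ones((d, d)) - np.diag(np.full(d, lam + 1.0))
    u = np.broadcast_to(np.asarray(u, dtype=float), (d,))
    return validate_system(u, B)


def maxent_given_steady_state(u, x_star) -> CompartmentalSystem:
    """Maximum-path-entropy system with given input vector and steady state.

    The maximizer has internal rates ``B_ij = x*_i / x*_j`` and diagonal
    ``-sum_{k != j} x*_k / x*_j - 1 / x*_j`` (exit rate ``1/x*_j``).  Since
    that matrix is determined by ``x*`` alone, the given ``u`` must be
    consistent with it (``-B^{-1} u = x*``); otherwise a ``ValueError`` is
    raised — the constraint set is empty.
    """
    x = np.asarray(x_star, dtype=float)
    if np.any(x <= 0):
        raise ValueError("steady-state stocks must be strictly positive")
    d = x.shape[0]
    B = x[:, None] / x[None, :]
    np.fill_diagonal(B, -(x.sum() - x) / x - 1.0 / x)
    sys = validate_system(u, B)
    if not np.allclose(B @ x + sys.u, 0.0, atol=1e-9 * max(sys.u_norm, 1.0)):
        raise ValueError(
            "u and x_star are incompatible: the maximum-entropy matrix for "
            "these stocks does not balance this input vector"
        )
    return sys


# ---------------------------------------------------------------------------
# Two-pool structural identification from transfer-function coefficients.


@dataclass(frozen=True)
class TransferConstraints:
    """Transfer-function coefficients of the observed two-pool system.

    The transfer function of ``dx/dt = Bx + Au`` observed through
    ``C = (1, 0)`` with ``A = I`` is ``(s + gamma1)/(s^2 + gamma2 s +
    gamma3)`` with

        gamma1 = B12 + z2
        gamma2 = B21 + z1 + B12 + z2
        gamma3 = z1 B12 + z1 z2 + B21 z2.

    Units: gamma1, gamma2 in 1/time, gamma3 in 1/time^2.
    """

    gamma1: float
    gamma2: float
    gamma3: float
    u: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self):
        if min(self.gamma1, self.gamma2, self.gamma3) <= 0:
            raise ValueError("transfer coefficients must be positive")


@dataclass(frozen=True)
class IdentificationResult:
    """Outcome of the multi-start constrained maximization of theta.

    ``local_maxima`` holds every converged feasible local maximum as
    ``(p, theta, residual)`` with ``p = (B12, B21, z1, z2)``; the best one
    (ties broken by smallest l1 norm of p) defines ``best_system``.
    ``feasible`` is False when no start converged to a feasible point.
    """

    feasible: bool
    best_system: CompartmentalSystem | None
    best_p: tuple[float, ...] | None
    best_theta: float
    local_maxima: list = field(default_factory=list)
    n_starts: int = 0
    settings: dict = field(default_factory=dict)


def gammas_from_parameters(p) -> tuple[float, float, float]:
    """Forward map from ``p = (B12, B21, z1, z2)`` to the transfer coefficients."""
    B12, B21, z1, z2 = (float(v) for v in p)
    return (
        B12 + z2,
        B21 + z1 + B12 + z2,
        z1 * B12 + z1 * z2 + B21 * z2,
    )


def system_from_parameters(p, u=(1.0, 0.0)) -> CompartmentalSystem:
    """Build the two-pool system with free parameters ``(B12, B21, z1, z2)``."""
    B12, B21, z1, z2 = (float(v) for v in p)
    B = [[-(B21 + z1), B12], [B21, -(B12 + z2)]]
    return validate_system(u, B, time_unit="yr", mass_unit="gC")


def _phi(x: float) -> float:
    """x (1 - log x), continuously extended to 0 at x = 0."""
    return 0.0 if x <= 0.0 else x * (1.0 - math.log(x))


def _theta_2pool(p, u) -> float:
    """Entropy rate per unit time of the two-pool system, closed form.

    Returns -inf when the parameters do not define a valid open system
    (some total rate or the determinant nonpositive).
    """
    B12, B21, z1, z2 = p
    if min(B12, B21, z1, z2) < 0:
        return -math.inf
    lam1 = B21 + z1
    lam2 = B12 + z2
    det = z1 * B12 + z1 * z2 + B21 * z2  # = lam1 lam2 - B12 B21
    if lam1 <= 0 or lam2 <= 0 or det <= 0:
        return -math.inf
    u1, u2 = u
    un = u1 + u2
    x1 = (lam2 * u1 + B12 * u2) / det
    x2 = (B21 * u1 + lam1 * u2) / det
    h_beta = -(u1 / un) * math.log(u1 / un) if u1 > 0 else 0.0
    if u2 > 0:
        h_beta -= (u2 / un) * math.log(u2 / un)
    h = h_beta + (x1 * (_phi(B21) + _phi(z1)) + x2 * (_phi(B12) + _phi(z2))) / un
    return h / ((x1 + x2) / un)


def identify_max_theta(
    constraints: TransferConstraints,
    mesh: float = 0.5,
    box: float = 5.0,
    rng: np.random.Generator | None = None,
    feasibility_tol: float = 1e-8,
    dedupe_tol: float = 1e-5,
) -> IdentificationResult:
    """Multi-start constrained maximization of theta over the model class.

    SLSQP runs from every point of a grid with side ``mesh`` over
    ``[0, box]^4``; each run maximizes the entropy rate per unit time
    subject to the three transfer-coefficient equality constraints and
    ``p >= 0``.  Converged runs whose residual exceeds ``feasibility_tol``
    are discarded; the surviving local maxima are deduplicated and the best
    is returned (ties within 1e-9 in theta broken by smallest l1 norm).

    ``rng``, when given, shuffles the start order; the result set does not
    depend on it.
    """
    target = np.array([constraints.gamma1, constraints.gamma2, constraints.gamma3])
    u = constraints.u

    def neg_theta(p):
        th = _theta_2pool(p, u)
        return 1e6 if not math.isfinite(th) else -th

    def residuals(p):
        return np.array(gammas_from_parameters(np.maximum(p, 0.0))) - target

    axis = np.arange(0.0, box + mesh / 2, mesh)
    starts = np.array(list(itertools.product(axis, repeat=4)))
    if rng is not None:
        rng.shuffle(starts)

    found: list[tuple[np.ndarray, float, float]] = []
    for x0 in starts:
        res = optimize.minimize(
            neg_theta,
            x0,
            method="SLSQP",
            bounds=[(0.0, None)] * 4,
            constraints=[{"type": "eq", "fun": residuals}],
            options={"maxiter": 200, "ftol": 1e-12},
        )
        p = np.maximum(res.x, 0.0)
        resid = float(np.max(np.abs(residuals(p))))
        th = _theta_2pool(tuple(p), u)
        if resid <= feasibility_tol and math.isfinite(th):
            found.append((p, th, resid))

    # deduplicate: cluster parameter vectors within dedupe_tol (l-inf)
    maxima: list[tuple[np.ndarray, float, float]] = []
    for p, th, resid in found:
        for k, (q, thq, rq) in enumerate(maxima):
            if np.max(np.abs(p - q)) < dedupe_tol:
                if th > thq:
                    maxima[k] = (p, th, resid)
                break
        else:
            maxima.append((p, th, resid))

    settings = {"mesh": mesh, "box": box, "feasibility_tol": feasibility_tol}
    if not maxima:
        return IdentificationResult(
            feasible=False, best_system=None, best_p=None,
            best_theta=-math.inf, local_maxima=[],
            n_starts=len(starts), settings=settings,
        )
    best_theta = max(th for _, th, _ in maxima)
    contenders = [m for m in maxima if m[1] >= best_theta - 1e-9]
    best = min(contenders, key=lambda m: float(np.sum(m[0])))
    records = [
        {"p": tuple(p), "theta": th, "residual": resid}
        for p, th, resid in sorted(maxima, key=lambda m: -m[1])
    ]
    return IdentificationResult(
        feasible=True,
        best_system=system_from_parameters(best[0], u=u),
        best_p=tuple(float(v) for v in best[0]),
        best_theta=float(best[1]),
        local_maxima=records,
        n_starts=len(starts),
        settings=settings,
    )
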