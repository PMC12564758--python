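"""Open compartmental systems in equilibrium and their Markov-chain diagnostics.

A compartmental system is the linear mass-balance ODE

    dx/dt = B x + u,

where ``u >= 0`` is the vector of external input fluxes and ``B`` is a
compartmental matrix: nonnegative off-diagonal rates ``B[i, j]`` (flux rate
from pool *j* to pool *i*), negative diagonal entries (total exit rate of
each pool), and nonpositive column sums whose absolute values ``z[j]`` are
the rates out of the system.  Requiring ``B`` to be invertible makes the
system *open*: every particle eventually leaves, and the journey of a single
particle is an absorbing continuous-time Markov chain with transition-rate
matrix built from ``(B, z)`` and entry distribution ``beta = u / ||u||``.

This module validates systems, computes the equilibrium stocks
``x* = -B^{-1} u``, and derives every jump-chain quantity (jump matrix,
fundamental matrix, expected visits/jumps, transit and occupation times)
that the entropy formulas consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

__all__ = [
    "CompartmentalSystem",
    "EquilibriumDiagnostics",
    "validate_system",
    "steady_state",
    "diagnostics",
    "transit_time_density",
    "transfer_function",
    "impulse_response",
    "read_system_json",
    "write_system_json",
    "read_system_csv",
]

# Relative tolerance below which a (slightly) positive column sum of B is
# treated as exactly zero outflux; columns more positive than this are
# rejected as mass-creating.
_COLSUM_RTOL = 1e-9
# Reciprocal condition number below which B is considered singular (closed).
_SINGULAR_RCOND = 1e-12


class SystemValidationError(ValueError):
    """Raised when (u, B) violate a compartmental-system invariant."""


@dataclass(frozen=True)
class CompartmentalSystem:
    """A validated open compartmental system ``dx/dt = B x + u`` in equilibrium.

    Construct via :func:`validate_system` (or the JSON/CSV readers), which
    enforce the sign and openness invariants.
    """

    u: np.ndarray
    B: np.ndarray
    pool_names: tuple[str, ...] = ()
    time_unit: str = ""
    mass_unit: str = ""

    @property
    def d(self) -> int:
        """Number of pools."""
        return self.u.shape[0]

    @property
    def u_norm(self) -> float:
        """Total input flux ``||u||`` (l1 norm)."""
        return float(np.sum(self.u))

    @property
    def beta(self) -> np.ndarray:
        """Entry distribution ``u / ||u||``."""
        return self.u / self.u_norm

    @property
    def z(self) -> np.ndarray:
        """Exit rates to the environment: negative column sums of B, clamped."""
        z = -self.B.sum(axis=0)
        z[np.abs(z) <= _COLSUM_RTOL * max(np.abs(self.B).max(), 1.0)] = 0.0
        return z

    @property
    def lam(self) -> np.ndarray:
        """Total exit rates ``lambda[j] = -B[j, j]`` of each pool."""
        return -np.diag(self.B)

    def with_rates_scaled(self, c: float) -> "CompartmentalSystem":
        """Return the system with all rates scaled, ``B -> c B`` (u unchanged)."""
        if c <= 0:
            raise ValueError("rate scaling factor must be positive")
        return validate_system(
            self.u, c * self.B, pool_names=self.pool_names or None,
            time_unit=self.time_unit, mass_unit=self.mass_unit,
        )

    def to_dict(self) -> dict:
        return {
            "pools": list(self.pool_names) if self.pool_names
            else [f"pool_{i + 1}" for i in range(self.d)],
            "u": self.u.tolist(),
            "B": self.B.tolist(),
            "time_unit": self.time_unit,
            "mass_unit": self.mass_unit,
        }


@dataclass(frozen=True)
class EquilibriumDiagnostics:
    """Steady-state and jump-chain quantities of a compartmental system.

    Attributes
    ----------
    x_star : equilibrium stocks ``-B^{-1} u`` (mass).
    beta : entry distribution ``u / ||u||``.
    z : exit rates to the environment (1/time).
    lam : total exit rates ``lambda[j] = -B[j, j]`` (1/time).
    jump_matrix : ``(d+1) x d`` column-stochastic one-step transition
        probabilities of the embedded jump chain; row ``d`` is the exit row.
    fundamental : ``(I - P|S)^{-1}``, expected visit counts.
    r : external output fluxes ``z * x_star`` (mass/time).
    ET : mean transit time, total stocks over total fluxes.
    EN_per_pool : expected visits to each pool, ``lambda * x_star / ||u||``.
    EN : total expected number of jumps (including the final exit jump).
    EO : expected occupation times ``x_star / ||u||`` (time).
    """

    x_star: np.ndarray
    beta: np.ndarray
    z: np.ndarray
    lam: np.ndarray
    jump_matrix: np.ndarray
    fundamental: np.ndarray
    r: np.ndarray
    ET: float
    EN_per_pool: np.ndarray
    EN: float
    EO: np.ndarray


def validate_system(
    u,
    B,
    pool_names=None,
    time_unit: str = "",
    mass_unit: str = "",
) -> CompartmentalSystem:
    """Validate ``(u, B)`` and return a :class:`CompartmentalSystem`.

    Raises :class:`SystemValidationError` naming the violated invariant:
    dimension mismatch, negative off-diagonal, nonnegative diagonal,
    mass-creating column sum, singular (closed) B, or zero input.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float)).copy()
    B = np.atleast_2d(np.asarray(B, dtype=float)).copy()
    d = u.shape[0]
    if u.ndim != 1 or B.shape != (d, d):
        raise SystemValidationError(
            f"dimension mismatch: u has length {d} but B has shape {B.shape}"
        )
    if np.any(u < 0):
        raise SystemValidationError("input vector u must be nonnegative")
    if not np.sum(u) > 0:
        raise SystemValidationError("input vector u must have a positive entry")
    off = B - np.diag(np.diag(B))
    if np.any(off < 0):
        i, j = np.argwhere(off < 0)[0]
        raise SystemValidationError(
            f"negative off-diagonal rate B[{i},{j}]={B[i, j]} (rates must be >= 0)"
        )
    if np.any(np.diag(B) >= 0):
        j = int(np.argmax(np.diag(B) >= 0))
        raise SystemValidationError(
            f"diagonal entry B[{j},{j}]={B[j, j]} must be negative"
        )
    colsum = B.sum(axis=0)
    tol = _COLSUM_RTOL * max(np.abs(B).max(), 1.0)
    if np.any(colsum > tol):
        j = int(np.argmax(colsum > tol))
        raise SystemValidationError(
            f"column {j} of B sums to {colsum[j]} > 0: the system would create mass"
        )
    if 1.0 / np.linalg.cond(B) < _SINGULAR_RCOND:
        raise SystemValidationError(
            "B is singular: the system is closed (material never leaves)"
        )
    # Invertible compartmental matrices have all eigenvalues in the open
    # left half-plane; a nonnegative steady state then always exists.
    if pool_names is not None:
        pool_names = tuple(str(n) for n in pool_names)
        if len(pool_names) != d:
            raise SystemValidationError(
                f"{len(pool_names)} pool names given for {d} pools"
            )
    else:
        pool_names = ()
    u.setflags(write=False)
    B.setflags(write=False)
    return CompartmentalSystem(u, B, pool_names, time_unit, mass_unit)


def steady_state(sys: CompartmentalSystem) -> np.ndarray:
    """Equilibrium stocks ``x* = -B^{-1} u``, the unique steady state."""
    x = linalg.solve(sys.B, -sys.u)
    # roundoff can leave tiny negative entries for stiff systems
    return np.where(np.abs(x) < 1e-14 * np.abs(x).max(), 0.0, x)


def diagnostics(sys: CompartmentalSystem) -> EquilibriumDiagnostics:
    """All equilibrium/jump-chain quantities of the one-particle Markov chain.

    The embedded jump chain has one-step probabilities
    ``P[i, j] = B[i, j] / lambda[j]`` for pools ``i != j`` and exit
    probability ``z[j] / lambda[j]``; its fundamental matrix
    ``M = (I - P|S)^{-1}`` counts expected visits.  Expected visits also
    follow from the stocks as ``lambda * x* / ||u||`` — the two routes agree
    and the second is used here.
    """
    d = sys.d
    x_star = steady_state(sys)
    lam = sys.lam
    z = sys.z
    u_norm = sys.u_norm
    P = np.zeros((d + 1, d))
    P[:d, :] = sys.B / lam  # column j divided by lam[j]
    np.fill_diagonal(P[:d, :], 0.0)
    P[d, :] = z / lam
    fundamental = linalg.solve(np.eye(d) - P[:d, :], np.eye(d))
    EN_per_pool = lam * x_star / u_norm
    return EquilibriumDiagnostics(
        x_star=x_star,
        beta=sys.beta,
        z=z,
        lam=lam,
        jump_matrix=P,
        fundamental=fundamental,
        r=z * x_star,
        ET=float(np.sum(x_star) / u_norm),
        EN_per_pool=EN_per_pool,
        EN=float(np.sum(EN_per_pool) + 1.0),
        EO=x_star / u_norm,
    )


def transit_time_density(sys: CompartmentalSystem, t) -> float | np.ndarray:
    """Phase-type transit-time density ``f_T(t) = z^T e^{tB} beta``.

    ``t`` may be a scalar or an array of nonnegative times.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("transit time density is defined for t >= 0 only")
    z, beta = sys.z, sys.beta
    vals = np.array([float(z @ linalg.expm(ti * sys.B) @ beta) for ti in t_arr])
    vals = np.maximum(vals, 0.0)
    return vals if np.ndim(t) else float(vals[0])


def transfer_function(sys: CompartmentalSystem, A, C, s: float) -> np.ndarray:
    """Transfer function ``Psi_hat(s) = C (sI - B)^{-1} A`` at frequency ``s >= 0``.

    ``A`` (d x m) distributes inputs over pools, ``C`` (k x d) selects the
    observed outputs; the result is the Laplace transform at ``s`` of the
    impulse response ``C e^{tB} A``.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if s < 0:
        raise ValueError("transfer function evaluated for s >= 0 only")
    return C @ linalg.solve(s * np.eye(sys.d) - sys.B, A)


def impulse_response(sys: CompartmentalSystem, A, C, t: float) -> np.ndarray:
    """Impulse-response matrix ``Psi(t) = C e^{tB} A``."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if t < 0:
        raise ValueError("impulse response evaluated for t >= 0 only")
    return C @ linalg.expm(t * sys.B) @ A


# ---------------------------------------------------------------------------
# I/O: JSON is the canonical format, CSV a convenience importer.

def read_system_json(path) -> CompartmentalSystem:
    """Read a system from the canonical JSON spec.

    Schema: ``{"pools": [...], "u": [...], "B": [[...]], "time_unit": str,
    "mass_unit": str}`` — pools and units optional.
    """
    with open(path) as fh:
        spec = json.load(fh)
    for key in ("u", "B"):
        if key not in spec:
            raise SystemValidationError(f"system spec is missing required field '{key}'")
    return validate_system(
        spec["u"],
        spec["B"],
        pool_names=spec.get("pools"),
        time_unit=spec.get("time_unit", ""),
        mass_unit=spec.get("mass_unit", ""),
    )


def write_system_json(sys: CompartmentalSystem, path) -> None:
    Path(path).write_text(json.dumps(sys.to_dict(), indent=2) + "\n")


def read_system_csv(path) -> CompartmentalSystem:
    """Read a system from a headerless d x (d+1) CSV: the d columns of B
    followed by the input column u."""
    table = np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=float))
    d, cols = table.shape
    if cols != d + 1:
        raise SystemValidationError(
            f"CSV system table must be d x (d+1); got {d} x {cols}"
        )
    return validate_system(table[:, d], table[:, :d])
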