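"""Reference carbon-cycle systems, simple textbook systems, and fixtures.

Two published box models are provided as parameterized builders:

* the five-pool global terrestrial carbon-cycle model of Emanuel et al.
  (non-woody/woody tree parts, ground vegetation, detritus, active soil
  carbon), with an environmental rate modifier ``xi`` scaling every rate —
  ``xi > 1`` emulates faster cycling under warming;
* the two-pool microbial soil model of Wang et al. (substrate organic
  carbon and microbial biomass), nonlinear in its original form and frozen
  here at its equilibrium, parameterized by the carbon use efficiency
  ``epsilon``.

Also here: the matched one-pool system with identical mean transit time
(the baseline against which multi-pool path entropies are compared), a
catalogue of small canonical systems (serial, parallel, feedback,
symmetric exchange), a seeded random-system generator used as the test
fixture factory, and parameter sweeps collecting every diagnostic and
entropy measure into a tidy table.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import optimize

from .entropy import path_entropy
from .system import CompartmentalSystem, diagnostics, validate_system

__all__ = [
    "WangParameters",
    "emanuel_system",
    "wang_system",
    "wang_unit_exit_epsilon",
    "one_pool_equivalent",
    "one_pool_breakeven_xi",
    "random_system",
    "parameter_sweep",
    "table1_systems",
]

# Exact rational rate coefficients (1/yr) of the five-pool global
# carbon-cycle model; lower triangular, so the model has no feedbacks.
_EMANUEL_B = [
    [Fraction(-77, 37), 0, 0, 0, 0],
    [Fraction(31, 37), Fraction(-31, 452), 0, 0, 0],
    [0, 0, Fraction(-36, 69), 0, 0],
    [Fraction(21, 37), Fraction(15, 452), Fraction(12, 69), Fraction(-48, 81), 0],
    [0, Fraction(2, 452), Fraction(6, 69), Fraction(3, 81), Fraction(-11, 1121)],
]
_EMANUEL_U = [77.0, 0.0, 36.0, 0.0, 0.0]  # PgC / yr
_EMANUEL_POOLS = (
    "non-woody tree parts",
    "woody tree parts",
    "ground vegetation",
    "detritus/decomposers",
    "active soil carbon",
)


def emanuel_system(xi: float = 1.0) -> CompartmentalSystem:
    """Five-pool global carbon-cycle system with rate modifier ``xi``.

    All rates are scaled by ``xi > 0``; the steady state scales by ``1/xi``
    while the jump structure (and hence the expected number of jumps) is
    unchanged.  At ``xi = 1`` the equilibrium stocks are approximately
    (37, 452, 69, 81, 1121) PgC.
    """
    if xi <= 0:
        raise ValueError("rate modifier xi must be positive")
    B = xi * np.array([[float(b) for b in row] for row in _EMANUEL_B])
    return validate_system(
        _EMANUEL_U, B, pool_names=_EMANUEL_POOLS, time_unit="yr", mass_unit="PgC"
    )


@dataclass(frozen=True)
class WangParameters:
    """Parameters of the two-pool microbial soil-carbon model.

    mu_b : microbial biomass turnover rate (1/yr).
    F_NPP : carbon influx into the soil (gC m^-2 yr^-1).
    K_s : half-saturation constant for substrate assimilation (gC m^-2).
    V_s : maximum assimilation rate per unit microbial biomass (1/yr);
        the default approximately reproduces the published equilibrium
        stocks Cs* ~ 12,650 and Cb* ~ 50.36 gC m^-2 at epsilon = 0.39.
    epsilon : carbon use efficiency, the assimilated fraction converted to
        biomass; must exceed mu_b / V_s for a positive substrate stock.
    """

    mu_b: float = 4.38
    F_NPP: float = 345.00
    K_s: float = 53954.83
    V_s: float = 59.13
    epsilon: float = 0.39

    def __post_init__(self):
        for name in ("mu_b", "F_NPP", "K_s", "V_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo = self.mu_b / self.V_s
        if not lo < self.epsilon < 1:
            raise ValueError(
                f"epsilon must lie in ({lo:.4g}, 1) for a positive substrate stock"
            )

    @property
    def Cs_star(self) -> float:
        """Equilibrium substrate carbon (gC m^-2)."""
        return self.K_s / (self.V_s * self.epsilon / self.mu_b - 1.0)

    @property
    def Cb_star(self) -> float:
        """Equilibrium microbial biomass carbon (gC m^-2)."""
        return self.F_NPP / (self.mu_b * (1.0 / self.epsilon - 1.0))

    @property
    def lam_star(self) -> float:
        """Substrate turnover rate Cb* V_s / (Cs* + K_s) at equilibrium (1/yr)."""
        return self.Cb_star * self.V_s / (self.Cs_star + self.K_s)


def wang_system(params: WangParameters | None = None, **kwargs) -> CompartmentalSystem:
    """Two-pool microbial soil model, linearized (frozen) at its equilibrium.

    The substrate pool loses carbon at the equilibrium rate
    ``lam* = Cb* V_s / (Cs* + K_s)``, a fraction ``epsilon`` of which
    becomes microbial biomass while ``1 - epsilon`` is respired out of the
    system; dead biomass returns to the substrate at rate ``mu_b``
    (a feedback).  The frozen system's steady state is exactly
    ``(Cs*, Cb*)``.
    """
    if params is None:
        params = WangParameters(**kwargs)
    lam = params.lam_star
    B = np.array([[-lam, params.mu_b], [params.epsilon * lam, -params.mu_b]])
    return validate_system(
        [params.F_NPP, 0.0],
        B,
        pool_names=("substrate organic carbon", "microbial biomass"),
        time_unit="yr",
        mass_unit="gC m^-2",
    )


def wang_unit_exit_epsilon(base: WangParameters | None = None) -> float:
    """Carbon use efficiency at which the substrate exit rate -B11 equals 1/yr.

    The Poisson entropy rate of the substrate-leaving process is maximal at
    intensity 1, so this efficiency marks the sojourn-uncertainty peak of
    the substrate pool.
    """
    base = base or WangParameters()

    def f(eps):
        p = WangParameters(base.mu_b, base.F_NPP, base.K_s, base.V_s, eps)
        return p.lam_star - 1.0

    lo = base.mu_b / base.V_s + 1e-9
    return float(optimize.brentq(f, lo, 1.0 - 1e-12, xtol=1e-12))


def one_pool_equivalent(sys: CompartmentalSystem) -> CompartmentalSystem:
    """One-pool system with the same total input and mean transit time.

    The single rate is ``1 / E[T]``; its path entropy is ``1 + log E[T]``,
    the uncertainty of the exit time alone.
    """
    ET = diagnostics(sys).ET
    return validate_system(
        [sys.u_norm], [[-1.0 / ET]],
        time_unit=sys.time_unit, mass_unit=sys.mass_unit,
    )


def one_pool_breakeven_xi(
    bracket: tuple[float, float] = (0.5, 10.0)
) -> float:
    """Rate modifier at which the five-pool model's path entropy equals that
    of its matched one-pool system.

    Slow cycling (small ``xi``) makes the detailed multi-pool path harder to
    predict than the single exit time; fast cycling reverses the order.  The
    crossing is found by root-finding on the difference of the two closed
    forms.
    """

    def gap(xi):
        sys = emanuel_system(xi)
        rep = path_entropy(sys)
        return rep.H_path - (1.0 + np.log(rep.ET))

    return float(optimize.brentq(gap, *bracket, xtol=1e-10))


def random_system(
    d: int,
    connectivity: float = 0.5,
    rng: np.random.Generator | None = None,
) -> CompartmentalSystem:
    """Draw a random valid open compartmental system (test-fixture factory).

    Off-diagonal rates are present with probability ``connectivity`` and
    drawn uniform on (0.1, 2); at least one pool gets a strictly positive
    exit rate, and ``u`` has at least one positive entry.  Draws whose B is
    numerically singular are rejected and redrawn.
    """
    if d < 1:
        raise ValueError("dimension must be >= 1")
    if not 0 < connectivity <= 1:
        raise ValueError("connectivity must be in (0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    for _ in range(1000):
        off = rng.uniform(0.1, 2.0, size=(d, d)) * (
            rng.random((d, d)) < connectivity
        )
        np.fill_diagonal(off, 0.0)
        z = rng.uniform(0.1, 1.0, size=d) * (rng.random(d) < 0.7)
        if not z.any():
            z[rng.integers(d)] = rng.uniform(0.1, 1.0)
        B = off - np.diag(off.sum(axis=0) + z)
        if np.any(np.diag(B) >= 0):
            continue
        u = rng.uniform(0.0, 2.0, size=d) * (rng.random(d) < 0.8)
        if not u.any():
            u[rng.integers(d)] = rng.uniform(0.5, 2.0)
        try:
            return validate_system(u, B)
        except ValueError:
            continue
    raise RuntimeError("could not draw a valid random system in 1000 attempts")


def _sweep_row(sys: CompartmentalSystem) -> dict:
    rep = path_entropy(sys)
    one = path_entropy(one_pool_equivalent(sys))
    row = {
        "ET": rep.ET,
        "EN": rep.EN,
        "H_path": rep.H_path,
        "H_jump_part": rep.H_jump_part,
        "H_sojourn_part": rep.H_sojourn_part,
        "theta_time": rep.theta_time,
        "theta_jump": rep.theta_jump,
        "H_system": rep.H_system,
        "onepool_H_path": one.H_path,
        "onepool_theta_time": one.theta_time,
        "onepool_theta_jump": one.theta_jump,
    }
    for i, x in enumerate(diagnostics(sys).x_star, start=1):
        row[f"x_star_{i}"] = x
    return row


def parameter_sweep(builder, values, param_name: str = "value") -> pd.DataFrame:
    """Evaluate ``builder(v)`` over ``values``, one tidy row per value.

    Each row carries every diagnostic and entropy measure plus the matched
    one-pool quantities; builder failures are recorded in an ``error``
    column rather than raised.
    """
    rows = []
    for v in np.asarray(values, dtype=float):
        row = {param_name: float(v)}
        try:
            row.update(_sweep_row(builder(v)))
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - failures become table rows
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def table1_systems(lam: float = 1.0) -> dict[str, CompartmentalSystem]:
    """The catalogue of small canonical systems, keyed by structure name.

    The one-pool system takes the free rate ``lam``; all other systems have
    fixed unit-scale rates.
    """
    build = validate_system
    return {
        "one_pool": build([1.0], [[-lam]]),
        "serial_2": build([1, 0], [[-1, 0], [1, -1]]),
        "parallel_2": build([1, 1], [[-1, 0], [0, -1]]),
        "feedback_2": build([1, 0], [[-1, 0.5], [1, -1]]),
        "exchange_2": build([1, 1], [[-1, 0.5], [0.5, -1]]),
        "serial_3": build([1, 0, 0], [[-1, 0, 0], [1, -1, 0], [0, 1, -1]]),
        "parallel_3": build([1, 1, 1], -np.eye(3)),
    }
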