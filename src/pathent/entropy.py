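"""Shannon path entropy and entropy rates of a single particle's journey.

The random journey of one particle through an open compartmental system in
equilibrium is an absorbing continuous-time Markov chain.  Its full
trajectory — the sequence of visited pools with their sojourn times — has a
well-defined Shannon entropy with the closed form

    H(P) = H(beta)
         + sum_j x*_j/||u|| * [ sum_{i!=j} B_ij (1 - log B_ij)
                                + z_j (1 - log z_j) ],

the *path entropy*.  It mixes the discrete entropy of jump decisions with
the differential entropy of exponential sojourn times, so it can be
negative.  Two further representations of the same number exist: a
continuous-time form weighting Poisson entropy rates by expected occupation
times, and a discrete-time form weighting per-pool jump and sojourn
entropies by expected visit counts.  All three are computed here and used
as mutual cross-checks.

Derived measures:

* entropy rate per unit time  ``theta = H(P) / E[T]``,
* entropy rate per jump       ``theta_J = H(P) / E[N]``,
* system entropy              ``H(M) = ||u|| H(P) = ||x*|| theta``,

the last upscaling the per-particle uncertainty to the macroscopic flux
through the system.  Everywhere the convention ``0 log 0 = 0`` and
``0 (1 - log 0) = 0`` applies: transitions of rate zero carry no
uncertainty.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .system import CompartmentalSystem, diagnostics

__all__ = [
    "EntropyReport",
    "categorical_entropy",
    "exponential_entropy",
    "poisson_entropy_rate",
    "path_entropy",
    "path_entropy_forms",
    "entropy_rates",
    "system_entropy",
]


def _xlogx(x: np.ndarray) -> np.ndarray:
    """x * log(x) elementwise with the 0 log 0 = 0 convention."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def _x_one_minus_logx(x: np.ndarray) -> np.ndarray:
    """x * (1 - log x) elementwise with the 0 * (1 - log 0) = 0 convention."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * (1.0 - np.log(x[pos]))
    return out


def categorical_entropy(p, base: float = math.e) -> float:
    """Shannon entropy ``-sum p_i log p_i`` of a probability vector."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    return float(-_xlogx(p).sum() / math.log(base))


def exponential_entropy(lam: float, base: float = math.e) -> float:
    """Differential entropy ``1 - log(lam)`` of an Exp(lam) sojourn time."""
    if lam <= 0:
        raise ValueError("exponential rate must be positive")
    return (1.0 - math.log(lam)) / math.log(base)


def poisson_entropy_rate(lam: float, base: float = math.e) -> float:
    """Entropy rate ``lam (1 - log lam)`` of a Poisson process of intensity lam.

    Maximal at ``lam = 1``; continuously extended to 0 at ``lam = 0``.
    """
    if lam < 0:
        raise ValueError("Poisson intensity must be nonnegative")
    if lam == 0:
        return 0.0
    return lam * (1.0 - math.log(lam)) / math.log(base)


@dataclass(frozen=True)
class EntropyReport:
    """All entropy measures of one compartmental system, in one log base.

    ``H_path = H_jump_part + H_sojourn_part`` exactly as computed;
    ``H_jump_part`` groups the entry-distribution entropy ``H_beta`` with
    the per-jump destination entropies (the discrete part), while
    ``H_sojourn_part`` collects the differential sojourn-time entropies and
    may be negative.  ``theta_time * ET = theta_jump * EN = H_path``.
    """

    H_path: float
    H_beta: float
    H_jump_part: float
    H_sojourn_part: float
    theta_time: float
    theta_jump: float
    H_system: float
    ET: float
    EN: float
    log_base: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path=None) -> str:
        cols = list(self.to_dict())
        vals = [repr(v) for v in self.to_dict().values()]
        text = ",".join(cols) + "\n" + ",".join(vals) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def path_entropy_forms(sys: CompartmentalSystem) -> tuple[float, float, float]:
    """The three equivalent closed forms of the path entropy, in nats.

    Returns ``(h_flux, h_occupation, h_visits)``:

    * flux form — entry entropy plus stock-weighted ``B_ij (1 - log B_ij)``
      and ``z_j (1 - log z_j)`` terms;
    * occupation form — entry entropy plus occupation-time-weighted Poisson
      entropy rates of every internal and exit transition channel;
    * visit form — entry entropy plus visit-count-weighted per-pool sojourn
      entropies ``1 - log lambda_j`` and jump-destination entropies.

    They agree to numerical precision; the redundancy is kept as an internal
    consistency check.
    """
    dg = diagnostics(sys)
    B, z, lam = sys.B, dg.z, dg.lam
    d = sys.d
    h_beta = float(-_xlogx(dg.beta).sum() + 0.0)

    off = B.copy()
    np.fill_diagonal(off, 0.0)
    # per-pool channel terms sum_{i != j} B_ij (1 - log B_ij) + z_j (1 - log z_j)
    channel = _x_one_minus_logx(off).sum(axis=0) + _x_one_minus_logx(z)

    h_flux = h_beta + float(dg.EO @ channel)
    h_occupation = h_beta + float(
        dg.EO @ np.array(
            [
                sum(poisson_entropy_rate(off[i, j]) for i in range(d))
                + poisson_entropy_rate(z[j])
                for j in range(d)
            ]
        )
    )
    P = dg.jump_matrix
    h_dest = np.array([-_xlogx(P[:, j]).sum() for j in range(d)])
    h_visits = h_beta + float(dg.EN_per_pool @ ((1.0 - np.log(lam)) + h_dest))
    return h_flux, h_occupation, h_visits


def path_entropy(sys: CompartmentalSystem, base: float = math.e) -> EntropyReport:
    """Path entropy of the particle's full trajectory, with its decomposition.

    Returns an :class:`EntropyReport` carrying the path entropy, its split
    into a discrete jump part and a continuous sojourn part, both entropy
    rates, and the macroscopic system entropy, all in ``log base`` units
    (nats by default).
    """
    dg = diagnostics(sys)
    h_flux, _, _ = path_entropy_forms(sys)
    h_beta = float(-_xlogx(dg.beta).sum() + 0.0)
    P = dg.jump_matrix
    h_dest = np.array([-_xlogx(P[:, j]).sum() for j in range(sys.d)])
    h_jump = h_beta + float(dg.EN_per_pool @ h_dest)
    h_sojourn = float(dg.EN_per_pool @ (1.0 - np.log(dg.lam)))
    ln_b = math.log(base)
    h_path = (h_jump + h_sojourn) / ln_b
    return EntropyReport(
        H_path=h_path,
        H_beta=h_beta / ln_b,
        H_jump_part=h_jump / ln_b,
        H_sojourn_part=h_sojourn / ln_b,
        theta_time=h_flux / ln_b / dg.ET,
        theta_jump=h_flux / ln_b / dg.EN,
        H_system=sys.u_norm * h_flux / ln_b,
        ET=dg.ET,
        EN=dg.EN,
        log_base=base,
    )


def entropy_rates(sys: CompartmentalSystem, base: float = math.e) -> tuple[float, float]:
    """``(theta_time, theta_jump)``: path entropy per mean transit time / jump."""
    rep = path_entropy(sys, base=base)
    return rep.theta_time, rep.theta_jump


def system_entropy(sys: CompartmentalSystem, base: float = math.e) -> float:
    """Macroscopic system entropy ``H(M) = ||u|| H(P) = ||x*|| theta``."""
    return path_entropy(sys, base=base).H_system
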