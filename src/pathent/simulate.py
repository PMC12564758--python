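"""Monte-Carlo simulation of single-particle paths through a compartmental system.

Samples trajectories of the absorbing continuous-time Markov chain — enter
through a pool drawn from ``beta``, stay an Exp(lambda_j) sojourn, jump
according to the embedded jump chain, repeat until absorption — and
evaluates the exact path density, so that the sample mean of
``-log f_P(path)`` is an unbiased estimator of the closed-form path
entropy.  These estimates serve as the independent stochastic oracle for
every analytic quantity in the package (path entropy, mean transit time,
jump counts, occupation times, visit counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .system import CompartmentalSystem, diagnostics

__all__ = [
    "ParticlePath",
    "PathStatistics",
    "PathSampler",
    "sample_path",
    "sample_paths",
    "path_log_density",
    "path_statistics",
    "mc_estimates",
    "paths_to_frame",
]

# Guard against effectively-closed user systems: a single path visiting this
# many pools aborts with a diagnostic rather than spinning forever.
MAX_JUMPS = 10_000_000


@dataclass(frozen=True)
class ParticlePath:
    """One completed particle trajectory: visited pools (1-based) and sojourns."""

    pools: tuple[int, ...]
    sojourns: tuple[float, ...]
    absorbed: bool = True

    def __post_init__(self):
        if len(self.pools) != len(self.sojourns) or not self.pools:
            raise ValueError("pools and sojourns must have equal length >= 1")
        if any(t <= 0 for t in self.sojourns):
            raise ValueError("sojourn times must be positive")
        if any(a == b for a, b in zip(self.pools, self.pools[1:])):
            raise ValueError("the jump chain never jumps a pool onto itself")

    @property
    def n_jumps(self) -> int:
        """Total jumps including the final exit jump."""
        return len(self.pools) + 1

    @property
    def transit_time(self) -> float:
        return float(sum(self.sojourns))


@dataclass(frozen=True)
class PathStatistics:
    """Sufficient statistics of one path for the path density.

    ``n_transitions[i, j]`` counts one-step transitions from pool ``j`` to
    pool ``i`` (0-based), with row ``d`` the exit transition; ``occupation``
    is the total time spent in each pool.
    """

    n_transitions: np.ndarray
    occupation: np.ndarray
    n_jumps: int
    transit_time: float


class PathSampler:
    """Reusable sampler with precomputed cumulative jump distributions."""

    def __init__(self, sys: CompartmentalSystem):
        self.sys = sys
        dg = diagnostics(sys)
        self.lam = dg.lam
        self._cum_beta = np.cumsum(dg.beta)
        # column j of jump_matrix: destination distribution (index d = exit)
        self._cum_jump = np.cumsum(dg.jump_matrix, axis=0)
        self.d = sys.d

    def sample(self, rng: np.random.Generator) -> ParticlePath:
        pools: list[int] = []
        sojourns: list[float] = []
        j = int(np.searchsorted(self._cum_beta, rng.random()))
        for _ in range(MAX_JUMPS):
            pools.append(j + 1)
            sojourns.append(rng.exponential(1.0 / self.lam[j]))
            nxt = int(np.searchsorted(self._cum_jump[:, j], rng.random()))
            if nxt >= self.d:
                return ParticlePath(tuple(pools), tuple(sojourns))
            j = nxt
        raise RuntimeError(
            f"particle not absorbed after {MAX_JUMPS} jumps; "
            "the system is numerically near-closed"
        )


def sample_path(sys: CompartmentalSystem, rng: np.random.Generator) -> ParticlePath:
    """Sample one particle path; see :class:`PathSampler` for bulk sampling."""
    return PathSampler(sys).sample(rng)


def sample_paths(
    sys: CompartmentalSystem, n_paths: int, rng: np.random.Generator
) -> list[ParticlePath]:
    sampler = PathSampler(sys)
    return [sampler.sample(rng) for _ in range(n_paths)]


def path_statistics(sys: CompartmentalSystem, path: ParticlePath) -> PathStatistics:
    d = sys.d
    counts = np.zeros((d + 1, d))
    occ = np.zeros(d)
    for a, b, t in zip(path.pools, list(path.pools[1:]) + [d + 1], path.sojourns):
        counts[b - 1, a - 1] += 1
        occ[a - 1] += t
    return PathStatistics(counts, occ, path.n_jumps, path.transit_time)


def path_log_density(sys: CompartmentalSystem, path: ParticlePath) -> float:
    """Log of the exact path density.

    ``log beta_{x1} + sum_k log(rate of jump k) - sum_k lambda_{x_k} t_k``,
    where internal jumps use ``B[i, j]`` and the final exit uses ``z[j]``.
    An infeasible transition (rate zero) yields ``-inf`` with a warning.
    """
    beta, B, z, lam = sys.beta, sys.B, sys.z, sys.lam
    j0 = path.pools[0] - 1
    rates = [beta[j0]]
    for a, b in zip(path.pools, path.pools[1:]):
        rates.append(B[b - 1, a - 1])
    rates.append(z[path.pools[-1] - 1])
    if min(rates) <= 0:
        warnings.warn("path contains a zero-rate transition; density is 0")
        return -np.inf
    log_dens = float(np.sum(np.log(rates)))
    for j, t in zip(path.pools, path.sojourns):
        log_dens -= lam[j - 1] * t
    return log_dens


def mc_estimates(
    sys: CompartmentalSystem, n_paths: int, rng: np.random.Generator
) -> dict:
    """Monte-Carlo estimates with standard errors from ``n_paths`` sampled paths.

    Returns a dict with keys ``H_path``, ``transit_time``, ``n_jumps``,
    ``occupation``, ``visits``, each mapping to ``{"estimate", "se", "n"}``
    (vectors for the per-pool quantities).  The estimators are the sample
    means of ``-log f_P``, the transit time, the jump count, per-pool
    occupation times, and per-pool visit counts.
    """
    if n_paths < 2:
        raise ValueError("need at least 2 paths for a standard error")
    sampler = PathSampler(sys)
    d = sys.d
    neg_logf = np.empty(n_paths)
    transit = np.empty(n_paths)
    jumps = np.empty(n_paths)
    occ = np.zeros((n_paths, d))
    visits = np.zeros((n_paths, d))
    for k in range(n_paths):
        p = sampler.sample(rng)
        neg_logf[k] = -path_log_density(sys, p)
        transit[k] = p.transit_time
        jumps[k] = p.n_jumps
        for j, t in zip(p.pools, p.sojourns):
            occ[k, j - 1] += t
            visits[k, j - 1] += 1

    def _mv(a):
        est = a.mean(axis=0)
        se = a.std(axis=0, ddof=1) / np.sqrt(n_paths)
        if np.ndim(est) == 0:
            return {"estimate": float(est), "se": float(se), "n": n_paths}
        return {"estimate": est.tolist(), "se": se.tolist(), "n": n_paths}

    return {
        "H_path": _mv(neg_logf),
        "transit_time": _mv(transit),
        "n_jumps": _mv(jumps),
        "occupation": _mv(occ),
        "visits": _mv(visits),
    }


def paths_to_frame(paths) -> pd.DataFrame:
    """Tidy export: one row per (path, step) with pool and sojourn."""
    rows = [
        (pid, step, pool, sojourn)
        for pid, p in enumerate(paths)
        for step, (pool, sojourn) in enumerate(zip(p.pools, p.sojourns))
    ]
    return pd.DataFrame(rows, columns=["path_id", "step", "pool", "sojourn"])
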