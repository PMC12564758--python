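# pathent

Information-theoretic analysis of open compartmental systems in
equilibrium: path entropy, entropy rates, and maximum-entropy model
selection.

## The problem

Mass-balanced box models — carbon-cycle reservoir models, tracer-kinetic
and pharmacokinetic systems, nutrient cycles — are linear ODE systems

```
dx/dt = B x + u
```

with nonnegative inputs `u`, nonnegative internal flux rates `B_ij`
(from pool `j` to pool `i`), and exit rates `z_j = -Σ_i B_ij` to the
environment. Such systems are dissipative, so classical dynamical-systems
entropies (metric, topological) vanish and say nothing about how
*uncertain* or *complex* a model is. Yet modelers constantly face
equifinality: structurally different models that fit the same observations
equally well. Which one should be selected?

`pathent` answers this by switching to the one-particle view. In
equilibrium, the journey of a single particle through the system is an
absorbing continuous-time Markov chain: it enters through pool `j` with
probability `β_j = u_j/‖u‖`, stays an `Exp(λ_j)` sojourn (`λ_j = -B_jj`),
jumps according to the embedded jump chain, and eventually exits. The
Shannon entropy of the particle's entire trajectory — visited pools *and*
sojourn times — has a closed form,

```
H(P) = H(β) + Σ_j (x*_j/‖u‖) [ Σ_{i≠j} B_ij (1 − log B_ij) + z_j (1 − log z_j) ],
```

with `x* = −B⁻¹u` the equilibrium stocks. From it derive

* `θ  = H(P)/E[T]` — entropy rate per unit time (`E[T] = ‖x*‖/‖u‖`, the
  mean transit time),
* `θ_J = H(P)/E[N]` — entropy rate per jump (`E[N] = Σ_j λ_j x*_j/‖u‖ + 1`),
* `H(M) = ‖u‖·H(P) = ‖x*‖·θ` — the macroscopic system entropy.

These are proper uncertainty measures, so the maximum-entropy principle
applies: among all systems consistent with given constraints (inputs,
transit time, stocks, or transfer-function coefficients from a tracer
experiment), select the one with maximal entropy — the least-biased model
given the data.

The package provides:

* `pathent.system` — validation, steady states, jump-chain diagnostics,
  phase-type transit-time densities, transfer functions, JSON/CSV I/O;
* `pathent.entropy` — the elementary entropies and the three equivalent
  closed forms of `H(P)`, entropy rates, system entropy;
* `pathent.simulate` — a particle-path sampler and exact path density,
  giving Monte-Carlo estimates that independently check every closed form;
* `pathent.maxent` — closed-form MaxEnt constructions and the multi-start
  constrained identification of the maximum-`θ` model from
  transfer-function coefficients;
* `pathent.models` — a five-pool global carbon-cycle model (with rate
  modifier ξ), a two-pool microbial soil model (with carbon use efficiency
  ε), matched one-pool systems, random fixtures, and parameter sweeps;
* a `pathent` command-line tool (`entropy`, `table1`, `simulate`,
  `identify`, `sweep`, `maxent`).

## Worked example

A two-pool system with a feedback: pool 1 feeds pool 2, half of pool 2's
outflow is recycled back into pool 1, and all input enters pool 1.

```python
import numpy as np
import pathent as pe

system = pe.validate_system(
    u=[1, 0], B=[[-1.0, 0.5], [1.0, -1.0]],
    pool_names=["fast", "slow"], time_unit="yr", mass_unit="gC",
)
print(pe.path_entropy(system).to_json())
```

```json
{
  "H_path": 5.386294361119891,
  "H_beta": 0.0,
  "H_jump_part": 1.3862943611198906,
  "H_sojourn_part": 4.0,
  "theta_time": 1.3465735902799727,
  "theta_jump": 1.0772588722239782,
  "H_system": 5.386294361119891,
  "ET": 4.0,
  "EN": 5.0,
  "log_base": 2.718281828459045
}
```

A particle spends on average 4 years in the system (`ET`) and makes 5
jumps including the final exit (`EN`). The whole-trajectory uncertainty is
`H_path ≈ 5.39` nats — `H = 4 + 2 log 2` exactly — of which
`H_jump_part ≈ 1.39` nats come from discrete jump decisions (the entry is
deterministic, `H_beta = 0`; the only choice is pool 2's recycle-or-exit
coin flips) and `H_sojourn_part = 4` nats from the four expected
unit-rate sojourn times. The same trajectory carries ≈1.35 nats of
uncertainty per year in the system and ≈1.08 nats per jump.

The Monte-Carlo oracle confirms the closed form: with 50,000 sampled
paths,

```python
est = pe.mc_estimates(system, 50_000, np.random.default_rng(7))
print(est["H_path"])
# {'estimate': 5.345046015453283, 'se': 0.018913074649395095, 'n': 50000}
```

the sample mean of `−log f_P` sits within about two standard errors of
5.386.

The same report from the command line:

```sh
pathent entropy --builder table1 --row 4        # this feedback system
pathent table1                                  # the whole catalogue
pathent identify --gamma1 3 --gamma2 5 --gamma3 4
```

The `identify` command solves an equifinality problem: a tracer experiment
on a two-pool system determines only the three transfer-function
coefficients `γ = (3, 5, 4)`, leaving a one-parameter family of
observationally equivalent models; multi-start constrained maximization of
θ selects the member with `θ_max ≈ 1.916` nats/yr.

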