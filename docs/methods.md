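# Methods

## Model class and the one-particle chain

`pathent` works with autonomous linear compartmental systems
`dx/dt = Bx + u` in equilibrium. Validity means: off-diagonal `B_ij ≥ 0`,
diagonal `B_jj < 0`, column sums `≤ 0`, `u ≥ 0` with `‖u‖ > 0`, and `B`
invertible (openness). Invertibility of a compartmental matrix is
equivalent to all eigenvalues having negative real part, which guarantees
a unique nonnegative steady state `x* = −B⁻¹u` and probability-one
absorption of the particle chain. A column sum within `1e-9·max|B|` of
zero is clamped to an exact zero exit rate — float-entered matrices
routinely miss exact balance — while a pool with *total* rate
`λ_j = −B_jj = 0` cannot occur in a valid system (its column would be
identically zero, making `B` singular), so the package rejects it rather
than implementing a special jump-probability branch.

The particle chain is fully determined by `(β, B, z)`: entry distribution
`β = u/‖u‖`, embedded jump probabilities `P_ij = B_ij/λ_j` (exit row
`z_j/λ_j`), sojourn rates `λ_j`. The absorbing state is an internal index
`d+1` and never appears in user-facing pool labels. Expected visits are
computed from the stocks as `λ_j x*_j/‖u‖`; the fundamental matrix
`(I − P|S)⁻¹` is also exposed, and the agreement of the two routes is a
standing test invariant (1e-10 relative).

## Entropy measures

Path entropy is evaluated in three algebraically equivalent closed forms —
the stock-weighted flux form, the occupation-time-weighted Poisson-rate
form, and the visit-count-weighted per-pool form — and their agreement to
1e-10 relative is asserted in tests and logged by the CLI on every run.
The reported decomposition groups the entry-distribution entropy `H(β)`
with the jump-destination entropies into the discrete part, and collects
the `E[N_j](1 − log λ_j)` sojourn terms into the continuous part; the
report also exposes `H(β)` as its own field, so either grouping can be
reconstructed. Zero rates contribute exactly zero to every sum
(`0·log 0 = 0`, `0·(1 − log 0) = 0`), consistent with the support of the
path density; this makes the formulas well defined for sparse matrices.

All internal computation is in nats; a single `base` parameter converts
reports (the default follows the convention of natural logarithms).
Because the sojourn part is a differential entropy, `H_path`,
`H_sojourn_part`, and the rates are not scale-invariant and may be
negative; only comparisons between composite quantities of the same kind
are meaningful, and the package deliberately never compares a discrete
part against a differential part in its reports.

Matrix exponentials (transit-time densities, impulse responses) use
scipy's dense Padé/scaling implementation; no diagonalizability of `B` is
assumed.

## Simulator

The path sampler draws the entry pool from `β`, sojourns from
`Exp(λ_j)`, and destinations from the jump-matrix columns via inverse-CDF
lookup on precomputed cumulative sums. Randomness always flows through an
explicit `numpy.random.Generator`; identical seeds give identical paths
and estimates. A safety cap of 1e7 jumps per path raises a diagnostic for
numerically near-closed systems instead of truncating silently. The exact
path log-density mirrors the sampler (`β`, internal `B_ij` rates, final
`z_j` exit, exponential sojourn factors), so the sample mean of
`−log f_P` is an unbiased estimator of `H(P)`; Monte-Carlo estimates come
with standard errors and are compared with closed forms at a 4-SE band in
the test suite. The simulator exercises exactly the mechanism the closed
forms describe — exponential sojourns, memoryless jumps — so agreement
validates the algebra, not the adequacy of the compartmental idealization
for any real tracer data (real systems may have non-exponential residence
times, time-varying rates, or nonlinearity; only the Wang model's frozen
equilibrium linearization is covered here).

## Reference models

The five-pool global carbon model stores its rate coefficients as exact
rationals (e.g. `31/37`, `−11/1121`), so the ξ=1 steady state reproduces
the published integer stocks to rounding rather than to re-derived
decimals. The rate modifier ξ scales `B` only; the analytic consequence
`H(ξ) = H(1) − (E[N]−1)·log ξ` is used as an oracle for the entropy code.
The two-pool microbial model freezes the nonlinear substrate uptake at
its equilibrium value `λ* = C_b* V_s/(C_s* + K_s)`; the default maximum
assimilation rate `V_s = 59.13 /yr` was chosen (by the model's original
presentation) to approximately reproduce the published stocks, and the
package computes `C_s* ≈ 12,650.8 gC m⁻²` from it rather than hard-coding
the rounded 12,650.00. Feasibility requires `ε > μ_b/V_s` (the substrate
stock diverges at the boundary), enforced at construction.

The random-system generator draws off-diagonal rates uniform on (0.1, 2)
with a connectivity probability, guarantees at least one positive exit
rate and input entry, and rejects numerically singular draws; it is the
fixture factory for all property tests. Its rate scale (order 1) and
dimensions (1–5) cover the regime of the analyzed models; it does not
emulate stiff systems with rate ratios beyond ~1e2, so the 1e-10
representation-agreement tolerance is a statement about that regime.
Sweeps default to log-spaced ξ and linear ε grids bracketing the models'
marked parameter values.

## MaxEnt constructions and identification

The two closed-form constructions are implemented directly: the
input+transit-time maximizer (all off-diagonal rates 1, total rate
`d − 1 + 1/E[T]`) and the input+stocks maximizer (`B_ij = x*_i/x*_j`,
exit rates `1/x*_j`). The stocks construction depends on `x*` alone, so
the given `u` is verified a posteriori against `−B⁻¹u = x*` and rejected
as incompatible otherwise; note that strongly unbalanced stock vectors
admit no nonnegative input at all under this matrix.

The transfer-function identification keeps the three coefficient
equations as explicit equality constraints for SLSQP (residual tolerance
1e-8, nonnegativity bounds) rather than eliminating parameters
analytically — the residual form is uniform in the data, whereas
elimination branches on sign cases. The analytic elimination *is*
implemented in the test suite as an independent oracle (the feasible set
for the two-pool problem is a one-parameter curve), giving a dual-route
check on the optimizer. Starts form a grid of side 0.5 over `[0, 5]⁴`
(14,641 starts, about two minutes with the closed-form two-pool
objective); the mesh is a parameter, coarse grids run in seconds, and
refining the grid can only improve the reported maximum (tested).
Converged maxima are deduplicated at 1e-5 in parameter space; ties within
1e-9 in θ break deterministically toward the smallest parameter l1-norm.
θ — not the path entropy — is maximized because path entropy is unbounded
over the constraint class (slowing a system down inflates it
indefinitely); the θ-optimal model demonstrably does not maximize path
entropy along the feasible curve. The built-in constraint map covers the
two-pool experiment with inputs into pool 1 and observation of pool 1;
the optimizer accepts a general input vector, but no other constraint
maps are built in. Global optimality is not claimed — the feasible set is
not convex in general — only the best local maximum over the grid.

An infeasible constraint set (no nonnegative parameters reproduce the
coefficients) is reported as an explicit infeasible result, not an
exception.

## Problem sizes and numerical choices

Default test-suite scales: 50–200 random fixtures for property checks,
20,000 paths per Monte-Carlo comparison, 500 rejection-sampled
competitors for the dominance check, identification at meshes 0.5–2.5.
Root-finding (break-even ξ, unit-exit-rate ε) uses bracketed Brent
iteration to 1e-10–1e-12. Steady-state accuracy is asserted as
`‖Bx* + u‖ ≤ 1e-10 ‖u‖`.

## Known limitations

Only autonomous systems in equilibrium are covered; non-autonomous or
transient analyses are out of scope. The identification module's
constraint map is specific to the two-pool tracer setup; higher
dimensions would need their own coefficient maps and, realistically,
better-than-brute-force optimization. The stationary recycled process
underlying the per-jump rate's entropy-rate interpretation is not
simulated; only the finite absorbing chain is.
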