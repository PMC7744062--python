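# Methods

## Model

`M` filaments are birth–death chains on non-negative integer lengths
(monomer units), coupled only through the free monomer count. Transitions of
filament `i` at lengths `{L}`:

- growth `L_i → L_i + 1` at rate `r({L}) = k₊(N − Σ_j L_j)` in finite-pool
  mode, or the constant `k₊N` in large-pool mode;
- shrinkage `L_i → L_i − 1` at rate `γ(L_i) = k₋ C(L_i)` for `L_i ≥ 1`,
  where `C` is the depolymerizer concentration profile, linear
  `C0(1 + x/λ)` or exponential `C0 e^{x/λ}`.

Assumptions inherited from the underlying biophysics, and their scope:

- **Adiabatic gradient.** The depolymerizer profile relaxes much faster than
  the filament length changes (photobleaching recovery in seconds–minutes vs
  growth in minutes–hours), so `γ` depends on the current length only; the
  depolymerizer's own stochastic dynamics are not modeled.
- **Linear depolymerization kinetics.** `γ ∝ C(L)` assumes the depolymerizer
  is dilute (binding to the tip is rate limiting). The package applies the
  linear law at every `L`, including where `C(L)` is no longer small; no
  saturating variant is provided.
- **Single rate constant `k₊`.** Assembly is proportional to the free
  monomer count with a length-independent per-monomer rate; motor-limited
  transport effects are excluded.
- **Boundary at zero.** An empty filament cannot shrink: `γ(0) = 0`
  (equivalently `f(0) = 1` in the product form below), making 0 a reflecting
  boundary and the chain irreducible on the simplex `Σ L_i ≤ N`.

## Parameters

| symbol | meaning | units | default / reference value |
|---|---|---|---|
| `Q_N = k₊N/(k₋C0)` | max assembly over baseline disassembly rate | – | 5 (linear), 200 (exponential) |
| `λ` | gradient length scale | monomers | 6.66×10³–6.66×10⁴ (lin), 3.94×10³–3.94×10⁴ (exp) |
| `N` | total monomer pool | monomers | 2×10⁶ |
| `M` | filament count | – | 1 (large pool), 2 (finite pool) |
| monomers/micron | unit convention | 1/μm | 20,000 (2000 dimers/μm/microtubule × 10 microtubules) |

The dimensionless constructor fixes the time unit by `k₋C0 = 1`; stationary
quantities depend only on `(Q_N, λ, N, M, kind)` — any other choice of
`k₋C0` rescales time, which a test asserts by comparing distributions from
the two parameterizations. `λ` is stored as a real number; reference values
like 6.66×10⁴ are not rounded to integers. The plausibility range
`1 < Q_N < 1000` for estimated ratios is enforced as a warning, not an
error.

## Stationary solutions

**Single filament, large pool.** Detailed balance of the birth–death chain
gives `P(L) ∝ Π_{l≤L} r/γ(l)`. The product telescopes to closed form:
`L ln(Q_N λ) − lnΓ(L+λ+1)` (linear; identical to the Gamma-function law up
to normalization) and `L ln Q_N − L(L+1)/(2λ)` (exponential; exactly a
Gaussian restricted to integers, mean `λ ln Q_N − ½`, variance `λ`). The
half-monomer offset is a convention — mean versus mode of the continuous
envelope differ by less than one monomer — and is kept in the Gaussian
closed form.

**M filaments, finite pool.** Every transition is reversible, so the joint
chain satisfies detailed balance with

`P(L₁..L_M) ∝ k₊^{ΣL} / (Π_i f(L_i) · (N − ΣL)!)`, `f(L) = Π_{l≤L} γ(l)`.

The placement of `f` and the factorial in the denominator is fixed by the
one-step balance identity
`γ(L_i+1) P(.., L_i+1, ..) = k₊(N − ΣL) P(.., L_i, ..)`,
which the implementation reproduces exactly in log space and which is locked
in by a brute-force oracle (below). For the exponential kind the per-monomer
ratio `q = k₊/(k₋C0) = Q_N/N` appears in the weights; the implementation
works with `ln k₊` directly, so no separate symbol is exposed.

**Moments.** No closed-form moments are used for reported values: means,
variances and the noise are obtained by direct summation over the enumerated
support. The closed-form approximations (`⟨L⟩ ≈ (Q_N−1)λ`, `Var ≈ Q_Nλ`
linear; `⟨L⟩ ≈ λ ln Q_N − ½`, `Var = λ` exponential) are provided separately
and agree with the exact sums to ~0.5% at the reference parameters.

**Noise.** "Noise" throughout is the coefficient of variation
`√Var(L)/⟨L⟩`. This is the only reading consistent with the `⟨L⟩^{−1/2}`
scaling law and with the reference values ~0.007 at `Q_N = 5`,
`λ = 6.66×10³`; it is recorded here because the bare ratio `Var/⟨L⟩` is a
plausible misreading.

## Numerical choices

- **Log space everywhere.** `Γ(L+λ+1)` at `L ~ 10⁵` overflows float64 by
  orders of magnitude; all weights are `lnΓ`-based and normalized by
  log-sum-exp, followed by an exact renormalization over the enumerated
  support (so probabilities sum to 1 to machine precision).
- **Support windows.** 1-D: start at the deterministic balance point and
  expand symmetrically until the edge weights drop below `tail_tol`
  (default 10⁻¹²) times the peak; the omitted mass is estimated from the
  geometric decay of the edge ratios and reported as `truncation_mass`.
  2-D (`M = 2`): same criterion, but the expansion probes only the four
  boundary lines of the window (1-D evaluations), and the final matrix is
  filled in row blocks with a streaming log-sum-exp, so peak memory is one
  float64 matrix of the window (~0.6 GB at the largest reference case).
  Windows are clipped to `L ≥ 0` and `ΣL ≤ N`; exact joint enumeration is
  deliberately limited to `M = 2` (the combinatorial box explodes beyond
  that; the product-form weight itself is exposed for any `M`, and the
  simulator covers `M > 2`).
- **Floating-point limits.** At cellular scale the log-weights contain `lnΓ`
  terms of magnitude ~10⁷ whose few-ulp rounding leaves one-step
  detailed-balance residuals of order 10⁻⁹ in log space; on small pools
  (N ≤ 60, where the oracle runs) residuals are below 10⁻¹⁰. Tests assert
  at both scales accordingly.
- **Steady-state solvers.** Linear kind: closed form
  `λ(Q_N−1)N/(N + M Q_N λ)`. Exponential kind: `ln`-transformed bisection
  (Brent) of `Q_N(1 − ML/N) = e^{L/λ}` on `[0, N/M]` to 10⁻⁶ monomers.
  `Q_N < 1` raises `NoSteadyStateError`; `Q_N = 1` returns 0.
- **Oracle.** For `N ≤ 60` the full generator over all `(N+1)(N+2)/2`
  states (M = 2) is assembled from the same elementary rate functions and
  its stationary vector obtained by replacing one balance equation with the
  normalization constraint — robust for reversible generators without
  eigensolvers. Product form vs oracle agrees to < 10⁻⁸ across both
  gradient kinds, `Q_N ∈ {0.5, 2, 5}`, `λ ∈ {2..10}`.

## Stochastic simulator

Exact SSA: per event, one exponential waiting time at the total rate
`M·k₊·(free pool) + Σγ(L_i)` and one categorical channel draw — exactly two
uniforms per event from a single Mersenne-Twister stream seeded once per
simulation, so trajectories are reproducible given (model, seed, backend).
The inner loop is numba-jitted (~10⁷ events/s); a pure-Python fallback runs
the identical algorithm when numba is absent (trajectories agree between
backends in distribution, not draw-for-draw).

- **Stationary sampling** is time-grid based (state held at fixed times
  after burn-in), not per-event, to avoid event-frequency bias. Default
  burn-in is 10 heuristic relaxation times `λ·max(1, 1/(Q_N−1))`; thinning
  defaults to one fifth of one. These are heuristics — tests that need
  quantitative agreement start at the balance point and estimate Monte-Carlo
  standard errors by batch means rather than trusting the defaults.
- **Severing experiment** (`M = 2`, finite pool): equilibrate, set
  `L₁ ← 0`, continue on a fixed grid, average over replicates (seeds spawned
  from a root seed). By default the severed monomers are **discarded** — the
  flagellum is physically lost, so the effective pool shrinks by the pre-cut
  length — matching the observed sequence: the intact filament shrinks while
  the stump regrows, the lengths equalize, and the common final length
  undershoots the pre-cut value. `discard_severed=False` returns the
  monomers instead (then the original steady state is recovered), provided
  for sensitivity analysis since the physical fate of severed material is
  an experimental question.
- **Mean-field ODE** `dL_i/dt = r({L}) − γ(L_i)` (LSODA, lengths clamped at
  zero) shares its fixed points with the steady-state solvers and is used
  for qualitative checks such as the equalization of asymmetric initial
  lengths.

## What a green test does and does not establish

The SSA is validated against exact enumeration (small pools: moments within
3 batch-mean standard errors; total-variation distance of histograms < 0.05)
and against the analytic distributions at reference scale (moments within
3 SE). Total-variation comparisons **at reference scale** are computationally
out of reach — with λ ~ 10⁴ the chain's relaxation time is ~λ time units and
a TV < 0.05 test would need ~10¹¹ events — so distribution-shape agreement
is established on scaled-down models and only moment agreement at full
scale. Green simulator tests therefore certify the dynamics on small systems
plus unbiasedness of the first two moments at scale, not the full law at
scale.

## Observed values worth recording

- At `Q_N = 5`, `λl = 6.66×10³`, `N = 2×10⁶`: exact large-pool noise
  0.006850; exact finite-pool (M = 2) marginal noise 0.006930. The pool
  coupling lowers the mean (−3.2%) slightly more than the standard deviation
  (−2.1%), so the CV rises marginally — both values round to 0.007 at one
  significant digit. A Laplace (Gaussian-curvature) expansion of the joint
  weight reproduces both numbers independently.
- The fitted log-noise vs log-mean slope over `Q_N ∈ {5, 50, 500}` at fixed
  `λl`, using exact moments, is −0.523, not −0.500: the
  `√(Q_Nλ)/((Q_N−1)λ)` law only approaches the asymptotic −½ exponent once
  `Q_N ≫ 1`, and `Q_N = 5` is not yet in that regime. Varying `λ` at fixed
  `Q_N` the exponent is exactly −½.

## Known limitations

- Depolymerizer transport is not spatially resolved; gradients are given,
  not derived, and time-dependent or saturating gradients are out of scope.
- Exact joint enumeration refuses `M > 2`; per-filament parameter
  heterogeneity (different `λ` or `C0` per filament) is supported by the
  product form in principle but is not part of the tested surface.
- Measurement (diffraction-limit) noise is not modeled; computed CVs are
  intrinsic to the dynamics and are roughly two orders of magnitude below
  reported experimental length fluctuations.
- First-passage and time-dependent distributional analytics are not
  provided; the simulator is the tool for those questions.
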