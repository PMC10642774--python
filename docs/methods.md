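# Methods

## Model class and assumptions

All computations assume linear compartmental dynamics
`dx/dt = u(t) + B(t) x`: non-negative off-diagonal entries of `B`
(transfer rates between pools), non-positive diagonal, non-positive
column sums whose magnitude minus the internal transfers is each pool's
release rate `z_j ≥ 0`, and non-negative inputs `u`.  Linearity is what
makes ages tractable: each carbon atom moves independently through the
continuous-time Markov chain whose sub-generator is `B`, so the
equilibrium transit time is the absorption time of that chain — a
phase-type distribution with density `f_T(τ) = −1ᵀB e^{τB} u/‖u‖`,
moments `E[T] = 1ᵀ(−B⁻¹)u/‖u‖ = ‖x*‖/‖u‖` and
`E[T²] = 2·1ᵀB⁻²u/‖u‖`, and CDF `1 − 1ᵀe^{τB}u/‖u‖`.  Nonlinear or
state-dependent models are out of scope; a model with feedbacks must be
linearized along a solved trajectory before using this package.

The per-pool age densities are normalized pool by pool,
`(e^{aB}u)_i / x*_i`, so that each component is a proper pdf; the
alternative global normalization by `‖u‖` makes the components integrate
to pool-dependent constants and breaks the downstream mass-density
bookkeeping, so it is not used.

## Backward transit times out of equilibrium

A run starts from the equilibrium `x* = −B⁻¹u` of a base system at
`t0`.  The age-resolved mass density at evaluation time `t` is

- `m(t,a) = Φ(t, t−a) u(t−a)` for `a < t−t0` (carbon that entered
  during the run), and
- `m(t,a) = Φ(t, t0) e^{(a−(t−t0))B} u` for `a ≥ t−t0` — the
  equilibrium age structure of the carbon already present at `t0`,
  transported forward.  This branch integrates exactly to `Φ(t,t0)x*`,
  so total mass is conserved by construction.

The respiration-age density is `r(t,a) = z(t)ᵀ m(t,a)`; integrated over
age it equals ecosystem respiration `Re(t) = z(t)ᵀ x(t)`.

Numerically we never form `Φ(t,s)` for large spans: its fast modes
underflow (for the five-pool model, `e^{−2.08·170}` ≈ 10⁻¹⁵⁴), making
inversion-based evaluation of `Φ(t, t−a)` hopeless.  Instead the row
vector `v(a) = z(t)ᵀ Φ(t, t−a)` is propagated through the n-dimensional
linear ODE `dv/da = v B(t−a)`, `v(0) = z(t)` (LSODA, rtol 1e-10,
atol 1e-12), giving `r(t,a) = v(a)·u(t−a)` directly; `v` is bounded and
non-negative, so the computation is well conditioned.  The same routine
with unit weights yields the age density of the stored carbon and hence
the mean system age `E_A(t)`.  `Φ(t,s)` itself (for the cocycle and
positivity checks, and the annual cache) is obtained by solving the
matrix ODE `dΦ/dt = B(t)Φ` forward; off-grid times are reached by
solving the short ODE from the nearest cached node rather than by
interpolating matrices, which can violate positivity.

### Age grids and tails

Summaries use a fixed age grid: spacing `min(0.02, 0.04/k_max)` yr below
5 yr (with `k_max` the fastest pool rate — trapezoid error grows like
`(h·k)²`), 0.1 yr to 30 yr, 0.5 yr to 150 yr, 2 yr to 400 yr, 10 yr
beyond; the maximum age is doubled until the truncated transit-time mass
is below `tail_tol = 1e-4`.  The density beyond the grid maximum is not
discarded: its mass and first moment are carried analytically from the
equilibrium tail (`∫ e^{sB} ds = −B⁻¹`, `∫ s e^{sB} ds = B⁻²`), so
means are exact up to quadrature on the grid, not truncated.  If a
caller's grid ends before the run length, the remaining history is
integrated on an auxiliary 0.05-yr quadrature grid.

Equilibrium quantiles are computed by bracketed root-finding (brentq)
on the closed-form CDF — grid-free and exact to 1e-10.  This matters:
truncating the density at a finite maximum age and renormalizing biases
upper quantiles low (for the five-pool model, a 430-yr cutoff moves the
95 % quantile from 76.98 to 74.5 yr and a 600-yr cutoff moves the mean
from 15.58 to 15.38 yr), which is why the package reports the exact
values.  Non-autonomous quantiles, which have no closed form, come from
linear interpolation of the trapezoidal CDF on the grid above.

## The five-pool global-change experiments

The base system is the five-pool terrestrial biosphere (non-woody tree
parts, woody tree parts, ground vegetation, detritus/decomposers,
active soil carbon; GPP 113 PgC yr⁻¹ split 77/36 between the two
photosynthesizing pools; equilibrium stocks 37/452/69/81/1121 PgC).
Forcing over 1850–2020:

- CO₂ `xa(t)` rises from 285 ppm along a logistic-like curve
  (rate 0.0305 yr⁻¹, saturation 2134 ppm);
- temperature `Ts(t) = 15 + (4.5/ln 2)·ln(xa/285)` °C — an equilibrium
  climate sensitivity of 4.5 °C per CO₂ doubling;
- inputs `u(t) = (1 + 2.5 β(t) ln(xa/285)) u` with the
  CO₂-fertilization factor
  `β = 3ρxaΓ / ((ρxa − Γ)(ρxa + 2Γ))`, `ρ = 0.65`, and the
  compensation-point quadratic
  `Γ(Ts) = 42.7 + 1.68(Ts−25) + 0.012(Ts−25)²` ppm;
- rates `B(t) = ξ(t) B` with `ξ = 2^{0.1·Ts − 1.5}` (Q10 = 2, equal to
  1 at 15 °C), scaling all cycling and release rates uniformly, which
  preserves the compartmental property.

Three experiments: `co2` (fertilization only, `ξ ≡ 1`), `temp` (rate
modifier only, `u` constant) and `both`.  A deliberate design choice:
the productivity channel is driven by CO₂ alone, so `u(t)` always
evaluates `β/Γ` at the temperature implied by the CO₂ curve — the `co2`
and `both` runs therefore share one GPP trajectory, and "constant
temperature" means the cycling rates are unaffected (`ξ ≡ 1`), not that
the weak temperature dependence inside `β` is frozen.  Conversely
"constant CO₂" freezes `xa` inside `u(t)` only, while `ξ` still follows
the warming — otherwise that experiment would be a no-op.  Percent
changes are reported as `100·(v(2020) − v(1850))/v(1850)` (signed);
the acceptance script converts them to the magnitude of the named
decrease or increase.

Output is annual; internal solver steps are adaptive (LSODA, rtol 1e-8,
atol 1e-10 for trajectories — the ~200× stiffness ratio between the
fastest (2.08 yr⁻¹) and slowest (0.0098 yr⁻¹) pools is mild but real).

## Radiocarbon

The ¹⁴C sub-system shares the transport operator and adds decay:
`dx14/dt = u(t)F_atm(t) + (B(t) − λI)x14`, `λ = ln 2/5730 yr⁻¹`,
`F_atm = 1 + Δ¹⁴C_atm/1000`.  Spin-up is analytic — equilibrium with
the atmosphere pinned at the curve's earliest value — rather than a
long transient.  No isotopic fractionation is applied on uptake or
respiration: Δ¹⁴C histories are conventionally fractionation-corrected,
so fractionation cancels by definition of the reporting scale.  Pool
and respired signatures are `1000·(x14/x − 1)` with flux weights
`z(t)` for the respired value.  The solver was cross-validated against
an independent identity: respired Δ¹⁴C equals the BTT-density-weighted,
decay-corrected atmospheric label at entry time,
`F_resp(t) = ∫ p_b(t,a) F_atm(t−a) e^{−λa} da`; the two routes agree to
~0.003 ‰ and the identity is kept as a test.

## Synthetic data

Two generators make every stage testable offline:

- **Random systems** — per-pool loss rates log-uniform over half a
  decade around `rate_scale`, each off-diagonal transfer present with
  probability `connectivity`, Dirichlet split of each pool's loss
  between transfers and release, inputs positive somewhere; systems are
  redrawn (bounded retries) until structurally valid and invertible.
- **Synthetic bomb curve** — a Graven-style atmospheric Δ¹⁴C history:
  0 ‰ plateau before 1950 (optional Suess-effect ramp), a smooth rise
  over 9 yr to 700 ‰ at 1964, then exponential relaxation at
  0.06 yr⁻¹.  The defaults mimic the Northern-Hemisphere annual means
  in shape and scale.

What the synthetic data do *not* emulate: real curves carry seasonal
structure, hemispheric offsets and the post-1990s fossil-fuel dilution
trend; random systems have no mass-balance closure with observations.
Tests passing on them demonstrate the correctness of the machinery, not
the realism of any particular ecosystem parameterization.

The **particle oracle** is deliberately independent of the analytic
code: atoms enter in pools drawn proportional to `u`, hold for
exponential times at the pool's total loss rate, jump or exit with the
column-wise rate ratios, and the empirical exit-age distribution is
compared with the analytic CDF by Kolmogorov–Smirnov tests at fixed
seeds.  Time-dependent systems are simulated on piecewise-constant
regimes (forcing evaluated at regime midpoints, holding times capped at
regime edges) — exact when the forcing is itself piecewise constant on
the regime grid, which is how the oracle tests are set up; entries
follow the correspondingly discretized inhomogeneous Poisson process of
rate `‖u(t)‖`, started long before any output window so the
pre-existing carbon is represented.

## Degenerate inputs and tie-breaks

Singular `B` (closed loops with no release) is rejected wherever a
steady state or moment is required, with the defect named.  Pools with
zero equilibrium stock make the per-pool age pdf undefined and raise.
Aggregation of transit-time distributions across sub-systems requires
identical age grids and evaluation times — no silent resampling, which
can shift medians at the 0.1-yr scale.  Quantile levels outside (0,1)
and evaluation times before `t0` raise.  Tiny negative densities from
round-off in repeated matrix-exponential steps are clamped to zero; the
recursive one-step accumulation is reset against a direct
scaling-and-squaring evaluation every 50 steps.

## Known limitations

- The framework is linear; the forcing functions enter as prescribed
  time dependencies, not as state feedbacks.
- The five-pool experiments are aspatial; the aggregation operator
  (summing respiration-age densities over "cells" on a shared grid)
  supports gridded use, but no gridded model ships with the package.
- The temperature modifier scales all rates uniformly; differential
  pool sensitivities (e.g. soil vs foliage Q10) are not represented.
- Radiocarbon results with the synthetic bomb curve reproduce the
  qualitative behaviour of the tracer (delayed, damped respired spike;
  scenario-minus-equilibrium sign changes); quantitative Δ¹⁴C levels
  require an observed atmospheric record supplied as CSV.
- Non-autonomous quantiles inherit the age-grid resolution (0.02 yr at
  young ages by default); medians are accurate to roughly that scale.
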