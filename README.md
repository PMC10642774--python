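# ctransit

Transit-time and age distributions of carbon in compartmental ecosystem
models: equilibrium closed forms, time-dependent backward transit times
under global-change forcing, radiocarbon (Δ¹⁴C) signatures, and
homogeneity diagnostics — built around the classic five-pool model of
the pre-industrial terrestrial biosphere.

## The problem

Terrestrial ecosystems take up carbon by photosynthesis and return it by
respiration.  How long an individual carbon atom spends inside the
biosphere — its *transit time* — controls how effective the land sink is
at keeping carbon out of the atmosphere.  For a linear compartmental
model

```
dx/dt = u(t) + B(t) x,
```

with pool contents `x` (PgC), inputs `u ≥ 0` (PgC yr⁻¹) and a
compartmental matrix `B` (yr⁻¹), the equilibrium transit time is
phase-type distributed with density

```
f_T(τ) = −1ᵀ B e^{τB} u / ‖u‖,
```

and the stored carbon has the system-age density
`f_A(a) = −1ᵀ B e^{aB} x*/‖x*‖` with `x* = −B⁻¹u`.  Out of equilibrium,
the *backward* transit time — the age of the carbon in today's
respiration flux — follows from the age-resolved mass density
`m(t,a) = Φ(t, t−a) u(t−a)` (with the equilibrium age structure carried
over for carbon already present at the start), weighted by the release
rates `z(t)ᵀ = −1ᵀB(t)`:

```
r(t,a) = z(t)ᵀ m(t,a)        (PgC yr⁻¹ per yr of age).
```

`ctransit` computes these distributions exactly (matrix exponentials and
root-finding on the closed-form CDF at equilibrium; back-propagated
state-transition weights for the non-autonomous case), together with
means, medians, quantiles, the homogeneity ratios
`h = m_b/(ln 2 · E_b)` and `h′ = E_b/E_A`, and ¹⁴C tracer dynamics
driven by an atmospheric Δ¹⁴C history.  A seeded particle oracle
(continuous-time Markov chain simulation of individual atoms) provides
an independent cross-check of every analytic result.

## Worked example

The five-pool model (non-woody tree parts, woody tree parts, ground
vegetation, detritus/decomposers, active soil carbon; GPP 113 PgC yr⁻¹,
stocks 1760 PgC) at equilibrium:

```
$ ctransit equilibrium --out demo_eq
median 2.29 yr, q95 76.98 yr
$ cat demo_eq/summary.json
{
  "total_stock_PgC": 1760.0,
  "gpp_PgC_per_yr": 113.0,
  "mean_transit_time_yr": 15.575221238938052,
  "sd_transit_time_yr": 45.01182760673106,
  "median_transit_time_yr": 2.29338064264349,
  "q95_transit_time_yr": 76.97913030028313,
  "h": 0.21243029740989391
}
```

Half of the carbon fixed by photosynthesis is respired within 2.3 years,
yet the mean transit time is 15.6 years with a standard deviation of
45 years: the distribution has a long tail of old soil carbon, and the
homogeneity ratio h ≈ 0.21 (1 would be a one-pool, exponential system)
says the mean is nearly five times ln 2 times the median.

Running the combined CO₂-fertilization + warming experiment over
1850–2020 (here with an 85-yr output step; drop `--step` for annual
output):

```
$ ctransit scenarios --which both --out demo_runs --step 85
both: gpp +33.6%, re +33.0%, total_stock +5.8%, mean_btt -13.1%, median_btt -19.0%, q95 -16.9%
```

GPP rises by a third; the mean, median and 95 % quantile of the backward
transit time all *fall* (by 13, 19 and 17 %): the extra productivity
floods the respiration flux with young carbon and outweighs the
temperature-driven release of old carbon.  Running `--which co2` and
`--which temp` separates the two effects: fertilization alone shortens
transit times (mean −15 %), warming alone lengthens the mean (+3 %)
while still shortening the median (−12 %).

The same machinery works for any user-defined system (`ctransit synth
--what system`, YAML/JSON round-trip via `ctransit.io`), and
`ctransit radiocarbon --synthetic-curve` runs the ¹⁴C tracer against a
built-in Graven-style bomb curve with no external data.

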