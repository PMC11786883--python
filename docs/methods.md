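# Methods

## Model

`nutrispan` projects the life-expectancy (LE) effect of a sustained diet
change with a proportional-hazards adjustment of a period life table.  The
inputs are (i) an age/sex-specific all-cause mortality schedule, (ii) one
dose–response relative-risk curve per food group, and (iii) two diet
patterns (baseline and target) in grams/day for 14 food groups.

Assumptions, in the order they bite:

1. **Period, not cohort.** The baseline schedule is held fixed; no secular
   mortality decline, no morbidity, no competing non-fatal outcomes.  The
   projection is a population-level "what if", not a personal forecast.
2. **Proportional hazards.** A diet change multiplies the all-cause hazard
   by the same factor at every age past the change age.  There is no
   age-specific attenuation of relative risks at the oldest ages; this is
   a documented simplification.
3. **Multiplicative combination with overlap attenuation.** Per-group log
   hazard ratios add (risks multiply); the sum is multiplied by a single
   overlap weight `overlap_w ∈ [0, 1]` because food-group effects are
   correlated (changing one group partly captures the effect of another).
   The functional form — one multiplicative attenuation of the summed
   log-HR — is this package's choice; the weight is surfaced in the
   scenario config so an externally estimated value can be dropped in.
   Default 1.0 (no attenuation).
4. **Linear phase-in.** The fraction of the full log-effect realized `t`
   years after the change is `f(t) = f₀ + (1 − f₀)·min(t/L, 1)` with lag
   `L = 10` y and initial fraction `f₀ = 0` by default.  The ramp shape and
   defaults are choices; both are configurable.  The discrete pipeline
   evaluates `f` at the start of each year of age.

## Life-table conventions

Single-year ages 0..105; `q(x) = 1 − exp(−m(x))` (constant hazard within
the year); deaths mid-year (`a(x) = 0.5`, so `L = l − 0.5·d`); open-ended
closure with `L = l/m` at the top age, which fails loudly if the closure
rate is zero.  Age bands in input files are expanded by holding the rate
constant within the band — the simplest defensible rule.  Against a
continuous-time integrator these conventions reproduce constant-hazard LE
to ~0.01% and scenario gains to well under 1%.

## Dose–response curves

Curves are gridded RR values with pointwise 95% CIs, normalized to RR = 1
at a reference intake.  Interpolation is piecewise-linear on the log-RR
scale (ratio semantics); outside the grid the terminal values are clamped
rather than extrapolated — conservative, and recommendation targets are
intended to sit within evidence range.  Monte-Carlo sampling draws one
standard-normal z per curve and shifts every grid point by `z·SD(x)` with
`SD(x) = (ln RR_hi − ln RR_lo)/(2·1.96)`: perfectly correlated within a
curve (adjacent doses come from the same studies), independent across
curves.  Evidence grades are carried as metadata only; no down-weighting.

## Decomposition

A group's raw contribution is the gain from changing it alone (all other
groups at baseline) under the same lag and overlap settings.  Because the
life table is non-linear, raw contributions do not sum exactly to the
joint gain, so they are rescaled by a common factor to conserve it; shares
are percentages of the absolute rescaled contributions.  With full overlap
weight, zero lag and log-linear curves the solo log-HRs sum exactly and the
rescaling is the identity.  When the joint gain is exactly zero, shares are
undefined and reported empty with a warning.

## Uncertainty

Intervals are empirical central percentiles (default 95%) over Monte-Carlo
draws, robust to the skew that log-scale hazard ratios induce; the central
estimate is always the point-curve projection, so the interval never moves
the headline number.  The energy a diet leaves uncategorized (the share of
the estimated requirement not covered by the 14 groups) carries no central
effect but widens the interval: each draw adds a uniform log-HR offset in
`±(fraction × κ)` per diet, with sensitivity constant `κ = 0.1` by default
and an off switch (`κ = 0` or the toggle).  The uniform-bounded mechanism
and default κ are this package's choices; only the qualitative widening is
externally motivated.  Fewer than 40 draws for a 95% interval triggers a
percentile-instability warning.

## Diet data and energy accounting

Canonical intakes are fresh/prepared weight: dry whole grain × 3.33, dry
legumes × 2.5, cheese × 7.5 into milk equivalents, applied at ingest only.
The packaged patterns (8 countries × 2 sexes, plus feasible and
full-potential recommendation targets) are transcribed survey averages; a
provenance column marks rows whose transcription was ambiguous (the
uncategorized-energy percentages) and `unchanged` target cells (refined
grains, white meat) that inherit the baseline intake when a scenario is
built.  The fixture file carries a SHA-256 checksum verified at load.
Energy densities per group and the linear energy-requirement equation live
in a versioned YAML config; both are documented approximations standing in
for survey-specific values, and the requirement equation fails explicitly
if its coefficients are missing.

## Synthetic study conditions

The generators make every pipeline stage testable without external data:

- **Mortality**: Gompertz–Makeham hazards `m(x) = c + b·e^{θx}` with
  defaults `c = 10⁻⁴`, `b = 3×10⁻⁵`, `θ = 0.095`, giving LE at birth
  ≈ 79 y — inside the 74–84 y band of the populations the packaged diets
  describe, so synthetic runs are magnitude-comparable.
- **Curves**: log-linear (log RR linear in intake, reference at the grid
  minimum) or J-shaped (quadratic with a stated nadir), with a CI profile
  whose SD grows linearly from zero at the reference.  The illustrative
  set uses signs and relative magnitudes from the cohort literature
  (protective plant foods and fish; harmful processed/red meat, sugar,
  and — weakly — eggs; J-shaped milk), with absolute sizes calibrated so a
  feasible-style multi-group change gives a joint hazard ratio near 0.8.
  They are synthetic stand-ins, not any study's estimates.
- **Scenarios**: `make_scenario(seed, "easy")` uses a constant hazard and a
  single noise-free curve, with the closed-form truth
  `1/(m·HR) − 1/m`; `"realistic"` draws Gompertz–Makeham parameters, ~10
  changed groups, a random overlap weight, and hands back *noisy* curve
  estimates (one normal error per curve, consistent with the printed CIs)
  while the true gain is computed from the noise-free curves by an
  independent continuous-time integrator (0.01-year steps, continuous lag
  ramp, trapezoidal person-years) that shares no code with the life-table
  module.

Passing tests on these conditions establish that the numerics are
faithful to the stated model and that the intervals are calibrated *under
the model's own error structure* (estimation error matching the printed
CIs, independent across groups).  They do not validate the epidemiology:
real meta-analytic curves have correlated errors across food groups,
residual confounding, and reference intakes that rarely sit at zero — with
a reference inside the grid, the single-z sampling scheme understates the
uncertainty of contrasts that straddle it.

## Problem sizes and numerical choices

The test suite and the acceptance script use 100 random schedules for the
life-table oracle, a 5×5 constant-hazard grid, 25 + 25 scenarios for
recovery against the fine-step oracle, and 200 scenarios × 1000 draws for
interval coverage (91–99% acceptance band around the nominal 95%); the
whole run takes seconds on one core because the life-table recursion is
vectorized across draws.  Ties and degenerate inputs: zero-change
scenarios return exactly 0 gain; zero-variance curves give zero-width
intervals; `overlap_w = 0` wipes the effect exactly; survivorship
underflow at extreme hazards reports e = 0 rather than NaN.

## Known limitations

Besides assumptions 1–3 above: the uncategorized-energy mechanism is
heuristic; mortality schedules are treated as fixed (no sampling error);
the decomposition depends on the one-at-a-time path (interaction effects
are spread proportionally by the rescaling); and the packaged energy
densities and requirement equation are placeholders adequate for energy
*accounting*, not nutrition science.
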