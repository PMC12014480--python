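# Methods

This note documents the models the package implements, the defaults and why
they hold, what the synthetic generator does and does not emulate, and the
numerical choices that shape the estimates.

## Sign conventions and units

Leaf water potential Ψ is stored in MPa and is always ≤ 0; a positive value
is a validation error, never silently negated (dropped minus signs are a
classic corruption in water-potential tables). Conductance g_s is in
mol m⁻² s⁻¹, VPD in kPa, DBH in cm, sap flux density in m³ m⁻² s⁻¹.
Timestamps live on a fixed UTC+1 clock; the pre-dawn window is
[04:00, 06:00) and the midday window [12:00, 14:00), half-open.

## The stomatal closure point (P_st)

### Model

Normalized conductance is assumed to decline with Ψ as a negative
exponential that transitions, at the species closure point, to a shallow
linear tail (conductance loss then reflecting declining soil-path
conductivity rather than active regulation), modulated multiplicatively by
VPD:

    g(Ψ, D) = f(Ψ) · (D / D_ref)^β,   D_ref = 1 kPa

with f exponential above the closure point and linear below, continuous at
the join. P_st is operationalized as the Ψ at which a flexible smooth of
the data becomes statistically indistinguishable from the projected
post-closure line.

### Estimation chain

1. **Normalization.** g_s is divided by the species' maximum observed value
   (a robust quantile option exists for outlier-contaminated data), so the
   response is comparable across species with different absolute maxima.
2. **Axis pairing.** On the pre-dawn axis each midday conductance is paired
   with the same tree's pre-dawn Ψ from the same campaign day; the midday
   axis uses the midday rows directly.
3. **VPD standardization.** Both the smooth and the projection are computed
   on conductances rescaled to the projection's VPD setting (2.4 kPa) with
   a species-level log–log VPD coefficient estimated from the full species
   table. Comparing an ambient-VPD smooth with a high-VPD projection leaves
   a multiplicative gap that never closes; standardizing both sides removes
   it and takes VPD-driven scatter out of the projection band.
4. **Smooth.** A penalized cubic regression spline (25 B-spline basis
   functions, second-derivative penalty) with the penalty chosen by GCV and
   then divided by 30. GCV minimizes global prediction error and
   over-smooths localized features; deliberate undersmoothing is the
   standard remedy when the object of interest is the *location* of a kink
   rather than the curve as a whole. Tree-level intercepts are absorbed by
   two backfitting passes between the smooth and centred tree-mean
   residuals — a desk-scale stand-in for a joint smooth-plus-random-effects
   fit, adequate because tree effects enter as near-constant offsets.
5. **Post-closure projection.** The post-closure subset is selected on the
   *regressor*: observations with Ψ more negative than the
   fixed-threshold estimate minus 0.1 MPa, refined once from the resulting
   intersection estimate and clamped to the 10–55% Ψ-quantile range.
   (Selecting on low conductance instead — the intuitive rule — picks
   disproportionately negative noise realizations and shifts the projected
   line about one residual s.d. low; the bias is structural, not a small-n
   artifact.) The shallow post-closure slope is fitted jointly across
   species (species intercepts, common slope) unless a BIC margin > 2 says
   the species-specific slopes fit decisively better, which happens exactly
   when noise is small relative to between-species slope differences (e.g.
   the noiseless verification limit). The 95% band is a normal-theory
   *prediction* interval — the band the data points themselves occupy,
   which is what a response curve can meaningfully "approach"; a
   confidence-of-the-line band collapses with n and balloons under
   extrapolation, making the entry point either unreachable or
   uninformative.
6. **Intersection scan.** On a shared 0.01-MPa grid ordered wet → dry,
   detection requires the smooth to fall to the band's upper limit and stay
   at or below it for 15 consecutive grid points (0.15 MPa; shorter runs
   are spline noise dips, whose wiggle scale is one knot spacing ≈ 0.07
   MPa) after first having been above the band (the band is extrapolative
   at the wet end and can trivially contain the smooth there). The reported
   P_st is the first point within the entered run where the smooth reaches
   `mean + 0.1·(upper95 − mean)`: the first touch of the upper limit
   precedes the closure point by about half a band width over the local
   slope contrast, while the literal line crossing is unstable because the
   two curves are near-parallel beyond closure; a level just above the band
   centre removes the entry bias without inheriting that instability.
   Numerical tolerances: 5·10⁻³ normalized units for the entry test (it
   must exceed the spline's kink-approximation error or the noiseless limit
   never "enters"), 10⁻³ for the reported crossing.
7. **Fixed-threshold variant.** The first grid Ψ where the (ambient-VPD)
   smooth falls below 0.05 mol m⁻² s⁻¹ divided by the species reference —
   the conventional closure level — tagged separately and used both as a
   robustness check and to seed the regime cut (with the threshold relaxed
   in 25% steps when it lies below the smooth's dry-end plateau).

### Error structure

On default synthetic worlds the estimator recovers species closure points
with ≈ 0.1 MPa RMSE and < 0.05 MPa bias. In the noiseless limit errors
collapse not to the grid step but to the smoothing resolution: a cubic
spline rounds a kink over roughly one knot spacing, bounding noiseless
errors at ~0.02–0.07 MPa depending on the species' curvature. That floor is
intrinsic to any smoothing-based changepoint reading, and is why the test
suite asserts ≤ 0.08 MPa there rather than one grid step.

## Growth cessation

Zero-growth transform: per tree, DBH readings are replaced by their running
maximum, so only irreversible expansion counts; the transform is monotone
and idempotent. Interval rates are ΔDBH/Δdays; June–August intervals
(midpoint rule) are kept, excluding winter cambial dormancy. Each interval
is matched to the nearest pre-dawn campaign within ±7 days of its midpoint
(ties go to the later campaign). The binary non-zero-growth indicator is
fitted with a binomial mixed model — species and tree-in-species random
intercepts, estimated by variational Bayes, with a plain-logistic fallback
when the variational fit fails or returns a wrong-signed slope — and the
population logistic inverts in closed form:

    Ψ(p) = (logit p − β₀) / β₁.

The p = 0.05 threshold is therefore exactly logit(0.05)/β₁ beyond the
p = 0.5 midpoint, a self-consistency the tests check to 10 decimals.

## Hydroscape

The (Ψ_pd, Ψ_md) cloud is fitted with a continuous two-segment line,
y = a + b·Ψ_pd + c·(Ψ_pd − brk)·1[Ψ_pd < brk], breakpoint by grid search at
0.01 MPa over the pre-dawn range excluding the outer 10% on each side
(boundary breakpoints are unidentifiable). The segmented model is reported
only when its BIC (counting the breakpoint as a parameter) improves on the
single line by more than 2; otherwise a "no breakpoint" result carries the
straight-line coefficients. An orientation check (≥ 95% of pairs must have
Ψ_md ≤ Ψ_pd) catches swapped columns. The same machinery provides the
shift detection for conductance-vs-Ψ_pd clouds.

## Sap flow

ΔT series convert by the classical thermal-dissipation calibration
K = (ΔT_max − ΔT)/ΔT, u = 118.99·10⁻⁶·K^1.231 m³ m⁻² s⁻¹, with ΔT_max the
rolling 7-day maximum of pre-dawn ΔT per tree (accommodating probe
baseline drift); both constants and the window are configurable. Daily
maxima are expressed as % of the tree's seasonal maximum (exactly one day
scores 100, ties share it) and modelled as
log(response) = α + β·log(−Ψ_pd) with species (and site within species)
random intercepts — the sign-flipped log being the standard resolution of
"log-transform" for a negative-valued regressor.

## The synthetic generator

The generator is phenomenological, not a mechanistic soil–plant–atmosphere
model. Its defaults are the study conditions every recovery test runs
under:

- **Design:** 9 species × 10 trees × 35 campaigns over a 160-day season;
  site-level pre-dawn Ψ dries from −0.25 to −2.0 MPa along a mildly convex
  ramp with 0.06 MPa campaign jitter.
- **Species:** closure points ~N(−1.2, 0.2²) MPa (clipped to [−1.75,
  −0.75]); g_s,max ~U(0.2, 0.4) mol m⁻² s⁻¹; the exponential rate is set so
  each species' absolute conductance crosses the conventional 0.05
  mol m⁻² s⁻¹ level near its own closure point (the empirical agreement of
  the two P_st definitions is a property of real closure curves, so the
  generator builds it in); post-closure slope U(0.01, 0.03) per MPa; VPD
  exponent U(−0.65, −0.25).
- **Hydroscape:** Ψ_md = −0.5 + 1.5·Ψ_pd above the species break (slope
  s.d. 0.40 across species, intercept s.d. 0.15), shallower slope 0.4
  below, continuous at the break; this places the midday closure point
  near −2.3 MPa with roughly three times the pre-dawn spread, and
  guarantees Ψ_md ≤ Ψ_pd.
- **Noise:** additive Gaussian s.d. 0.05 on normalized conductance
  (truncated at 0), 0.05 MPa on pre-dawn Ψ (pressure-chamber scale), 0.18
  MPa on midday Ψ (midday potentials scatter far more), lognormal tree
  effects (s.d. 0.15 log units), campaign-level VPD ramping 0.9 → 2.1 kPa
  with 0.20 log s.d. between campaigns and 0.25 within (leaf-to-leaf and
  hour-to-hour variation). These values were chosen so the synthetic
  worlds reproduce the qualitative fit statistics of real campaigns
  (mixed-model R² near 0.5–0.6 on the pre-dawn axis, lower on the midday
  axis, VPD adding explanatory power).
- **Growth:** weekly increments are Bernoulli in the interval-mean pre-dawn
  Ψ with a logistic anchored at p = 0.5 at −1.2 MPa and p = 0.05 at −1.5
  MPa (steepness 9.81 per MPa follows from the two anchors); increment
  sizes are gamma with mean 0.03 cm. Observed readings superimpose elastic
  shrinkage (0.005 cm/MPa), reading noise (0.0005 cm) and quantization to
  0.005 cm (vernier girth-band resolution). The measurement model is
  constrained to noise ≪ resolution ≪ weekly increment: outside that
  ordering the zero-growth transform converts reading noise into spurious
  growth ticks (a probability floor that destroys the p = 0.05 inversion)
  or defers sub-resolution growth into drier weeks.
- **Sap flow:** diel ΔT with zero night flow and a half-sine day course,
  whose implied daily maximum follows a power law in Ψ_pd; ΔT is the exact
  inverse of the Granier calibration, so the preprocessing transform
  recovers the intended flux to numerical precision (a round-trip oracle).

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about real data: instrument drift and data gaps,
azimuthal/radial sap-flow heterogeneity and wounding, inter-annual
carry-over and acclimation, species-specific VPD response shapes beyond a
power law, within-species tree-level threshold variation (exposed as a
parameter, default 0 because no empirical value constrains it), rain pulses
and rewetting dynamics, and spatial soil heterogeneity within a site.

## Reproducibility

Every stochastic stage draws from a substream derived from one global seed
and a fixed stage label, so stage randomness is independent of execution
order. A run directory always contains the config and seed that produced
it; re-running reproduces every CSV byte-identically. Estimates are
invariant to row order and tree relabelling.

## Known limitations

- The intersection estimator's noiseless accuracy is bounded by the spline
  kink-rounding floor (above), and its noisy accuracy by the shallow slope
  contrast at closure — a parametric segmented fit would be ~2–3× more
  efficient, but the band-intersection reading is the method this package
  implements and verifies.
- The binomial GLMM uses variational Bayes, which mildly shrinks the
  logistic slope; the p = 0.05 inversion is accurate to ~0.05 MPa at
  n = 2000 but the slope itself should not be interpreted strictly.
- With a single species and site, the stress-response mixed models drop to
  ordinary regression (with a warning); crossed species × site random
  effects are approximated by nesting site within species.
- The full dendrometer chain carries a small dry-ward bias (~0.05–0.1 MPa
  at p = 0.05) from residual measurement-process effects; the logistic
  model itself, tested on directly simulated logistic worlds, is unbiased.
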