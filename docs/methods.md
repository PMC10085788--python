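# Methods

## Model

The package treats nuclear blebbing on hyp7 nuclei as a linear birth–death
process of the M/M/∞ type:

* **Birth.** Each nucleus acquires blebs according to a nonhomogeneous Poisson
  process with intensity β(t) (events·nucleus⁻¹·day⁻¹), independent across
  nuclei. No generative mechanism is observable at desk scale, so this is the
  minimal memoryless model consistent with a prescribed mean trajectory and a
  constant detachment hazard.
* **Death (detachment).** Each standing bleb detaches after an independent
  Exponential(λ) delay, λ constant in age. Detached blebs leave the standing
  count; lysosomal capture and reabsorption are represented only as the
  terminal event, not as timed competing processes.
* **Chromatin content.** Assigned at birth as Bernoulli(0.42), independent of
  age and of detachment — the observed chromatin-positive fraction is a single
  pooled estimate (42%, n = 45) with no age stratification to support more.

The standing mean obeys dE[B]/dt = β(t) − λ·E[B], so

E[B(t)] = ∫₀ᵗ β(s)·e^(−λ(t−s)) ds,

evaluated in closed form for constant and linear β and by adaptive quadrature
(absolute tolerance 1e-10, integration split at the intensity's breakpoints)
otherwise. Inverting the balance gives the calibration rule
β(t) = B′(t) + λ·B(t), clipped at zero; wherever clipping is inactive the
simulator's analytic mean reproduces the target trajectory exactly. A target
that decays faster than λ·B would require negative births; calibration then
warns and the realised mean sits above the target there. Power-law targets
need p ≥ 1 for a bounded intensity at onset (the derivative diverges
otherwise), which calibration rejects.

## Estimation

Censored time-lapse tracks are analysed with the exponential
occurrence/exposure estimator: λ̂ = events / bleb-hours at risk, mean lifetime
1/λ̂, half-life ln2/λ̂. A detachment observed between frames is timestamped at
the first frame at which the bleb is absent, and that timestamp is the bleb's
at-risk time; the reconstructed 97-track cohort (96 censored at 8 h, one
event with 4 h at risk) is the only assignment whose exposure, 96×8 + 4 = 772
bleb-hours, matches the published 772-h lifetime. Confidence intervals are
exact Poisson (Garwood): low = Qgamma(α/2; k)/E, high = Qgamma(1−α/2; k+1)/E —
chosen over Wald because realistic event counts are 0–2. With zero events the
estimate reports rate 0, infinite lifetime/half-life and a one-sided upper
bound −ln(α)/E rather than failing, since small cohorts commonly observe no
event.

## Parameters, units, defaults

| parameter | unit | default | why |
|---|---|---|---|
| detachment rate λ | per hour | 1/772 | occurrence/exposure estimate from the 97-track cohort |
| trajectory B(t) | blebs/nucleus | power law, t₀=1, T=14, B_max=0.35, p=2 | the underlying per-day counts are not published; this is the simplest smooth shape matching "near zero at AD1, 0.35 at AD14". A quadratic (p=2) was chosen over linear because blebbing accelerates with age; p is refittable from data via `fit_power_trajectory` |
| chromatin fraction | probability | 0.42 | observed pooled fraction |
| diameter ratio | — | 1/5 | observed bleb/nucleus diameter ratio; volume fraction derived as its cube (spherical scaling), no DNA-density correction |
| total somatic DNA loss | fraction | 0.15 (range 0.10–0.25) | midpoint convention of the observed range; the range endpoints are always reported alongside |
| age window | adult days | [1, 14] | AD1 is the blebbing onset; both AD11 and AD14 endpoints are supported as parameters since the loss statements straddle them |
| frame interval | hours | 0.5 | 30-min imaging cadence |
| observation window | hours | 8 | tracked window per bleb (exposed as a parameter; imaging sessions can be longer than the tracked window) |

Internally all kinetics run in hours; the 24 h/day conversion is applied only
at the trajectory/budget boundary and at I/O. Extrapolation of any trajectory
beyond its last knot or horizon is constant, never linear, to avoid unbounded
predictions. Percentages are derived presentation fields formatted with
round-half-even at the reported precision (0.016%, 0.1%); machine-readable
fractions are always retained.

With the default trajectory the expected detachments per nucleus over
[AD1, AD14] is (24/772)·0.35·13/3 ≈ 0.047. This is a documented
reconstruction: the originally used trajectory values are not published, and
0.047 should not be quoted as the published 0.049.

## Simulation and sampling choices

* Thinning against the exact piecewise supremum of β (all supported intensity
  families are piecewise monotone, so the supremum is attained at piece
  endpoints).
* One root seed; per-nucleus and per-sampler child streams derived via
  `numpy.random.SeedSequence` spawn keys, so nucleus *i* generates identical
  blebs regardless of population size and samplers never share a stream.
* Time-lapse sampling selects standing blebs uniformly without replacement
  and quantises events to the first-absent frame, matching the estimator's
  convention. Replicated-cohort summaries (`simulate_timelapse_cohorts`) draw
  exponential residual lifetimes directly — valid because a standing bleb's
  residual life is Exponential(λ) by memorylessness — which keeps 10,000-
  replicate experiments to seconds.
* The default study design scores 100 nuclei on adult days 1, 4, 7, 9, 11 and
  14 and tracks 97 blebs for 8 h starting at AD9. Tracking earlier than ~AD4
  is impractical in simulation (and in reality requires pooling many animals):
  at AD2 the trajectory gives ~0.002 blebs/nucleus, so a 97-bleb cohort would
  need tens of thousands of nuclei. The tracking age is a design parameter.

Default problem sizes (1,000–10,000 nuclei, 200 replicate studies, 10,000
replicate cohorts) keep every check well inside a minute or two on one core
while leaving Monte-Carlo standard errors far smaller than the tolerances
being checked.

## What the generator does and does not emulate

It reproduces the study's quantitative skeleton: the rising bleb frequency,
rare exponential detachment, the chromatin-positive fraction, censored
frame-quantised tracks, and per-day cross-sections. It does **not** emulate
image-level noise, bleb identification error, inter-animal heterogeneity in
aging rate, age-varying detachment hazards, multiple blebs interacting on one
nucleus, or reabsorption/lysosome kinetics. Passing tests therefore show that
the estimators recover the parameters of this idealised process at realistic
sample sizes — not that the estimates are robust to scoring error or
between-worm variation in real data.

## Numerical notes

* Garwood bounds use `scipy.stats.gamma.ppf`; the k = 0 lower bound is 0 by
  definition.
* Trajectory integrals are closed-form (trapezoid on knots; power-law
  antiderivative); the quadrature fallback in the simulator's analytic mean
  carries absolute tolerance 1e-10.
* The power-law fit runs bounded least squares (B_max, p ≥ 0) from
  (max observed level, p = 1), tolerances 1e-14; noiseless data are recovered
  to better than 1e-6 relative error.
* Duplicate-day frequency observations are pooled by summing counts
  (equivalently, nuclei-weighted averaging) before interpolation.
* Degenerate inputs have defined behaviour rather than exceptions where a
  zero is meaningful: zero detachment rate gives zero expected detachments
  and an all-censored time-lapse; an all-zero trajectory integrates to zero;
  any zero budget factor annihilates the product.

## Limitations

The headline share (~0.1%) inherits every point estimate's uncertainty
multiplicatively; the single observed detachment makes λ the dominant
uncertainty (its 95% CI spans two orders of magnitude), which
`propagate_uncertainty` can make explicit but the point budget hides. The
equal-DNA-density assumption (volume fraction = DNA fraction) is untested
biology, and the quadratic trajectory is one of several shapes compatible
with two anchored points.
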