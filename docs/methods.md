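# Methods

This note records the modelling choices behind `photocycle`: what the
synthetic cohorts emulate, how each analysis stage is defined, which
defaults matter, and what the test suite does and does not establish
about real data.

## Synthetic cohorts

Real cycle-tracking exports are private, so the package ships a
generator whose output has the statistical structure the analysis
assumes and whose generating parameters are known exactly.  Ground
truth (per-cycle ovulation indicator, luteal shift-onset day, per-user
random intercept, true coefficient vector) is returned alongside the
data, which is what makes pipeline-level parameter recovery testable.

**Cohort composition.** Each user contributes 1–13 contiguous cycles
(the per-user count is uniform on that range) with integer lengths
drawn from a truncated normal, mean 29 d, sd 3.5 d, truncated to
15–40 d.  Ages are a truncated normal (mean 30, sd 7) on 17–64 y and
the BMI proxy a truncated normal (mean 25, sd 5) on 13–56 — the app
never defines "BMI proxy", so the generator treats it as an opaque
covariate on that range.  Coordinates are uniform over the
continental-US box (25–49° N, 124–67° W).  First cycle start dates are
uniform over a two-year window (2021–2022) so every day of year is
populated.

**Ovulation model.** Cycle ovulation is Bernoulli with

    logit p = b0 + u_i + b_age*age + b_bmi*bmi + b_len*len + b_dl*DL
              + A * [bump(spring) + bump(autumn)],

`u_i ~ N(0, 0.5^2)` (logit units), defaults `b0 = 3.4`,
`b_age = −0.02`/y, `b_bmi = −0.03`/unit, `b_len = −0.02`/d,
`b_dl = +0.001`/min, equinox amplitude `A = 0` (Gaussian bumps of
sd 15 d centered on days 79 and 266 when planted).  These defaults
put the marginal anovulatory fraction near 10%, inside the 3.4–18.6%
range reported for healthy cycles, and make day length a real but
modest effect (~0.24 logit units across the seasonal range at
mid-latitude).

**BBT traces.** A cycle's temperature is a follicular plateau (per-
cycle baseline ~ N(97.2, 0.3²) °F) plus, for ovulatory cycles only, a
logistic-ramp luteal rise of drawn size (truncated normal, mean
0.4 °F, sd 0.07, support (0.05, 0.5) — "typically less than half a
degree") beginning at a shift day drawn uniformly from 11–18 (capped
two days before cycle end) and spanning about two days, plus i.i.d.
N(0, 0.1²) °F measurement noise.  This is the simplest biphasic shape
the detectors target; real traces have slow drifts, premenstrual
dips, and autocorrelated noise that the generator does not model, so
detector operating points measured here are upper bounds on
real-data performance.

**Logging process.** Each daily field is masked independently: BBT
present with probability 5/7, libido with 0.04, sex with 0.18
(matching 96%/82% unlogged), LH tests present for 31% of cycles.
Deviation flags (illness/alcohol/sleep) hit 2% of logged BBT days so
the exclusion path is exercised.  Behavioral logs carry user-level
heterogeneity — a per-user libido set-point (N(2, 0.5²), daily values
rounded into 1–3) and a per-user had-sex propensity (Beta(3,2)) — so
the random intercept of the behavior models reflects real structure
rather than being degenerate at zero.  LH tests are positive the day
before the true shift day of ovulatory cycles and negative otherwise
(no false negatives are modelled).

**Weather.** Ambient temperature is a hemisphere-aware sinusoid of
day-of-year (peak mid-July north of the equator), latitude-scaled
amplitude, plus N(0, 2²) °C noise; ~2% of cycles lack a temperature
to exercise that exclusion.  This stands in for station weather and
is therefore seasonally collinear with day length by construction —
exactly the situation the temperature-controlled variant probes.

**Determinism.** One seed; each user draws from an independent
substream keyed by (seed, user index), so a user's data is invariant
to the cohort size, and identical seed + config yields byte-identical
CSVs.

## Exclusions

Applied in a fixed order, each removed cycle counted once under the
first matching reason: precondition users; cycles > 40 d; cycles with
< 10 valid BBT readings (deviation-flagged readings do not count —
and they are likewise dropped before imputation); event cycles
(miscarriage / emergency contraception remove the event cycle and the
next, pregnancy removes the event cycle and the two following, with
adjacency resolved on the user's full chronological sequence before
other filters); missing coordinates; missing temperature.  Counts are
invariant to input row order.

## BBT imputation

Natural cubic splines (zero second derivative at the end knots)
through each cycle's observed (day, temperature) points, evaluated on
interior missing days only — no extrapolation beyond the observed
span, and no imputation across cycle boundaries.  The boundary
condition is not dictated by the twice-differentiability requirement;
natural is the standard default.  With fewer than 4 observations the
spline is underdetermined and the series is passed through unimputed
(detectors then see the gaps).  Knots are reproduced exactly (tested
to 1e-9 °F).

## Ovulation detectors

All comparisons written "exceeds"/"greater" are strict.  Detectors run
on the spline-completed series; windows touching imputed days are
allowed and visible through the series masks.

* **Coverline** — threshold = max(days 1–10) + 0.15 °F; ovulatory iff
  any later day strictly exceeds it; indeterminate below 11 days or
  without usable temperatures on both sides of day 10.
* **3-over-6** — ovulatory iff some three consecutive days each
  strictly exceed the maximum of the six preceding days;
  indeterminate when no complete 9-day window exists.
* **NC-like** — an approximation of a commercial detector's published
  verbal description (the real algorithm is proprietary): scanning
  3-day windows, a window qualifies when (a) each of its days sits
  strictly above the pre-window (follicular) mean plus a rise margin,
  (b) its mean strictly exceeds that raised level and the whole-cycle
  mean, and (c) its mean lies within τ of the mean from window start
  to cycle end (the luteal segment).  Defaults τ = 0.15 °F and rise
  margin = 0.15 °F, both configurable.  The rise margin is essential:
  without it some noise window always clears the three mean
  comparisons at the default 0.1 °F noise (specificity ≈ 0.05),
  whereas with it the detector operates at sensitivity ≈ 0.997 /
  specificity ≈ 0.88 (0.999/0.98 at 0.05 °F noise).  A small epsilon
  (1e-9) guards the strict mean comparisons against floating-point
  round-off on constant series.
* **LH** — ovulatory iff any positive test; indeterminate when the
  cycle has no tests (LH status is missing, not negative, for the
  ~69% of cycles without tests).

## Behavior scores

Daily sex codes collapse to binary had-sex (protected or unprotected
→ 1, explicit no-sex → 0, unlogged → missing).  Unlogged days would
score zero and are dropped before averaging, so a cycle with sex
logged on 3 of its 4 logging days scores 0.75; cycles with no logged
days have no score and are excluded from the corresponding model
(listwise, per outcome).  Libido (1–3, with 0 reserved for
"unlogged" — the schema cannot distinguish a logged zero, mirroring
the source data's ambiguity) is averaged the same way.

## Day length

Sunrise hour-angle equation with the Spencer Fourier-series
declination and the conventional −0.833° zenith offset (refraction +
solar disk), clamped to 0/1440 min poleward of the polar circles.
Day length is timezone-free; longitude is carried but unused.  The
offset is exposed as a parameter: with it, day length on the equinox
exceeds 12 h everywhere (by ~7 min at mid-latitude, ~16 min at 66°),
and the geometric (offset = 0) day length is the quantity that is 12 h
at zero declination.  For the same reason, the day lengths of two
mirrored-declination dates sum to slightly more than 24 h.  Against a
high-precision ephemeris the implementation agrees within 5 min for
|lat| ≤ 60° (the synthetic cohort spans 25–49°); the Spencer
approximation drifts to ~6 min of day-length error by 65°.  Each
cycle's day length is evaluated at its start date, mirroring the
temperature covariate; a cycle-mean option exists in the config.
Users' coordinates are taken as given in users.csv — reducing a
region to its centroid (with up to ~25 min of day-length error) is
the data producer's concern.

## Mixed models

Binary outcomes: the random-intercept logistic GLMM is fit by
maximizing the exact marginal likelihood with fixed-point
Gauss–Hermite quadrature (25 nodes by default) over (β, log σ) with
analytic gradients (L-BFGS-B, ftol 1e-12).  Non-adaptive quadrature
is accurate at this design's cluster sizes (1–13) and intercept scale
(σ ≈ 0.5); the implementation matches lme4::glmer (nAGQ = 25) on
simulated data to ~3 decimal places in coefficients and
log-likelihood.  Standard errors come from the inverse numerical
Hessian (central differences on the analytic gradient) with σ on the
natural scale; p-values are two-sided Wald z-tests — the choice of
test is a convention, not forced by the estimates.  Single-class
outcomes and degenerate (|b| > 1000) fits raise a separation error
naming the outcome.  Random slopes are not fit.

Continuous outcomes use statsmodels MixedLM (ML, default optimizer —
the lbfgs option can stall on the σ=0 boundary); if the random-
intercept variance degenerates the model collapses to OLS and the
result is flagged.  A constant outcome short-circuits to zero slopes
with a degenerate-variance note.

Variants: `target` (age, BMI proxy, cycle length, day length);
`temperature` adds ambient temperature; `fertile_age` restricts to
ages 18–45 inclusive and keeps temperature (matching the covariate
rows of the corresponding published table layout, though the text
describes it only as an age restriction); `standardized` swaps day
length in minutes for half-hour units (0–48) and leaves the other
covariates on their natural ranges.  Rescaling a covariate by c
scales its coefficient by 1/c and leaves z = b/SE invariant, which is
what makes the standardized variant a pure reparameterization at the
optimum.

## Equinox tests

The peak model is rate(d) = c + a₁·G(d; 79, s) + a₂·G(d; 266, s) — a
constant plus Gaussian bumps at the two equinoxes with shared width
s ∈ [2, 60] d — fit by least squares to the per-day-of-year outcome
rate, weighted by the day's cycle count; R² is the weighted variance
explained (clipped at 0).  Day-of-year resolution (≈365 points)
keeps the null R² near zero (4 free parameters on 365 points absorb
~1% of pure noise); coarser binning would inflate it.  The form of
the peak model is a design choice — nothing in the problem dictates
Gaussian bumps — and is therefore reported with its parameters.
Strata: twelve_hour = within ±5 min of 720 (documented tolerance),
near_equinox = 660–780 min (the 11–13 h band) outside that, other =
everything else; pairwise comparisons use two-proportion z-tests for
binary outcomes and Welch t-tests for continuous ones, with empty-
stratum comparisons reported absent.

## Pipeline and problem sizes

Stages hand off plain CSV/JSON files so each is independently
testable; a manifest records config hash, seed, timings and artifact
digests (identical config + seed ⇒ identical digests).  The test
suite validates parameter recovery on 50 cohorts of 2,000 users × 8
cycles (sign of the day-length effect recovered in ≥95% of fits,
estimate within 2 SE of truth in ≥90%) and Wald type-I error on 200
cohorts of 250 users (rejection rate within [0.02, 0.10] at α = 0.05);
recovery fits use the generator's true ovulation indicator, the clean
oracle uncontaminated by detector misclassification, which at these
noise levels mainly inflates SEs (visible in the README example).
These sizes give the checks real power while keeping a full suite run
in a few minutes on one CPU.

## Known limitations

The generator's independence assumptions (i.i.d. daily masks, no
within-user cycle-length autocorrelation, noise-free LH tests, no
behavioral seasonality) mean passing tests certify the pipeline's
correctness and calibration under the stated model, not detector or
model performance on real traces.  The NC-like detector is a
documented approximation, not a reproduction, of the commercial
algorithm.  Day length uses a mean-year declination approximation
(sub-minute ephemeris accuracy is out of scope), and weather is
synthetic.  No multiple-testing correction is applied across
outcomes or variants.
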