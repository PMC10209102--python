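# photocycle

Photoperiod and ovulation-rate analysis for menstrual-cycle-tracking
cohorts.

Many species time reproduction to day length, and there is evidence
that human ovarian function varies seasonally too.  Testing this on
cycle-tracking app data means chaining together a series of fiddly
steps: an exclusion cascade over users and cycles, imputation of
sparsely-logged basal body temperature (BBT), several
ovulation-detection rules, aggregation of even sparser behavior logs,
solar geometry for the day-length covariate, and random-intercept
mixed models for cycles nested within users.  `photocycle` implements
that pipeline end to end as a tested library and CLI, together with a
synthetic-cohort generator with known ground truth, so every stage —
and the whole chain — can be validated without access to any
proprietary app export.

It is intended for researchers who want to reproduce, stress-test, or
extend this style of photoperiod analysis: power analyses, detector
comparisons, and sensitivity of mixed-model estimates to preprocessing
choices.

## The model

Each cycle *j* of user *i* is labelled ovulatory/anovulatory and
modelled with a random-intercept logistic regression

```
logit P(ovulatory_ij) = b0 + u_i + b_age * age_i + b_bmi * bmi_i
                        + b_len * cyclelength_ij + b_dl * daylength_ij,
u_i ~ N(0, sigma_u^2)
```

where `daylength_ij` is the sunrise-to-sunset duration in minutes at
the user's coordinates on the cycle start date, from the sunrise
hour-angle equation `cos w0 = -tan(phi) tan(delta)` with the standard
−0.833° refraction/solar-disk correction.  The marginal likelihood is
maximized by Gauss–Hermite quadrature; p-values are two-sided Wald
z-tests.  Continuous outcomes (per-cycle libido and sexual-activity
scores) use a random-intercept Gaussian mixed model.

Cycles are labelled by four detectors: **Coverline** (any temperature
after day 10 exceeding the first-10-day maximum + 0.15 °F),
**3-over-6** (three consecutive temperatures above the maximum of the
preceding six), an **NC-like** three-day-window rule approximating a
published verbal description of a commercial detector, and **LH**
(any positive urinary luteinizing-hormone test).  Missing BBT days are
filled by natural cubic splines within each cycle before detection.

Model variants mirror a target-plus-robustness design: the target
covariate set; adding ambient temperature; restricting to likely
fertile ages (18–45); and re-expressing day length in half-hour units
(0–48) so its range matches the other covariates.  An equinox check
fits a constant-plus-Gaussian-bumps peak model to the daily ovulation
rate versus day of year and compares the 12-hour / 11–13-hour / other
day-length strata.

## Worked example

```bash
photocycle run --out runs/demo --seed 42
```

runs the whole chain — simulate (750 users, ~5,000 cycles by default),
exclusions, spline imputation, detection, behavior aggregation, model
fits, equinox tests — and prints

```
run complete: 4848 analysis rows, config a091f2a8871c, seed 42
```

`runs/demo/results.json` then holds one block per variant × outcome.
For the default cohort (which plants `b_dl = 0.001` per minute of day
length):

```json
"target": {
  "ovul_3over6": {
    "terms": {
      "day_length": {"b": 0.000958, "p": 0.0767, "se": 0.000541}, ...
    },
    "n_users": 729, "n_cycles": 4848, ...
  }
}
```

i.e. the fitted day-length log-odds slope — 0.000958 per minute,
recovering the planted 0.001 well within one standard error (label
noise from the detector inflates the SE relative to a fit on the true
ovulation indicator).  `runs/demo/equinox.json` reports the
peak-model R² (0.0003 on this null-equinox cohort: day length drives
a smooth seasonal trend, but nothing special happens at the
equinoxes) and the stratum comparisons.  Individual stages are
available as `photocycle simulate/preprocess/detect/behavior/fit/equinox`,
and

```bash
photocycle daylength --lat 59.33 --lon 18.07 --date 2022-06-21
# 1117.5
```

prints a day length in minutes.

## Layout

- `src/photocycle/synthetic.py` — cohort generator + ground truth
- `src/photocycle/solar.py` — declination, day length, equinox strata
- `src/photocycle/preprocess.py` — exclusion cascade, spline imputation
- `src/photocycle/detect.py` — the four ovulation detectors
- `src/photocycle/behavior.py` — libido/sex per-cycle scores
- `src/photocycle/glmm.py` — random-intercept logistic GLMM
- `src/photocycle/inference.py` — analysis table, variants, fits, equinox tests
- `src/photocycle/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — modelling assumptions, defaults, limitations
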