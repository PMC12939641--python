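# Methods

This note records the models, conventions and design choices behind
`guyton-bedside`, in enough detail that a reader can judge what the
package's results do and do not show.

## Physiologic model

The package works in the Guytonian frame: steady-state cardiac output is
set at the intersection of a venous-return line and a cardiac-function
curve. The venous-return line is parameterized by the mean circulatory
filling pressure (MCFP) — the equilibrium vascular pressure that would
obtain if flow stopped, an index of vascular filling relative to
compliance — and by the venous resistance Rv between the MCFP node and
the right atrium:

    VR(RAP) = (MCFP − RAP) / Rv .

Neither MCFP nor Rv is directly measured at the bedside. They are
estimated row-by-row (per monitoring sample) from routine signals:

| quantity | formula | units |
|---|---|---|
| VO2i | 242.1 + 9.7 ln(age) − 34 ln(weight) − 9.6·SV − 11.2·CI flags | mL O2/min/m² |
| CI | VO2i / (1.36 · Hb · (SaO2 − SvO2) · 10) | L/min/m² |
| CO | CI · BSA | L/min |
| SVRi | (MAP − CVP) · 80 / CI | dyn·s·cm⁻⁵·m² |
| MCFP | 0.96·CVP + 0.04·MAP + 0.2·CO | mmHg |
| Rv | (MCFP − CVP) / VR | mmHg/(L/min) |
| cOER, rOER | (SaO2 − NIRS) / SaO2 | — |

with the renal NIRS value standing in for the venous saturation SvO2 in
the Fick step, and venous return VR taken equal to cardiac output at
steady state.

Conventions the formulas leave open, all settable in `HemoConstants`:

- **Hemoglobin** is required by Fick but is not a monitored signal. It is
  a per-patient constant (generator draws U(10, 15) g/dL; default 13
  when a profile carries none). Derived CI/CO values scale inversely
  with the assumed Hb — absolute levels should be read with that in
  mind; directions of drug effects are unaffected.
- **VO2 indexing**: the estimating regression is treated as indexed
  (mL/min/m²), so the Fick quotient is directly a cardiac *index*; a
  toggle treats it as absolute.
- **Flow convention**: the 0.2·CO term of the MCFP formula and the Rv
  denominator use absolute cardiac output in L/min (toggles allow
  indexed flow). The 0.2 coefficient mixes mmHg with L/min without an
  anthropometric rescaling; with indexed flow selected, MCFP values
  shift by 0.2·CI·(1 − BSA) relative to the default.
- **Oxygen capacity** 1.36 mL O2/g Hb; dissolved oxygen ignored.
- Saturations are percent at I/O (monitor convention) and fractions
  inside the Fick step; the extraction ratios are scale-invariant.
- **BSA** by Mosteller, √(height·weight/3600).

Undefined rows — a NIRS reading at or above SaO2 (no arteriovenous
gradient), nonpositive flow — are flagged as NaN and propagated, never
replaced by fabricated values; downstream model assembly drops them with
a logged count.

The Guyton diagram's cardiac-function curve is a saturating exponential
`Fmax·(1 − exp(−(RAP − rap0)/τ))` clipped at zero — any monotone
plateauing family would serve; the operating point is solved by
bisection on [RAP_min, MCFP] to 1e-9 mmHg (the venous line falls, the
cardiac curve rises, so the gap function is strictly decreasing and the
root is unique when it exists; a no-intersection bracket is reported
explicitly rather than extrapolated).

## Synthetic cohort generator

Real bedside streams of this kind are not shareable, so the package
carries its study conditions as code. Per patient:

- **Demographics**: age drawn from four strata (<1, 1–5, 6–10, >10 y,
  weights 10/11/5/20 mirroring a published transplant cohort's mix),
  weight and height from coarse growth curves with log-normal jitter,
  BSA by Mosteller; single-ventricle flag at 15%, critical-illness at
  50%; hemoglobin U(10, 15) g/dL.
- **Baselines**: age-appropriate resting values (infant HR ≈ 130 down
  to ≈ 90 in adolescents, MAP U(55, 75) mmHg, CVP U(6, 12) mmHg, SaO2
  U(96, 100)%, cerebral NIRS U(55, 80)%, renal NIRS U(65, 80)%).
- **Dose schedules**: eight vasoactive infusions in native charting
  units, piecewise constant; the number of rate changes over 48 h is
  Poisson with mean 20 — titration every couple of hours, which is what
  bedside practice in an unstable early postoperative window looks like
  and which also keeps each dose trajectory from being collinear with
  elapsed time within a patient (at markedly lower change rates the
  dose–time collinearity makes drug effects unidentifiable to any
  observational model, forests included). Segment levels are 0 with
  probability 0.3, otherwise uniform over the drug's clinical range.
  Phenylephrine is charted but dosed zero by default.
- **Effects**: each drug shifts each raw signal by
  `magnitude · dose/(dose + k)` with k at mid-range — monotone,
  saturating, zero at zero dose, instantaneous (no pharmacokinetics).
  The default effect table is calibrated so the *derived* MCFP and Rv
  respond to each drug with the direction pattern in
  `DEFAULT_OUTCOME_SIGNS` (epinephrine, norepinephrine, vasopressin
  venoconstrictive: MCFP↑ Rv↑; milrinone, nitroprusside venodilating:
  MCFP↓ Rv↓; calcium chloride MCFP-neutral with Rv↓ via its cardiac
  output effect; nicardipine arterial-selective: MCFP↓, Rv neutral).
  One structural constraint is worth knowing: within a patient, SVRi
  and Rv − 0.2 are both proportional to (MAP − CVP)/flow, so no
  raw-signal effect assignment can move them in opposite directions;
  the defaults prioritize the venous-side pattern and the arterial
  columns follow the formula physics.
- **Noise**: per-signal AR(1) (coefficient 0.97 per sample step,
  innovation SDs 0.15–0.6 signal units), started in its stationary
  distribution; hard physiologic clip bounds; 2% missing completely at
  random per cell (time never blanked).
- **Reproducibility**: one RNG stream per patient at a fixed offset from
  the master seed, so patient k is bit-identical whatever the cohort
  size.

What the generator does *not* emulate: waveform morphology, drug
onset/offset kinetics, measurement artifacts, informative (non-MCAR)
missingness, interventions other than the eight infusions (fluid
boluses, ventilation changes), and between-signal noise correlation.
Passing recovery tests on this generator therefore show that the
pipeline's machinery is sound — not that effects of this size are
detectable in real ICU data, where confounding by indication (sicker
patients get more drug) has no analogue here.

## Preprocessing

Wall-clock timestamps become whole seconds since ICU admission, with a
half-open [0, 48 h) analysis window; pre-admission and post-window rows
drop. Medication administration records (drug, dose, unit, timestamp)
expand onto the sample grid as last-observation-carried-forward step
functions: zero before the first record, and a charted zero is a stop
that propagates. Units are validated against the native charting unit
per drug. Missing monitor values are imputed with the patient's own
median for that signal (idempotent, never pooling across patients);
signals with no observed value at all stay absent and are flagged so
the patient can be excluded from outcomes that need them.

## Dose–response models

One `RandomForestRegressor` per outcome (MCFP, Rv, SVRi, CI, cOER,
rOER): 100 trees, minimum leaf 2, bootstrap, all features considered at
each split, predicting from relative time, an integer-ordinal patient
code, age, weight and the eight doses. Rows are split 80:20 at random
(seeded); a patient-grouped split is available behind a flag. Held-out
R² and MAE summarize fit; impurity importances (normalized, ties broken
alphabetically) summarize ranking.

Row-level splitting of strongly autocorrelated series puts
near-duplicate rows on both sides of the split, so held-out R² here
measures within-record interpolation, not generalization to new
patients — on synthetic cohorts it runs ≈ 0.98 where a grouped split
would be far lower. Read it as a fidelity check on the fitted surface,
not a clinical performance claim.

Partial dependence is computed directly (pin the dose column to each of
25 grid points between the 1st and 99th percentile of observed doses,
average predictions over a 2000-row background sample); a constant dose
column collapses to a degenerate two-point grid and a flat curve.

### Direction-of-effect calls

A drug's call (increase / decrease / neutral) summarizes its PD sweep.
Two gates must pass:

1. **Clinical deadband**: |pd(last) − pd(first)| > 0.05 · SD(outcome).
   Table-style summaries need a neutral band; a twentieth of the
   outcome's spread is the smallest change worth an arrow.
2. **Out-of-sample evidence**: the drug's held-out permutation
   importance, relative to baseline test MSE, must exceed 0.05.
   Rationale: a deep forest fitted to an unlearnable target memorizes
   noise in tiny leaves, and the few extreme-dose leaves that dominate
   both sweep endpoints give the endpoint delta a sampling noise of
   order 0.1·SD — above any deadband that would still admit weak real
   effects. Between-tree agreement cannot rescue the deadband (trees
   share the training data and memorize the same extreme points), but
   a memorized dose column has no *out-of-sample* predictive value,
   while even the weakest genuinely injected effect raises held-out
   MSE by >15% when permuted versus <1% under the null — a separation
   of more than an order of magnitude on either side of the 0.05
   threshold. Five permutation repeats on a 2000-row held-out sample.

## Problem sizes and numerical choices

- Sign-recovery experiments run 10 patients × 48 h at 30 s sampling
  (57,600 rows), five seeds, recovering ≥ 7/8 injected signs per venous
  outcome — sized so a full five-seed experiment completes in minutes
  on one core; recovery margins were comfortable at this resolution.
- Operating-point bisection tolerance 1e-9 mmHg; oracle-equivalence
  testing of the derivation pipeline at 1e-12 relative; BSA consistency
  enforced at 1e-9.
- Even-count medians are the mean of the central pair (pandas
  convention). All RNG flows from explicit seeds; reruns are
  byte-identical.

## Known limitations

- MCFP/Rv estimates inherit every assumption of the estimating
  equations (fixed Hb, NIRS-as-SvO2, regression-estimated VO2); they
  are bedside indices, not gold-standard measurements.
- Direction calls are associational. The generator has no confounding,
  so recovery there says nothing about causal validity in real data.
- The SVRi/Rv structural coupling above means arterial-side direction
  columns on synthetic cohorts are constrained by the venous-side
  calibration.
- The relevance-gate threshold (0.05) was sized against this
  generator's noise regime; very low signal-to-noise clinical data may
  need a smaller threshold to avoid over-calling neutral.
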