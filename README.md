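# guyton-bedside

Bedside estimation of Guytonian venous parameters — mean circulatory
filling pressure (MCFP) and venous resistance (Rv) — from routine
high-frequency ICU monitoring signals, with random-forest
characterization of vasoactive drug dose–response.

## Who this is for

Intensive-care management usually watches the arterial side (blood
pressure, systemic vascular resistance). In Guyton's model of the
circulation it is the *venous* side that sets steady-state cardiac
output: venous return flows down the gradient from the mean circulatory
filling pressure to right-atrial pressure, through the venous
resistance,

    VR(RAP) = (MCFP − RAP) / Rv ,

and the heart operates where this line crosses its cardiac-function
curve. This package is for clinician-scientists and computational
physiologists who want to estimate MCFP and Rv continuously from
signals every monitored ICU patient already has, and to ask how
vasoactive infusions (epinephrine, norepinephrine, milrinone,
vasopressin, calcium chloride, nitroprusside, nicardipine,
phenylephrine) move them.

Per monitoring sample, the package derives estimated oxygen consumption
(regression in log age/weight), cardiac index by the Fick principle
with renal NIRS as the venous-saturation surrogate, indexed systemic
vascular resistance (MAP − CVP)·80/CI, MCFP = 0.96·CVP + 0.04·MAP +
0.2·CO, Rv = (MCFP − CVP)/CO, and cerebral/renal oxygen extraction
ratios. One random forest per derived outcome (100 trees, minimum leaf
2, bootstrap, 80:20 held-out split) then yields feature-importance
rankings, partial-dependence curves per drug, and
increase/decrease/neutral direction-of-effect calls.

Because real data of this kind cannot be shared, the package includes a
first-class synthetic cohort generator — per-patient baselines, slow
postoperative trends, piecewise-constant infusion schedules in native
units, saturating monotone dose effects with known injected signs,
AR(1) noise, random missingness — so every claim the pipeline makes can
be tested against a known ground truth.

## Worked example

```python
import guyton_bedside as gb

# a 3-year-old, 14 kg, critically ill, Hb 12 g/dL, BSA 0.62 m2
vo2 = gb.estimate_vo2(age_years=3.0, weight_kg=14.0,
                      single_ventricle=0, critical_illness=1)
ci = gb.fick_cardiac_index(vo2, sao2_frac=0.97, svo2_frac=0.72,
                           hemoglobin_g_dl=12.0)
co = ci * 0.62
print(f"VO2i = {vo2:.1f} mL/min/m2")
print(f"CI   = {ci:.2f} L/min/m2;  CO = {co:.2f} L/min")
print(f"SVRi = {gb.svri(62.0, 8.0, ci):.0f} dyn.s.cm-5.m2")
m = gb.mcfp(8.0, 62.0, co)
rv = gb.venous_resistance(m, 8.0, co)
print(f"MCFP = {m:.2f} mmHg")
print(f"Rv   = {rv:.2f} mmHg/(L/min)")
diag = gb.guyton_diagram(m, rv)
print(f"operating point: RAP = {diag.operating_point[0]:.2f} mmHg, "
      f"flow = {diag.operating_point[1]:.2f} L/min")
```

prints

```
VO2i = 151.8 mL/min/m2
CI   = 3.72 L/min/m2;  CO = 2.31 L/min
SVRi = 1161 dyn.s.cm-5.m2
MCFP = 10.62 mmHg
Rv   = 1.14 mmHg/(L/min)
operating point: RAP = 6.16 mmHg, flow = 3.93 L/min
```

Reading it: with MAP 62, CVP 8 and an arteriovenous saturation gap of
25 points, Fick puts this child's cardiac index at 3.7 L/min/m². The
estimated filling pressure of 10.6 mmHg sits 2.6 mmHg above the CVP;
that gradient over 2.3 L/min of venous return gives Rv ≈ 1.1 mmHg per
L/min. The Guyton diagram intersects this venous-return line with a
default saturating cardiac-function curve to locate the operating
point. (CI and CO scale with the assumed hemoglobin and VO2 estimate —
treat absolute values as indices; see `docs/methods.md`.)

An end-to-end run — generate a cohort, impute, derive, fit all six
outcome forests, render summary tables and Guyton diagrams:

```bash
guyton-bedside run --out demo_run/ --seed 11     # default 10 patients x 48 h
```

or in Python with a smaller cohort:

```python
from guyton_bedside import SyntheticConfig
from guyton_bedside.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=11, synthetic=SyntheticConfig(
    n_patients=4, duration_s=43_200, sample_interval_s=60))
run_pipeline(cfg, "demo_run")
```

`demo_run/` then contains the cohort CSVs and manifest, the feature
table, per-outcome model JSONs (`r2`, `mae`, importance ranking, PD
curves, direction calls), a ranking matrix and a direction-of-effect
matrix (cells in {↑, ↓, blank}), per-drug Guyton venous-return figures,
and a run log. On the 4-patient demo above the MCFP model reports
held-out R² = 0.982, MAE = 0.212 mmHg, and the direction matrix marks
epinephrine, norepinephrine and vasopressin as raising MCFP with
milrinone, nitroprusside and nicardipine lowering it — the venous
pattern the generator injects. (Held-out R² under row-level splitting
of autocorrelated series measures interpolation, not new-patient
generalization; see `docs/methods.md`.)

## Layout

- `src/guyton_bedside/synthetic.py` — cohort generator (study conditions as code)
- `src/guyton_bedside/preprocessing.py` — time alignment, dose collation, imputation, feature assembly
- `src/guyton_bedside/hemodynamics.py` — derived parameters and Guyton diagrams
- `src/guyton_bedside/modeling.py` — per-outcome forests, partial dependence, direction calls
- `src/guyton_bedside/pipeline.py`, `cli.py` — orchestration, reporting, command line
- `docs/methods.md` — model assumptions, parameter choices, limitations
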