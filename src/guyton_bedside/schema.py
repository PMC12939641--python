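"""Column vocabularies shared across the pipeline.

Every tabular artifact in the package (vitals, doses, derived
hemodynamics, model features) uses the column names defined here, in the
order defined here. Keeping the vocabulary in one module means schema
drift shows up as an import-time error rather than a silent join bug.
"""

from __future__ import annotations

#: Monitored signals sampled on the 1 Hz (configurable) grid.
VITAL_SIGNALS: tuple[str, ...] = (
    "hr",      # heart rate, beats/min (telemetry)
    "sbp",     # systolic arterial pressure, mmHg
    "map",     # mean arterial pressure, mmHg
    "dbp",     # diastolic arterial pressure, mmHg
    "rr",      # respiratory rate, breaths/min
    "sao2",    # arterial oxygen saturation, %
    "cvp",     # central venous pressure, mmHg
    "cnirs",   # cerebral near-infrared spectroscopy, %
    "rnirs",   # renal near-infrared spectroscopy, %
)

VITALS_COLUMNS: tuple[str, ...] = ("time_s", *VITAL_SIGNALS)

#: The eight vasoactive infusions, in their native charting units.
DRUGS: tuple[str, ...] = (
    "epinephrine",       # mcg/kg/min
    "norepinephrine",    # mcg/kg/min
    "milrinone",         # mcg/kg/min
    "vasopressin",       # milliunits/kg/min
    "phenylephrine",     # mcg/kg/min
    "calcium_chloride",  # mg/kg/hr
    "nitroprusside",     # mcg/kg/min
    "nicardipine",       # mcg/kg/min
)

DOSE_UNITS: dict[str, str] = {
    "epinephrine": "mcg/kg/min",
    "norepinephrine": "mcg/kg/min",
    "milrinone": "mcg/kg/min",
    "vasopressin": "milliunits/kg/min",
    "phenylephrine": "mcg/kg/min",
    "calcium_chloride": "mg/kg/hr",
    "nitroprusside": "mcg/kg/min",
    "nicardipine": "mcg/kg/min",
}

DOSES_COLUMNS: tuple[str, ...] = ("time_s", *DRUGS)

#: Derived hemodynamic quantities, one column per row-wise formula.
DERIVED_COLUMNS: tuple[str, ...] = (
    "time_s",
    "vo2i",   # estimated oxygen consumption, mL O2/min/m^2
    "ci",     # cardiac index, L/min/m^2
    "co",     # cardiac output, L/min
    "svri",   # indexed systemic vascular resistance, dyn*s*cm^-5*m^2
    "mcfp",   # mean circulatory filling pressure, mmHg
    "rv",     # venous resistance, mmHg per L/min
    "coer",   # cerebral oxygen extraction ratio, fraction
    "roer",   # renal oxygen extraction ratio, fraction
)

#: Modelled outcomes (one random forest per outcome).
OUTCOMES: tuple[str, ...] = ("mcfp", "rv", "svri", "ci", "coer", "roer")

#: Predictors entering the forests: relative time, patient identifier,
#: age, weight, and the eight infusion doses.
FEATURE_COLUMNS: tuple[str, ...] = (
    "time_s",
    "patient_id",
    "age_years",
    "weight_kg",
    *DRUGS,
)
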