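"""Synthetic post-transplant cohort generator.

Real high-frequency ICU monitoring data of the kind this package analyses
is not shareable, so the package carries a first-class simulator of a
pediatric post-heart-transplant cohort: per-patient demographic profiles,
1 Hz (configurable) vital-sign streams, and piecewise-constant vasoactive
infusion schedules in native charting units.

The generative model per patient and signal is

    x(t) = baseline + trend * t_hours
           + sum over drugs of  effect[drug, signal] * sat(dose_t)
           + AR(1) noise,                       then clipped to bounds,

where ``sat(d) = d / (d + k)`` is a saturating Michaelis-Menten-style
response with half-dose ``k`` at the drug's mid-range, so effects are
monotone in dose, zero at zero dose, and approach the configured
asymptotic magnitude. Effects act instantaneously on the raw monitored
signals (no pharmacokinetics); the derived venous parameters then inherit
dose responses through the derivation formulas.

The default effect table is calibrated so that the *derived* mean
circulatory filling pressure and venous resistance respond to each drug
with the direction-of-effect pattern the package's modelling stage is
meant to recover (see ``DEFAULT_OUTCOME_SIGNS``). Note one structural
constraint of the derivations: indexed systemic vascular resistance and
venous resistance are both monotone functions of (MAP - CVP)/flow within
a patient, so no choice of raw-signal effects can move them in opposite
directions; the defaults prioritise the venous-side pattern.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .schema import DOSE_UNITS, DRUGS, VITAL_SIGNALS, VITALS_COLUMNS

__all__ = [
    "ConfigError",
    "PatientProfile",
    "SyntheticConfig",
    "Cohort",
    "generate_cohort",
    "generate_profile",
    "generate_dose_schedule",
    "apply_effect_model",
    "inject_missingness",
    "mosteller_bsa",
    "DEFAULT_EFFECTS",
    "DEFAULT_OUTCOME_SIGNS",
]


class ConfigError(ValueError):
    """A synthetic-cohort configuration field is invalid."""


def mosteller_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area, m^2, by the Mosteller square-root formula."""
    return float(np.sqrt(height_cm * weight_kg / 3600.0))


@dataclass(frozen=True)
class PatientProfile:
    """Demographics and physiologic constants the derivations need."""

    patient_id: str
    age_years: float
    weight_kg: float
    height_cm: float
    bsa_m2: float
    single_ventricle: int
    critical_illness: int
    hemoglobin_g_dl: float

    def __post_init__(self) -> None:
        for name in ("age_years", "weight_kg", "height_cm", "bsa_m2", "hemoglobin_g_dl"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"PatientProfile.{name} must be > 0")
        for name in ("single_ventricle", "critical_illness"):
            if getattr(self, name) not in (0, 1):
                raise ConfigError(f"PatientProfile.{name} must be 0 or 1")
        if abs(self.bsa_m2 - mosteller_bsa(self.height_cm, self.weight_kg)) > 1e-9:
            raise ConfigError("PatientProfile.bsa_m2 inconsistent with Mosteller formula")


# --------------------------------------------------------------------------
# Default study conditions
# --------------------------------------------------------------------------

#: Asymptotic drug effects on raw signals, signal units at saturating dose.
#: Sign is the sign of the entry; magnitude its absolute value. Signals not
#: listed are unaffected. Phenylephrine is charted but dosed zero by
#: default, so it carries no effect entries.
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "epinephrine": {
        "hr": 20.0, "sbp": 22.0, "map": 20.0, "dbp": 17.0,
        "cvp": 4.0, "rnirs": 1.0, "cnirs": 4.0,
    },
    "norepinephrine": {
        "hr": 5.0, "sbp": 18.0, "map": 16.0, "dbp": 14.0,
        "cvp": 3.5, "rnirs": -1.5, "cnirs": -2.0,
    },
    "milrinone": {
        "hr": 8.0, "sbp": -8.0, "map": -7.0, "dbp": -6.0,
        "cvp": -2.5, "rnirs": 3.5, "cnirs": 3.5,
    },
    "vasopressin": {
        "hr": -5.0, "sbp": 15.0, "map": 14.0, "dbp": 13.0,
        "cvp": 3.0, "rnirs": -2.0, "cnirs": -2.5,
    },
    "phenylephrine": {},
    "calcium_chloride": {
        "map": -1.5, "sbp": -1.5, "dbp": -1.5,
        "rnirs": 5.0, "cnirs": 1.5,
    },
    "nitroprusside": {
        "hr": 5.0, "sbp": -14.0, "map": -12.0, "dbp": -10.0,
        "cvp": -2.5, "rnirs": 2.5, "cnirs": 2.5,
    },
    "nicardipine": {
        "hr": 6.0, "sbp": -12.0, "map": -10.0, "dbp": -8.0,
        "cvp": -1.5, "rnirs": -4.0, "cnirs": 2.0,
    },
}

#: Direction of effect the DEFAULT_EFFECTS table injects on the derived
#: venous parameters (+1 increase, -1 decrease, 0 neutral). These are the
#: ground-truth signs a successful end-to-end dose-response analysis
#: should recover.
DEFAULT_OUTCOME_SIGNS: dict[str, dict[str, int]] = {
    "mcfp": {
        "epinephrine": +1, "norepinephrine": +1, "milrinone": -1,
        "vasopressin": +1, "phenylephrine": 0, "calcium_chloride": 0,
        "nitroprusside": -1, "nicardipine": -1,
    },
    "rv": {
        "epinephrine": +1, "norepinephrine": +1, "milrinone": -1,
        "vasopressin": +1, "phenylephrine": 0, "calcium_chloride": -1,
        "nitroprusside": -1, "nicardipine": 0,
    },
}

#: Slow postoperative drift, signal units per hour.
DEFAULT_TIME_TREND: dict[str, float] = {
    "hr": -0.4, "sbp": 0.17, "map": 0.15, "dbp": 0.13, "rr": -0.05,
    "sao2": 0.0, "cvp": -0.04, "cnirs": 0.06, "rnirs": 0.05,
}

#: AR(1) coefficient (per sample step) and innovation SD per signal.
DEFAULT_NOISE: dict[str, tuple[float, float]] = {
    "hr": (0.97, 0.5), "sbp": (0.97, 0.6), "map": (0.97, 0.5),
    "dbp": (0.97, 0.5), "rr": (0.97, 0.3), "sao2": (0.97, 0.15),
    "cvp": (0.97, 0.25), "cnirs": (0.97, 0.4), "rnirs": (0.97, 0.4),
}

#: Hard physiologic clip bounds per signal.
DEFAULT_CLIP_BOUNDS: dict[str, tuple[float, float]] = {
    "hr": (40.0, 220.0), "sbp": (30.0, 200.0), "map": (20.0, 150.0),
    "dbp": (15.0, 120.0), "rr": (5.0, 80.0), "sao2": (50.0, 100.0),
    "cvp": (0.0, 30.0), "cnirs": (15.0, 95.0), "rnirs": (15.0, 95.0),
}

#: Dose range per drug in native units; phenylephrine is charted at zero.
DEFAULT_DOSE_RANGES: dict[str, tuple[float, float]] = {
    "epinephrine": (0.0, 0.1),
    "norepinephrine": (0.0, 0.1),
    "milrinone": (0.0, 1.0),
    "vasopressin": (0.0, 1.0),
    "phenylephrine": (0.0, 0.0),
    "calcium_chloride": (0.0, 20.0),
    "nitroprusside": (0.0, 4.0),
    "nicardipine": (0.0, 3.0),
}

#: Relative frequency of the cohort's age strata (<1, 1-5, 6-10, >10 y).
AGE_STRATA: tuple[tuple[float, float], ...] = ((0.1, 1.0), (1.0, 6.0), (6.0, 11.0), (11.0, 18.0))
AGE_STRATA_WEIGHTS: tuple[float, ...] = (10.0, 11.0, 5.0, 20.0)

#: Offset multiplier deriving one RNG stream per patient from the master
#: seed, so patient k is reproducible regardless of cohort size.
PATIENT_SEED_STRIDE = 10_007


@dataclass
class SyntheticConfig:
    """Study conditions for a simulated cohort.

    Defaults describe a 48 h postoperative window sampled at 1 s, eight
    vasoactive infusions with the package's calibrated effect table,
    AR(1) measurement noise, and 2% missing-completely-at-random cells.
    """

    n_patients: int = 10
    duration_s: int = 172_800          # 48 h
    sample_interval_s: int = 1
    drugs: tuple[str, ...] = DRUGS
    effect_spec: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {d: dict(v) for d, v in DEFAULT_EFFECTS.items()})
    time_trend: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TIME_TREND))
    noise: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NOISE))
    clip_bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLIP_BOUNDS))
    dose_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_RANGES))
    mean_dose_changes_per_48h: float = 20.0
    p_dose_zero: float = 0.3           # chance a schedule segment is off
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.sample_interval_s <= 0:
            raise ConfigError("sample_interval_s must be > 0")
        if self.duration_s <= 0 or self.duration_s % self.sample_interval_s != 0:
            raise ConfigError("duration_s must be a positive multiple of sample_interval_s")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.p_dose_zero <= 1.0:
            raise ConfigError("p_dose_zero must be in [0, 1]")
        if self.mean_dose_changes_per_48h < 0:
            raise ConfigError("mean_dose_changes_per_48h must be >= 0")
        for sig, (phi, sd) in self.noise.items():
            if not 0.0 <= phi < 1.0:
                raise ConfigError(f"noise AR(1) coefficient for '{sig}' must be in [0, 1)")
            if sd < 0:
                raise ConfigError(f"noise innovation SD for '{sig}' must be >= 0")
        for drug in self.drugs:
            lo, hi = self.dose_ranges.get(drug, (0.0, 0.0))
            if lo < 0 or hi < lo:
                raise ConfigError(f"dose_ranges['{drug}'] must satisfy 0 <= lo <= hi")
        unknown = set(self.effect_spec) - set(self.drugs)
        if unknown:
            raise ConfigError(f"effect_spec for unknown drugs: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return self.duration_s // self.sample_interval_s

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_samples, dtype=np.int64) * self.sample_interval_s

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drugs"] = list(self.drugs)
        d["noise"] = {k: list(v) for k, v in self.noise.items()}
        d["clip_bounds"] = {k: list(v) for k, v in self.clip_bounds.items()}
        d["dose_ranges"] = {k: list(v) for k, v in self.dose_ranges.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "drugs" in d:
            d["drugs"] = tuple(d["drugs"])
        for key in ("noise", "clip_bounds", "dose_ranges"):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        return cls(**d)


class Cohort(NamedTuple):
    profiles: list[PatientProfile]
    vitals: list[pd.DataFrame]
    doses: list[pd.DataFrame]


# --------------------------------------------------------------------------
# Profiles
# --------------------------------------------------------------------------

def _weight_for_age(age: float) -> float:
    # Coarse pediatric growth curve, kg.
    if age < 1.0:
        return 3.3 + 6.0 * age
    if age < 6.0:
        return 9.3 + 2.2 * (age - 1.0)
    if age < 11.0:
        return 20.3 + 3.0 * (age - 6.0)
    return min(35.3 + 4.5 * (age - 11.0), 75.0)


def _height_for_age(age: float) -> float:
    # Coarse pediatric growth curve, cm.
    if age < 1.0:
        return 50.0 + 25.0 * age
    if age < 6.0:
        return 75.0 + 8.5 * (age - 1.0)
    if age < 11.0:
        return 117.5 + 5.5 * (age - 6.0)
    return min(145.0 + 3.5 * (age - 11.0), 178.0)


def generate_profile(patient_id: str, rng: np.random.Generator) -> PatientProfile:
    """Draw one patient profile from the cohort's age-stratified mix."""
    w = np.asarray(AGE_STRATA_WEIGHTS) / sum(AGE_STRATA_WEIGHTS)
    lo, hi = AGE_STRATA[rng.choice(len(AGE_STRATA), p=w)]
    age = float(rng.uniform(lo, hi))
    weight = _weight_for_age(age) * float(rng.lognormal(0.0, 0.12))
    height = _height_for_age(age) * float(rng.normal(1.0, 0.04))
    height = max(height, 45.0)
    return PatientProfile(
        patient_id=patient_id,
        age_years=age,
        weight_kg=weight,
        height_cm=height,
        bsa_m2=mosteller_bsa(height, weight),
        single_ventricle=int(rng.random() < 0.15),
        critical_illness=int(rng.random() < 0.5),
        hemoglobin_g_dl=float(rng.uniform(10.0, 15.0)),
    )


def _baseline_signals(profile: PatientProfile, rng: np.random.Generator) -> dict[str, float]:
    """Age-appropriate resting values for one patient, signal units."""
    age = profile.age_years
    hr0 = 130.0 - 40.0 * min(age, 18.0) / 18.0 + rng.uniform(-10.0, 10.0)
    map0 = rng.uniform(55.0, 75.0)
    pp = rng.uniform(25.0, 45.0)                 # pulse pressure
    rr0 = max(40.0 - 1.5 * min(age, 16.0), 14.0) + rng.uniform(-3.0, 3.0)
    return {
        "hr": hr0,
        "sbp": map0 + 2.0 * pp / 3.0,
        "map": map0,
        "dbp": map0 - pp / 3.0,
        "rr": rr0,
        "sao2": rng.uniform(96.0, 100.0),
        "cvp": rng.uniform(6.0, 12.0),
        "cnirs": rng.uniform(55.0, 80.0),
        "rnirs": rng.uniform(65.0, 80.0),
    }


# --------------------------------------------------------------------------
# Dose schedules
# --------------------------------------------------------------------------

def generate_dose_schedule(
    drug: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.Series:
    """Piecewise-constant infusion schedule for one drug, native units.

    The number of dose changes over the window is Poisson with the
    configured 48 h mean (scaled to the window length); change times are
    uniform; each segment's level is 0 with probability ``p_dose_zero``
    and otherwise uniform over the drug's dose range.
    """
    if drug not in config.drugs:
        raise ConfigError(f"unknown drug '{drug}'; known drugs: {list(config.drugs)}")
    lo, hi = config.dose_ranges.get(drug, (0.0, 0.0))
    t = config.time_grid
    if hi == 0.0:
        return pd.Series(np.zeros(len(t)), name=drug)

    mean_changes = config.mean_dose_changes_per_48h * config.duration_s / 172_800.0
    n_changes = int(rng.poisson(mean_changes))
    change_times = np.sort(rng.uniform(0.0, config.duration_s, size=n_changes))

    def draw_level() -> float:
        if rng.random() < config.p_dose_zero:
            return 0.0
        return float(rng.uniform(lo, hi))

    levels = np.array([draw_level() for _ in range(n_changes + 1)])
    seg = np.searchsorted(change_times, t, side="right")
    return pd.Series(levels[seg], name=drug)


def _dose_frame(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    cols = {"time_s": config.time_grid}
    for drug in config.drugs:
        cols[drug] = generate_dose_schedule(drug, config, rng).to_numpy()
    return pd.DataFrame(cols)


# --------------------------------------------------------------------------
# Effect model
# --------------------------------------------------------------------------

def saturating_response(dose, half_dose: float):
    """Monotone saturating dose transform d / (d + k), zero at zero dose."""
    d = np.asarray(dose, dtype=float)
    if half_dose <= 0:
        return np.zeros_like(d)
    return d / (d + half_dose)


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) sample path of length n."""
    if sd == 0.0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd, size=n)
    # start from the stationary distribution so early samples are typical
    innov[0] /= np.sqrt(1.0 - phi * phi)
    return lfilter([1.0], [1.0, -phi], innov)


def apply_effect_model(
    baseline: pd.DataFrame,
    doses: pd.DataFrame,
    effect_spec: Mapping[str, Mapping[str, float]],
    time_trend: Mapping[str, float],
    noise: Mapping[str, tuple[float, float]],
    rng: np.random.Generator,
    dose_ranges: Mapping[str, tuple[float, float]] | None = None,
    clip_bounds: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Turn baselines + dose schedules into a noisy vitals frame.

    The expected value of each signal at time t is
    baseline + trend * t_hours + sum over drugs of
    effect * sat(dose_t); AR(1) noise is added around that mean and the
    result clipped to physiologic bounds (if given).
    """
    if not np.array_equal(baseline["time_s"].to_numpy(), doses["time_s"].to_numpy()):
        raise ValueError("baseline and dose frames are not on the same time grid")
    dose_ranges = dose_ranges or DEFAULT_DOSE_RANGES
    t_hours = baseline["time_s"].to_numpy(dtype=float) / 3600.0
    out = {"time_s": baseline["time_s"].to_numpy()}
    for sig in VITAL_SIGNALS:
        mean = baseline[sig].to_numpy(dtype=float) + time_trend.get(sig, 0.0) * t_hours
        for drug, effects in effect_spec.items():
            mag = effects.get(sig, 0.0)
            if mag == 0.0 or drug not in doses.columns:
                continue
            lo, hi = dose_ranges.get(drug, (0.0, 0.0))
            half = (lo + hi) / 2.0
            mean = mean + mag * saturating_response(doses[drug].to_numpy(), half)
        phi, sd = noise.get(sig, (0.0, 0.0))
        x = mean + _ar1(len(mean), phi, sd, rng)
        if clip_bounds and sig in clip_bounds:
            x = np.clip(x, *clip_bounds[sig])
        out[sig] = x
    return pd.DataFrame(out, columns=list(VITALS_COLUMNS))


def inject_missingness(
    vitals: pd.DataFrame,
    rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Blank each signal cell independently with probability ``rate``.

    Missingness is completely at random; the time column is never
    blanked.
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigError("missing_rate must be in [0, 1)")
    out = vitals.copy()
    if rate == 0.0:
        return out
    signals = [c for c in out.columns if c != "time_s"]
    mask = rng.random((len(out), len(signals))) < rate
    values = out[signals].to_numpy(dtype=float)
    values[mask] = np.nan
    out[signals] = values
    return out


# --------------------------------------------------------------------------
# Cohort assembly
# --------------------------------------------------------------------------

def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full cohort: profiles, vitals frames, dose frames.

    One RNG stream per patient is derived from the master seed by a fixed
    offset, so a given patient index reproduces identically whatever the
    cohort size. The whole cohort is bit-for-bit reproducible from
    ``config.seed``.
    """
    profiles: list[PatientProfile] = []
    vitals_list: list[pd.DataFrame] = []
    doses_list: list[pd.DataFrame] = []
    for i in range(config.n_patients):
        rng = np.random.default_rng(config.seed + PATIENT_SEED_STRIDE * (i + 1))
        profile = generate_profile(f"P{i:03d}", rng)
        doses = _dose_frame(config, rng)
        base_vals = _baseline_signals(profile, rng)
        baseline = pd.DataFrame({"time_s": config.time_grid}
                                | {s: np.full(config.n_samples, v)
                                   for s, v in base_vals.items()})
        vitals = apply_effect_model(
            baseline, doses, config.effect_spec, config.time_trend,
            config.noise, rng, config.dose_ranges, config.clip_bounds,
        )
        vitals = inject_missingness(vitals, config.missing_rate, rng)
        profiles.append(profile)
        vitals_list.append(vitals)
        doses_list.append(doses)
    return Cohort(profiles, vitals_list, doses_list)
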