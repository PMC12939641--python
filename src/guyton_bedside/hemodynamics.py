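"""Derived hemodynamics: Fick cardiac index, Guytonian venous parameters.

This module computes, row by row from monitored vitals, the derived
physiologic quantities at the core of the package:

* estimated oxygen consumption (Seckeler regression, indexed mL/min/m^2),
* cardiac index by the Fick principle with renal NIRS standing in for the
  mixed-venous saturation,
* indexed systemic vascular resistance (the x80 dyn*s*cm^-5 convention),
* mean circulatory filling pressure (MCFP) from the clinically validated
  linear combination of CVP, MAP and cardiac output,
* venous resistance Rv = (MCFP - CVP) / venous return, with venous return
  taken equal to cardiac output at steady state,
* cerebral and renal oxygen extraction ratios.

All functions are vectorized over numpy arrays and return NaN (a flagged,
undefined result — never an exception and never a fabricated value) where
a formula's preconditions fail for a particular row, e.g. a NIRS reading
at or above the arterial saturation in the Fick denominator.

The module also builds Guyton venous-return diagrams: the straight
venous-return line dropping from MCFP with slope -1/Rv, a saturating
cardiac-function curve, and their intersection (the operating point).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.optimize import bisect

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import PatientProfile

__all__ = [
    "HemoConstants",
    "CardiacFunctionCurve",
    "GuytonDiagram",
    "estimate_vo2",
    "fick_cardiac_index",
    "svri",
    "mcfp",
    "venous_resistance",
    "oxygen_extraction",
    "derive_all",
    "guyton_diagram",
]

#: mL O2 bound per gram of hemoglobin (Hüfner constant as used clinically).
O2_CAPACITY_ML_PER_G = 1.36


@dataclass(frozen=True)
class HemoConstants:
    """Physiologic conventions that the printed formulas leave open.

    Parameters
    ----------
    o2_capacity_ml_per_g:
        Oxygen-carrying capacity of hemoglobin, mL O2 per gram. Dissolved
        oxygen is ignored throughout.
    default_hemoglobin_g_dl:
        Fallback hemoglobin when a patient profile does not carry one.
        Hemoglobin is required by the Fick equation but is not part of the
        monitored stream, so it enters as a per-patient constant.
    vo2_is_indexed:
        If True (default), the estimated VO2 is treated as indexed
        (mL/min/m^2) so the Fick quotient is directly a cardiac *index*.
        If False the estimate is treated as absolute and divided by BSA.
    mcfp_flow / rv_flow:
        Whether the flow entering the MCFP formula and the venous-return
        denominator is absolute cardiac output in L/min ("absolute",
        default) or indexed L/min/m^2 ("indexed").
    """

    o2_capacity_ml_per_g: float = O2_CAPACITY_ML_PER_G
    default_hemoglobin_g_dl: float = 13.0
    vo2_is_indexed: bool = True
    mcfp_flow: str = "absolute"
    rv_flow: str = "absolute"

    def __post_init__(self) -> None:
        for name in ("mcfp_flow", "rv_flow"):
            if getattr(self, name) not in ("absolute", "indexed"):
                raise ValueError(f"{name} must be 'absolute' or 'indexed'")


def estimate_vo2(
    age_years: float,
    weight_kg: float,
    single_ventricle: int = 0,
    critical_illness: int = 0,
) -> float:
    """Estimated indexed oxygen consumption, mL O2/min/m^2.

    Linear-in-logs regression (natural logarithms):

        VO2i = 242.1 + 9.7 ln(age) - 34 ln(weight)
               - 9.6 * single_ventricle - 11.2 * critical_illness

    with age in years and weight in kg.
    """
    age = np.asarray(age_years, dtype=float)
    wt = np.asarray(weight_kg, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age_years must be > 0")
    if np.any(wt <= 0):
        raise ValueError("weight_kg must be > 0")
    out = (
        242.1
        + 9.7 * np.log(age)
        - 34.0 * np.log(wt)
        - 9.6 * np.asarray(single_ventricle, dtype=float)
        - 11.2 * np.asarray(critical_illness, dtype=float)
    )
    return out if out.ndim else float(out)


def fick_cardiac_index(
    vo2i,
    sao2_frac,
    svo2_frac,
    hemoglobin_g_dl,
    o2_capacity_ml_per_g: float = O2_CAPACITY_ML_PER_G,
):
    """Cardiac index by the Fick principle, L/min/m^2.

    CI = VO2i / (k * Hb * (SaO2 - SvO2) * 10), with saturations as
    fractions, Hb in g/dL and the factor 10 converting dL to L. The renal
    NIRS value is the usual surrogate for SvO2. Rows where SvO2 >= SaO2
    (no arteriovenous gradient, Fick undefined) yield NaN.
    """
    vo2i = np.asarray(vo2i, dtype=float)
    sao2 = np.asarray(sao2_frac, dtype=float)
    svo2 = np.asarray(svo2_frac, dtype=float)
    hb = np.asarray(hemoglobin_g_dl, dtype=float)
    denom = o2_capacity_ml_per_g * hb * (sao2 - svo2) * 10.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((sao2 > svo2) & (hb > 0), vo2i / denom, np.nan)
    return out if out.ndim else float(out)


def svri(map_mmHg, cvp_mmHg, ci):
    """Indexed systemic vascular resistance: (MAP - CVP) * 80 / CI.

    Units dyn*s*cm^-5*m^2 under the conventional x80 factor. NaN where
    CI <= 0 or is itself undefined.
    """
    m = np.asarray(map_mmHg, dtype=float)
    c = np.asarray(cvp_mmHg, dtype=float)
    ci = np.asarray(ci, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(ci > 0, (m - c) * 80.0 / ci, np.nan)
    return out if out.ndim else float(out)


def mcfp(cvp_mmHg, map_mmHg, co_L_min):
    """Mean circulatory filling pressure, mmHg.

    MCFP = 0.96 * CVP + 0.04 * MAP + 0.2 * CO.

    The 0.2*CO term uses cardiac output in L/min by convention here
    (see :class:`HemoConstants.mcfp_flow` for the indexed alternative).
    """
    out = (
        0.96 * np.asarray(cvp_mmHg, dtype=float)
        + 0.04 * np.asarray(map_mmHg, dtype=float)
        + 0.2 * np.asarray(co_L_min, dtype=float)
    )
    return out if out.ndim else float(out)


def venous_resistance(mcfp_mmHg, cvp_mmHg, vr_flow):
    """Venous resistance Rv = (MCFP - CVP) / VR, mmHg per L/min.

    ``vr_flow`` is the steady-state venous return, equal to cardiac
    output. NaN where flow <= 0 or undefined.
    """
    p = np.asarray(mcfp_mmHg, dtype=float)
    c = np.asarray(cvp_mmHg, dtype=float)
    q = np.asarray(vr_flow, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(q > 0, (p - c) / q, np.nan)
    return out if out.ndim else float(out)


def oxygen_extraction(sao2, nirs):
    """Regional oxygen extraction ratio: (SaO2 - NIRS) / SaO2.

    Scale-invariant, so percent or fraction inputs give the same answer.
    Negative values (NIRS above SaO2) are physiologically odd but allowed;
    NaN only where SaO2 <= 0.
    """
    s = np.asarray(sao2, dtype=float)
    n = np.asarray(nirs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(s > 0, (s - n) / s, np.nan)
    return out if out.ndim else float(out)


def derive_all(
    profile: "PatientProfile",
    vitals: pd.DataFrame,
    constants: HemoConstants | None = None,
) -> pd.DataFrame:
    """Apply every derivation row-wise to an (imputed) vitals frame.

    Order of application: VO2 -> CI -> CO (= CI * BSA) -> SVRi -> MCFP ->
    Rv -> oxygen extraction ratios. Undefined intermediates propagate as
    NaN; no value is ever fabricated for a flagged row.

    Saturations in ``vitals`` are percent (monitor convention) and are
    converted to fractions internally where the Fick equation needs them.
    """
    k = constants or HemoConstants()
    hb = getattr(profile, "hemoglobin_g_dl", None) or k.default_hemoglobin_g_dl

    vo2 = estimate_vo2(
        profile.age_years,
        profile.weight_kg,
        profile.single_ventricle,
        profile.critical_illness,
    )
    sao2_frac = vitals["sao2"].to_numpy(dtype=float) / 100.0
    svo2_frac = vitals["rnirs"].to_numpy(dtype=float) / 100.0

    vo2i = vo2 if k.vo2_is_indexed else vo2 / profile.bsa_m2
    ci = fick_cardiac_index(vo2i, sao2_frac, svo2_frac, hb, k.o2_capacity_ml_per_g)
    co = ci * profile.bsa_m2

    map_a = vitals["map"].to_numpy(dtype=float)
    cvp_a = vitals["cvp"].to_numpy(dtype=float)

    svri_a = svri(map_a, cvp_a, ci)
    mcfp_a = mcfp(cvp_a, map_a, co if k.mcfp_flow == "absolute" else ci)
    rv_flow = co if k.rv_flow == "absolute" else ci
    rv_a = venous_resistance(mcfp_a, cvp_a, rv_flow)

    coer = oxygen_extraction(vitals["sao2"].to_numpy(dtype=float),
                             vitals["cnirs"].to_numpy(dtype=float))
    roer = oxygen_extraction(vitals["sao2"].to_numpy(dtype=float),
                             vitals["rnirs"].to_numpy(dtype=float))

    return pd.DataFrame(
        {
            "time_s": vitals["time_s"].to_numpy(),
            "vo2i": np.broadcast_to(np.asarray(vo2i, dtype=float), len(vitals)).copy(),
            "ci": ci,
            "co": co,
            "svri": svri_a,
            "mcfp": mcfp_a,
            "rv": rv_a,
            "coer": coer,
            "roer": roer,
        }
    )


@dataclass(frozen=True)
class CardiacFunctionCurve:
    """Saturating Starling-form cardiac function curve.

    flow(RAP) = Fmax * (1 - exp(-(RAP - rap0) / tau)), clipped at 0.

    Monotone non-decreasing in right-atrial pressure and plateauing at
    ``f_max`` — any such family suffices for operating-point work; this
    exponential form is the package's default.
    """

    f_max_L_min: float = 5.0
    rap0_mmHg: float = 0.0
    tau_mmHg: float = 4.0

    def __post_init__(self) -> None:
        if self.f_max_L_min <= 0 or self.tau_mmHg <= 0:
            raise ValueError("f_max_L_min and tau_mmHg must be > 0")

    def __call__(self, rap):
        rap = np.asarray(rap, dtype=float)
        out = np.maximum(
            0.0, self.f_max_L_min * (1.0 - np.exp(-(rap - self.rap0_mmHg) / self.tau_mmHg))
        )
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class GuytonDiagram:
    """Sampled venous-return line and cardiac curve plus their crossing.

    ``operating_point`` is ``None`` when the curves do not intersect on
    the requested right-atrial-pressure bracket.
    """

    rap_grid: np.ndarray
    vr_line: np.ndarray
    cardiac_curve: np.ndarray
    operating_point: tuple[float, float] | None
    mcfp_mmHg: float
    rv_mmHg_per_L_min: float
    condition_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rap_mmHg": self.rap_grid,
                "venous_return_L_min": self.vr_line,
                "cardiac_output_L_min": self.cardiac_curve,
            }
        )


#: Bisection tolerance on the operating-point RAP, mmHg.
OPERATING_POINT_XTOL = 1e-9


def guyton_diagram(
    mcfp_mmHg: float,
    rv_mmHg_per_L_min: float,
    cardiac_curve: CardiacFunctionCurve | None = None,
    rap_grid: np.ndarray | None = None,
    rap_min_mmHg: float = 0.0,
    n_grid: int = 201,
    condition_label: str = "",
) -> GuytonDiagram:
    """Construct a Guyton venous-return / cardiac-output diagram.

    The venous-return line is VR(RAP) = (MCFP - RAP) / Rv: affine,
    strictly decreasing, crossing zero exactly at RAP = MCFP. The
    operating point solves VR(RAP) = cardiac_curve(RAP) by bisection on
    [rap_min, MCFP] to ``OPERATING_POINT_XTOL`` mmHg.
    """
    if rv_mmHg_per_L_min <= 0:
        raise ValueError("rv_mmHg_per_L_min must be > 0")
    curve = cardiac_curve or CardiacFunctionCurve()
    if rap_grid is None:
        if rap_min_mmHg >= mcfp_mmHg:
            raise ValueError("rap_min_mmHg must be below mcfp_mmHg")
        rap_grid = np.linspace(rap_min_mmHg, mcfp_mmHg, n_grid)
    else:
        rap_grid = np.asarray(rap_grid, dtype=float)
        rap_min_mmHg = float(rap_grid[0])

    def vr(rap):
        return (mcfp_mmHg - np.asarray(rap, dtype=float)) / rv_mmHg_per_L_min

    # g is strictly decreasing: vr falls, the cardiac curve rises.
    def g(rap):
        return float(vr(rap) - curve(rap))

    lo, hi = float(rap_min_mmHg), float(mcfp_mmHg)
    g_lo, g_hi = g(lo), g(hi)
    operating: tuple[float, float] | None
    if g_lo < 0:
        # Cardiac curve already above the VR line at the left edge.
        operating = None
    elif g_hi == 0.0:
        operating = (hi, 0.0)
    else:
        rap_star = float(bisect(g, lo, hi, xtol=OPERATING_POINT_XTOL))
        operating = (rap_star, float(vr(rap_star)))

    return GuytonDiagram(
        rap_grid=rap_grid,
        vr_line=vr(rap_grid),
        cardiac_curve=curve(rap_grid),
        operating_point=operating,
        mcfp_mmHg=float(mcfp_mmHg),
        rv_mmHg_per_L_min=float(rv_mmHg_per_L_min),
        condition_label=condition_label,
    )
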