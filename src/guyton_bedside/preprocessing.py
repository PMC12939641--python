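"""Time alignment, dose collation, imputation, and feature assembly.

Raw monitoring exports and medication-administration records arrive on
wall-clock timestamps; the analysis runs on a patient-relative axis with
time 0 at ICU admission and a half-open 48 h window. Infusion records
are events (drug, dose, timestamp) and are expanded onto the sample grid
as a last-observation-carried-forward step function — an infusion runs at
its most recently charted rate until the next charted change, and a
charted rate of zero is a stop that propagates. Missing monitor values
are imputed with the patient's own median for that signal; no information
ever crosses patients.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schema import DOSE_UNITS, DRUGS, FEATURE_COLUMNS, OUTCOMES, VITAL_SIGNALS

__all__ = [
    "ANALYSIS_WINDOW_S",
    "normalize_time",
    "collate_doses",
    "impute_patient_median",
    "build_feature_table",
]

log = logging.getLogger(__name__)

#: First 48 postoperative hours, half-open [0, 172800) seconds.
ANALYSIS_WINDOW_S = 172_800


def normalize_time(
    raw_timestamps,
    admission_timestamp,
    window_s: int = ANALYSIS_WINDOW_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert wall-clock timestamps to whole seconds since admission.

    Accepts datetime-like or numeric-seconds inputs. Samples before
    admission or at/after ``window_s`` are dropped. Returns
    ``(relative_seconds, keep_mask)`` where the mask indexes the original
    array; differences between retained timestamps are preserved exactly
    (the transform is a pure shift).
    """
    ts = pd.Series(raw_timestamps)
    if pd.api.types.is_datetime64_any_dtype(ts) or isinstance(
        admission_timestamp, (pd.Timestamp, np.datetime64)
    ):
        rel = (pd.to_datetime(ts) - pd.Timestamp(admission_timestamp)).dt.total_seconds()
    else:
        rel = ts.astype(float) - float(admission_timestamp)
    rel = np.floor(rel.to_numpy()).astype(np.int64)
    keep = (rel >= 0) & (rel < window_s)
    if not keep.any():
        warnings.warn("no samples fall inside the analysis window", stacklevel=2)
    return rel[keep], keep


def collate_doses(
    events: pd.DataFrame,
    time_grid,
    drugs: Sequence[str] = DRUGS,
    validate_units: bool = True,
) -> pd.DataFrame:
    """Expand administration-record events onto the sample grid.

    ``events`` has columns ``time_s``, ``drug``, ``dose`` and optionally
    ``unit``. The dose at grid time t is the most recent recorded dose at
    or before t (right-continuous step function), zero before a drug's
    first record. A recorded dose of zero is a stop and propagates.
    """
    grid = np.asarray(time_grid, dtype=np.int64)
    out = {"time_s": grid}
    if len(events) and (events["dose"] < 0).any():
        bad = events.loc[events["dose"] < 0]
        raise ValueError(f"negative doses in administration records: rows {list(bad.index)}")
    unknown = set(events["drug"]) - set(drugs) if len(events) else set()
    if unknown:
        raise ValueError(
            f"unknown drugs in administration records: {sorted(unknown)}; "
            f"known drugs: {list(drugs)}"
        )
    if validate_units and len(events) and "unit" in events.columns:
        for drug, unit in events[["drug", "unit"]].drop_duplicates().itertuples(index=False):
            expected = DOSE_UNITS.get(drug)
            if expected is not None and unit != expected:
                raise ValueError(
                    f"dose unit mismatch for {drug}: got '{unit}', expected '{expected}'"
                )
    for drug in drugs:
        sub = events[events["drug"] == drug].sort_values("time_s", kind="stable") \
            if len(events) else events
        if len(sub) == 0:
            out[drug] = np.zeros(len(grid))
            continue
        times = sub["time_s"].to_numpy(dtype=float)
        doses = sub["dose"].to_numpy(dtype=float)
        idx = np.searchsorted(times, grid, side="right") - 1
        col = np.where(idx >= 0, doses[np.clip(idx, 0, None)], 0.0)
        out[drug] = col
    return pd.DataFrame(out)


def impute_patient_median(vitals: pd.DataFrame) -> pd.DataFrame:
    """Fill each absent cell with that patient's median of the signal.

    Must be called on a single patient's frame — medians never pool
    across patients. Signals with no observed value at all cannot be
    imputed; they stay absent and are listed in
    ``result.attrs["fully_missing_signals"]`` so downstream stages can
    exclude the patient from outcomes that need them. Idempotent.
    """
    out = vitals.copy()
    fully_missing: list[str] = []
    for col in out.columns:
        if col == "time_s":
            continue
        series = out[col]
        if series.isna().all():
            fully_missing.append(col)
            continue
        if series.isna().any():
            out[col] = series.fillna(series.median())
    out.attrs["fully_missing_signals"] = fully_missing
    if fully_missing:
        log.warning("signals with no observed values left unimputed: %s", fully_missing)
    return out


def build_feature_table(
    profiles: Sequence,
    vitals_list: Sequence[pd.DataFrame],
    doses_list: Sequence[pd.DataFrame],
    derived_list: Sequence[pd.DataFrame],
) -> pd.DataFrame:
    """Assemble the model-ready table: one row per (patient, time point).

    Predictors are relative time, an integer-ordinal patient identifier
    (tree models are invariant to monotone recoding), age, weight, and
    the eight infusion doses; each derived outcome is appended as a
    target column. Frames are inner-joined on time within patient; rows
    whose derived outcomes are flagged (NaN) are dropped with a logged
    count, so the result contains no absent values.
    """
    if not (len(profiles) == len(vitals_list) == len(doses_list) == len(derived_list)):
        raise ValueError("profiles, vitals, doses and derived lists must align")
    parts = []
    n_dropped = 0
    for pid_code, (profile, vitals, doses, derived) in enumerate(
        zip(profiles, vitals_list, doses_list, derived_list)
    ):
        missing_times = np.setdiff1d(vitals["time_s"].to_numpy(),
                                     derived["time_s"].to_numpy())
        if missing_times.size:
            raise ValueError(
                f"patient {profile.patient_id}: derived outcomes absent for "
                f"{missing_times.size} time points present in the vitals"
            )
        merged = doses.merge(derived[["time_s", *OUTCOMES]], on="time_s", how="inner")
        merged = merged.sort_values("time_s", kind="stable")
        merged.insert(1, "patient_id", pid_code)
        merged.insert(2, "age_years", profile.age_years)
        merged.insert(3, "weight_kg", profile.weight_kg)
        ok = merged[list(OUTCOMES)].notna().all(axis=1)
        n_dropped += int((~ok).sum())
        parts.append(merged.loc[ok])
    if n_dropped:
        log.info("dropped %d rows with flagged (undefined) derived outcomes", n_dropped)
    table = pd.concat(parts, ignore_index=True)
    table = table.sort_values(["patient_id", "time_s"], kind="stable", ignore_index=True)
    return table[[*FEATURE_COLUMNS, *OUTCOMES]]
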