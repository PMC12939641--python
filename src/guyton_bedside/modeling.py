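"""Random-forest dose-response models for the derived hemodynamics.

One regression forest per outcome (MCFP, venous resistance, SVRi,
cardiac index, cerebral and renal oxygen extraction), each predicting the
outcome from relative time, patient identifier, age, weight, and the
eight infusion doses. The forests use 100 trees, a minimum leaf size of
two and bootstrap sampling, evaluated on a held-out 20% split by R^2 and
mean absolute error. Dose-response structure is read off the fitted
forest through impurity-based feature importances and partial-dependence
curves; each drug's partial-dependence sweep is summarized into a
direction-of-effect call (increase / decrease / neutral) by comparing the
end-to-end change of the curve against a deadband proportional to the
outcome's spread, gated by out-of-sample evidence that the drug matters
at all (held-out permutation importance).

A caveat worth restating wherever results are read: the default split is
row-level, so highly autocorrelated series place near-duplicate rows in
both halves and held-out R^2 is optimistic about generalization to new
patients. ``ModelSpec(group_by_patient=True)`` switches to a
patient-grouped split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import GroupShuffleSplit, train_test_split

from .schema import DRUGS, FEATURE_COLUMNS, OUTCOMES

__all__ = [
    "ModelSpec",
    "ModelResult",
    "split_data",
    "fit_outcome_model",
    "importance_ranking",
    "partial_dependence",
    "drug_relevance",
    "direction_of_effect",
    "run_all_outcomes",
]


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters and evaluation settings for one outcome model."""

    outcome: str = "mcfp"
    n_trees: int = 100
    min_leaf: int = 2
    bootstrap: bool = True
    split_fraction: float = 0.8
    seed: int = 0
    feature_list: tuple[str, ...] = FEATURE_COLUMNS
    group_by_patient: bool = False
    pd_grid_points: int = 25
    pd_background_rows: int = 2000
    neutral_epsilon: float = 0.05
    relevance_rows: int = 2000
    relevance_repeats: int = 5
    relevance_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.n_trees < 1 or self.min_leaf < 1:
            raise ValueError("n_trees and min_leaf must be >= 1")


@dataclass
class ModelResult:
    """Fitted-model summary for one outcome."""

    outcome: str
    r2: float
    mae: float
    importance_ranking: list[tuple[str, float]]
    pd_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    directions: dict[str, str]
    outcome_sd: float
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "r2": self.r2,
            "mae": self.mae,
            "importance_ranking": [
                {"feature": f, "weight": w} for f, w in self.importance_ranking
            ],
            "pd_curves": {
                d: {"grid": list(map(float, g)), "pd": list(map(float, v))}
                for d, (g, v) in self.pd_curves.items()
            },
            "directions": dict(self.directions),
            "outcome_sd": self.outcome_sd,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def split_data(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test split at the configured fraction.

    Row-level and seeded by default; with ``group_by_patient`` all rows
    of a patient land on the same side.
    """
    if len(table) == 0:
        raise ValueError("cannot split an empty table")
    if spec.group_by_patient:
        splitter = GroupShuffleSplit(
            n_splits=1, train_size=spec.split_fraction, random_state=spec.seed
        )
        train_idx, test_idx = next(splitter.split(table, groups=table["patient_id"]))
        return table.iloc[train_idx], table.iloc[test_idx]
    train, test = train_test_split(
        table, train_size=spec.split_fraction, random_state=spec.seed, shuffle=True
    )
    return train, test


def importance_ranking(
    model: RandomForestRegressor,
    feature_names: Sequence[str],
) -> list[tuple[str, float]]:
    """Impurity-based importances, descending, ties broken by name.

    Weights are normalized to sum to 1; a degenerate forest whose trees
    never split (all-constant features) gets uniform weights.
    """
    if not hasattr(model, "feature_importances_"):
        raise ValueError("model is not fitted")
    raw = np.asarray(model.feature_importances_, dtype=float)
    total = raw.sum()
    if total <= 0:
        raw = np.full(len(feature_names), 1.0 / len(feature_names))
    else:
        raw = raw / total
    pairs = sorted(zip(feature_names, raw), key=lambda p: (-p[1], p[0]))
    return [(name, float(w)) for name, w in pairs]


def partial_dependence(
    model: RandomForestRegressor,
    background: pd.DataFrame,
    drug: str,
    grid: np.ndarray,
    feature_list: Sequence[str] = FEATURE_COLUMNS,
    observed_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Average prediction with ``drug`` pinned to each grid value.

    Standard partial dependence over the empirical distribution of the
    remaining features in ``background``. The grid must stay inside the
    observed dose range (``observed_range``, defaulting to the range seen
    in ``background``) — partial dependence extrapolated beyond observed
    doses is meaningless for a tree ensemble.
    """
    if drug not in feature_list:
        raise ValueError(f"'{drug}' is not a model feature")
    if observed_range is None:
        observed = background[drug].to_numpy(dtype=float)
        lo, hi = observed.min(), observed.max()
    else:
        lo, hi = observed_range
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid.min() < lo - 1e-12 or grid.max() > hi + 1e-12):
        raise ValueError(
            f"grid [{grid.min()}, {grid.max()}] outside observed range [{lo}, {hi}]"
        )
    X = background[list(feature_list)].to_numpy(dtype=float)
    col = list(feature_list).index(drug)
    out = np.empty(grid.size)
    for i, v in enumerate(grid):
        Xg = X.copy()
        Xg[:, col] = v
        out[i] = float(model.predict(Xg).mean())
    return out


def _pd_grid(observed: np.ndarray, n_points: int) -> np.ndarray:
    """Evenly spaced grid between the 1st and 99th dose percentiles.

    A constant dose column (e.g. a drug charted but never infused)
    collapses to a two-point degenerate grid at the single value, which
    yields a flat curve and a neutral call downstream.
    """
    lo, hi = np.percentile(observed, [1.0, 99.0])
    if hi <= lo:
        return np.array([lo, lo])
    return np.linspace(lo, hi, n_points)


def direction_of_effect(
    pd_values: np.ndarray,
    outcome_sd: float,
    epsilon: float = 0.05,
    relevance: float | None = None,
    relevance_threshold: float = 0.05,
) -> str:
    """Summarize a partial-dependence sweep into a direction call.

    The end-to-end change Δ = pd(last) − pd(first) must clear two gates
    to be called a direction:

    * a clinical deadband of ``epsilon * outcome_sd`` — changes smaller
      than a twentieth of the outcome's spread are not worth a call; and
    * when ``relevance`` (the drug's held-out permutation importance
      relative to the model's baseline test error, see
      :func:`drug_relevance`) is supplied, an out-of-sample evidence
      gate ``relevance > relevance_threshold``. A deep forest fitted to
      an unlearnable target memorizes noise in tiny leaves, and the few
      extreme-dose leaves that dominate both sweep endpoints give Δ a
      sampling noise that can exceed any fixed deadband; a dose column
      that carries no real effect has no out-of-sample predictive
      value, so held-out permutation importance separates the cases.

    Beyond both gates upward -> "increase", downward -> "decrease",
    otherwise "neutral".
    """
    pd_values = np.asarray(pd_values, dtype=float)
    if pd_values.size < 2:
        raise ValueError("partial-dependence curve needs at least 2 points")
    delta = pd_values[-1] - pd_values[0]
    band = epsilon * outcome_sd
    if relevance is not None and relevance <= relevance_threshold:
        return "neutral"
    if delta > band:
        return "increase"
    if delta < -band:
        return "decrease"
    return "neutral"


def drug_relevance(
    model: RandomForestRegressor,
    held_out: pd.DataFrame,
    outcome: str,
    drug: str,
    rng: np.random.Generator,
    feature_list: Sequence[str] = FEATURE_COLUMNS,
    n_repeats: int = 5,
) -> float:
    """Relative held-out permutation importance of one dose column.

    Mean increase in test MSE when the drug's column is permuted,
    divided by the unpermuted test MSE. Near zero for a drug the model
    only memorized; well above zero for a drug with a real effect.
    """
    X = held_out[list(feature_list)].to_numpy(dtype=float)
    y = held_out[outcome].to_numpy(dtype=float)
    base = float(np.mean((model.predict(X) - y) ** 2))
    if base == 0.0:
        return 0.0
    col = list(feature_list).index(drug)
    increases = []
    for _ in range(n_repeats):
        Xp = X.copy()
        Xp[:, col] = rng.permutation(Xp[:, col])
        increases.append(float(np.mean((model.predict(Xp) - y) ** 2)) - base)
    return float(np.mean(increases)) / base


def fit_outcome_model(
    train: pd.DataFrame,
    test: pd.DataFrame,
    spec: ModelSpec,
) -> ModelResult:
    """Fit one forest and extract the full dose-response summary."""
    features = list(spec.feature_list)
    y_train = train[spec.outcome].to_numpy(dtype=float)
    y_test = test[spec.outcome].to_numpy(dtype=float)
    for name, y in (("train", y_train), ("test", y_test)):
        bad = ~np.isfinite(y)
        if bad.any():
            raise ValueError(
                f"non-finite '{spec.outcome}' values in {name} rows "
                f"{np.flatnonzero(bad)[:10].tolist()}"
            )
    model = RandomForestRegressor(
        n_estimators=spec.n_trees,
        min_samples_leaf=spec.min_leaf,
        bootstrap=spec.bootstrap,
        max_features=1.0,
        random_state=spec.seed,
        n_jobs=1,
    )
    model.fit(train[features].to_numpy(dtype=float), y_train)
    pred = model.predict(test[features].to_numpy(dtype=float))
    r2 = float(r2_score(y_test, pred))
    mae = float(mean_absolute_error(y_test, pred))

    ranking = importance_ranking(model, features)
    outcome_sd = float(np.std(y_train))

    rng = np.random.default_rng(spec.seed)
    if len(train) > spec.pd_background_rows:
        idx = rng.choice(len(train), spec.pd_background_rows, replace=False)
        background = train.iloc[np.sort(idx)]
    else:
        background = train

    if len(test) > spec.relevance_rows:
        idx = rng.choice(len(test), spec.relevance_rows, replace=False)
        held_out = test.iloc[np.sort(idx)]
    else:
        held_out = test

    pd_curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    directions: dict[str, str] = {}
    for drug in DRUGS:
        observed = train[drug].to_numpy(dtype=float)
        grid = _pd_grid(observed, spec.pd_grid_points)
        values = partial_dependence(
            model, background, drug, grid, features,
            observed_range=(float(observed.min()), float(observed.max())),
        )
        pd_curves[drug] = (grid, values)
        relevance = drug_relevance(
            model, held_out, spec.outcome, drug, rng, features,
            n_repeats=spec.relevance_repeats,
        )
        directions[drug] = direction_of_effect(
            values, outcome_sd, spec.neutral_epsilon,
            relevance=relevance, relevance_threshold=spec.relevance_threshold,
        )

    return ModelResult(
        outcome=spec.outcome,
        r2=r2,
        mae=mae,
        importance_ranking=ranking,
        pd_curves=pd_curves,
        directions=directions,
        outcome_sd=outcome_sd,
        n_train=len(train),
        n_test=len(test),
    )


def run_all_outcomes(
    table: pd.DataFrame,
    base_spec: ModelSpec | None = None,
) -> dict[str, ModelResult]:
    """Fit every outcome's forest; per-outcome seeds offset from the base."""
    base = base_spec or ModelSpec()
    missing = [o for o in OUTCOMES if o not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks outcome columns: {missing}")
    results: dict[str, ModelResult] = {}
    for i, outcome in enumerate(OUTCOMES):
        spec = dataclasses.replace(base, outcome=outcome, seed=base.seed + 101 * i)
        train, test = split_data(table, spec)
        results[outcome] = fit_outcome_model(train, test, spec)
    return results
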