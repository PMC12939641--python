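"""Forest fitting, importance, partial dependence, direction calls."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from guyton_bedside.modeling import (
    ModelSpec,
    direction_of_effect,
    drug_relevance,
    fit_outcome_model,
    importance_ranking,
    partial_dependence,
    run_all_outcomes,
    split_data,
)
from guyton_bedside.schema import DRUGS, FEATURE_COLUMNS, OUTCOMES

from conftest import make_feature_table


@pytest.fixture(scope="module")
def planted_linear():
    """Table whose outcomes are an exact linear function of one dose."""
    rng = np.random.default_rng(42)
    table = make_feature_table(
        10_000, rng, target_fn=lambda df: 5.0 + 3.0 * df["milrinone"]
    )
    spec = ModelSpec(outcome="mcfp", seed=0)
    train, test = split_data(table, spec)
    result = fit_outcome_model(train, test, spec)
    return table, spec, train, test, result


class TestSplit:
    def test_ratio(self):
        table = make_feature_table(1000, np.random.default_rng(0))
        train, test = split_data(table, ModelSpec(seed=1))
        assert len(train) == 800 and len(test) == 200

    def test_seed_reproducibility(self):
        table = make_feature_table(500, np.random.default_rng(0))
        s = ModelSpec(seed=3)
        a = split_data(table, s)
        b = split_data(table, s)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_disjoint_and_exhaustive(self):
        table = make_feature_table(500, np.random.default_rng(0))
        train, test = split_data(table, ModelSpec(seed=3))
        combined = pd.concat([train, test]).sort_index()
        pd.testing.assert_frame_equal(combined, table)

    def test_grouped_split_respects_patients(self):
        table = make_feature_table(1000, np.random.default_rng(0), n_patients=10)
        train, test = split_data(table, ModelSpec(seed=2, group_by_patient=True))
        assert set(train["patient_id"]) & set(test["patient_id"]) == set()
        assert len(train) + len(test) == 1000

    def test_empty_table_rejected(self):
        empty = make_feature_table(5, np.random.default_rng(0)).iloc[:0]
        with pytest.raises(ValueError):
            split_data(empty, ModelSpec())


class TestFit:
    def test_learnable_signal_high_r2(self, planted_linear):
        *_, result = planted_linear
        assert result.r2 >= 0.95
        assert result.mae >= 0.0

    def test_constant_target_zero_mae(self):
        rng = np.random.default_rng(1)
        table = make_feature_table(500, rng, target_fn=lambda df: 7.0)
        spec = ModelSpec(outcome="rv", seed=0)
        train, test = split_data(table, spec)
        result = fit_outcome_model(train, test, spec)
        assert result.mae == pytest.approx(0.0, abs=1e-12)

    def test_non_finite_target_rejected_with_rows(self):
        rng = np.random.default_rng(2)
        table = make_feature_table(100, rng)
        table.loc[17, "mcfp"] = np.nan
        spec = ModelSpec(outcome="mcfp", seed=0)
        with pytest.raises(ValueError, match="mcfp"):
            fit_outcome_model(table, table, spec)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        table = make_feature_table(
            2000, rng, target_fn=lambda df: df["epinephrine"] * 2.0
        )
        spec = ModelSpec(outcome="ci", seed=9)
        results = []
        for _ in range(2):
            train, test = split_data(table, spec)
            results.append(fit_outcome_model(train, test, spec))
        assert results[0].r2 == results[1].r2
        assert results[0].mae == results[1].mae
        assert results[0].importance_ranking == results[1].importance_ranking
        for d in DRUGS:
            assert np.array_equal(results[0].pd_curves[d][1], results[1].pd_curves[d][1])


class TestImportance:
    def test_planted_signal_ranked_first(self, planted_linear):
        *_, result = planted_linear
        assert result.importance_ranking[0][0] == "milrinone"
        assert result.importance_ranking[0][1] > 0.9

    def test_weights_sum_to_one(self, planted_linear):
        *_, result = planted_linear
        total = sum(w for _, w in result.importance_ranking)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert all(w >= 0 for _, w in result.importance_ranking)

    def test_all_constant_features_uniform_alphabetical(self):
        X = np.zeros((50, 4))
        y = np.zeros(50)
        model = RandomForestRegressor(n_estimators=5, random_state=0).fit(X, y)
        ranking = importance_ranking(model, ["delta", "alpha", "charlie", "bravo"])
        names = [n for n, _ in ranking]
        assert names == ["alpha", "bravo", "charlie", "delta"]
        assert all(w == pytest.approx(0.25) for _, w in ranking)

    def test_unfitted_model_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            importance_ranking(RandomForestRegressor(), ["a"])

    def test_shuffling_informative_feature_degrades_rank(self):
        # permutation sanity across seeds
        degraded = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            table = make_feature_table(
                3000, rng, target_fn=lambda df: 4.0 * df["vasopressin"]
            )
            spec = ModelSpec(outcome="svri", seed=seed)
            train, test = split_data(table, spec)
            res = fit_outcome_model(train, test, spec)
            rank_before = [f for f, _ in res.importance_ranking].index("vasopressin")

            shuffled = table.copy()
            shuffled["vasopressin"] = rng.permutation(shuffled["vasopressin"].to_numpy())
            train, test = split_data(shuffled, spec)
            res2 = fit_outcome_model(train, test, spec)
            rank_after = [f for f, _ in res2.importance_ranking].index("vasopressin")
            degraded += rank_after > rank_before
        assert degraded == 3


class TestPartialDependence:
    def test_ignored_drug_flat_curve(self, planted_linear):
        *_, result = planted_linear
        grid, values = result.pd_curves["nicardipine"]
        assert np.ptp(values) < 0.05 * result.outcome_sd

    def test_planted_monotone_signal_recovered(self, planted_linear):
        *_, result = planted_linear
        grid, values = result.pd_curves["milrinone"]
        # non-decreasing up to small estimation wiggle
        assert np.all(np.diff(values) > -0.01)
        assert values[-1] - values[0] > 2.0  # true slope 3 over ~unit range

    def test_single_point_grid_is_mean_prediction(self, planted_linear):
        table, spec, train, _, result = planted_linear
        model = RandomForestRegressor(
            n_estimators=10, min_samples_leaf=2, random_state=0
        ).fit(train[list(FEATURE_COLUMNS)].to_numpy(), train["mcfp"])
        background = train.head(200)
        value = partial_dependence(model, background, "milrinone", np.array([0.5]))
        pinned = background.copy()
        pinned["milrinone"] = 0.5
        expected = model.predict(pinned[list(FEATURE_COLUMNS)].to_numpy()).mean()
        assert value[0] == pytest.approx(expected, rel=1e-12)

    def test_grid_outside_observed_range_rejected(self, planted_linear):
        table, spec, train, _, result = planted_linear
        model = RandomForestRegressor(n_estimators=5, random_state=0).fit(
            train[list(FEATURE_COLUMNS)].to_numpy(), train["mcfp"]
        )
        with pytest.raises(ValueError, match="outside observed range"):
            partial_dependence(model, train.head(100), "milrinone", np.array([5.0]))


class TestDirectionOfEffect:
    def test_flat_curve_neutral(self):
        assert direction_of_effect(np.full(25, 3.0), 1.0) == "neutral"

    def test_full_sd_rise_is_increase(self):
        curve = np.linspace(0.0, 1.0, 25)
        assert direction_of_effect(curve, 1.0) == "increase"

    def test_full_sd_drop_is_decrease(self):
        curve = np.linspace(1.0, 0.0, 25)
        assert direction_of_effect(curve, 1.0) == "decrease"

    def test_sub_band_change_neutral(self):
        curve = np.linspace(0.0, 0.04, 25)
        assert direction_of_effect(curve, 1.0, epsilon=0.05) == "neutral"

    def test_single_point_curve_rejected(self):
        with pytest.raises(ValueError, match="2 points"):
            direction_of_effect(np.array([1.0]), 1.0)

    def test_irrelevant_drug_forced_neutral_by_evidence_gate(self):
        curve = np.linspace(0.0, 1.0, 25)  # large apparent change...
        assert direction_of_effect(curve, 1.0, relevance=0.01) == "neutral"
        assert direction_of_effect(curve, 1.0, relevance=0.5) == "increase"

    def test_drug_relevance_separates_signal_from_noise(self, planted_linear):
        table, spec, train, test, _ = planted_linear
        model = RandomForestRegressor(
            n_estimators=20, min_samples_leaf=2, random_state=0
        ).fit(train[list(FEATURE_COLUMNS)].to_numpy(), train["mcfp"].to_numpy())
        rng = np.random.default_rng(0)
        informative = drug_relevance(model, test, "mcfp", "milrinone", rng)
        spurious = drug_relevance(model, test, "mcfp", "nicardipine", rng)
        assert informative > 1.0      # permuting the real driver wrecks the fit
        assert spurious < 0.05        # permuting a memorized column does not


class TestRunAllOutcomes:
    def test_six_results_with_required_fields(self):
        rng = np.random.default_rng(5)
        table = make_feature_table(
            800, rng, target_fn=lambda df: df["epinephrine"] + 0.1 * df["time_s"] / 1e5
        )
        results = run_all_outcomes(table, ModelSpec(seed=1))
        assert set(results) == set(OUTCOMES)
        for res in results.values():
            assert set(res.directions) == set(DRUGS)
            assert set(res.directions.values()) <= {"increase", "decrease", "neutral"}
            assert len(res.pd_curves) == len(DRUGS)

    def test_missing_outcome_column_rejected(self):
        table = make_feature_table(100, np.random.default_rng(0)).drop(columns=["rv"])
        with pytest.raises(ValueError, match="rv"):
            run_all_outcomes(table)
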