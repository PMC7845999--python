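"""Jackknife CV, external validation, grid bookkeeping, apo importance."""

import numpy as np
import pandas as pd
import pytest

from kinemark.validation import (
    ExperimentPlan,
    count_planned_networks,
    ensemble_builder,
    external_validation,
    feature_importance,
    kfold_cv,
    linear_builder,
    r_squared,
    repeated_cv,
    run_experiment_grid,
    select_and_validate,
    _fold_indices,
)
from kinemark.nets import NetworkConfig


def oracle_builder():
    def build(table, target, features, seed):
        return lambda rows: rows[target].to_numpy(float)

    return build


def constant_builder(value=3.0):
    def build(table, target, features, seed):
        return lambda rows: np.full(len(rows), value)

    return build


def noisy_builder(scale=1.0):
    def build(table, target, features, seed):
        rng = np.random.default_rng(seed)
        beta = rng.normal(1.0, 0.2)
        return lambda rows: beta * rows[features[0]].to_numpy(float) + rng.normal(0, scale)

    return build


def linear_table(n=100, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, size=n)
    return pd.DataFrame({"x": x, "y": 2 * x + rng.normal(0, noise, size=n)})


class TestFolds:
    def test_partition_disjoint_exhaustive_balanced(self):
        for n, folds in [(100, 10), (37, 10), (12, 5)]:
            idx = _fold_indices(n, folds, np.random.default_rng(0))
            sizes = [len(f) for f in idx]
            assert max(sizes) - min(sizes) <= 1
            flat = np.concatenate(idx)
            assert len(flat) == n and len(np.unique(flat)) == n


class TestKfoldCV:
    def test_oracle_model_perfect(self):
        res = kfold_cv(linear_table(), "y", oracle_builder(), ["x"], rng=0)
        assert res.r2cv[0] == pytest.approx(1.0)

    def test_constant_model_zero_by_rule(self):
        with pytest.warns(UserWarning, match="constant"):
            res = kfold_cv(linear_table(), "y", constant_builder(), ["x"], rng=0)
        assert res.r2cv[0] == 0.0

    def test_linear_data_linear_model(self):
        res = kfold_cv(linear_table(noise=0.05), "y", linear_builder(), ["x"], rng=1)
        assert res.r2cv[0] >= 0.95

    def test_every_row_predicted_once(self):
        table = linear_table(n=43)
        res = kfold_cv(table, "y", oracle_builder(), ["x"], rng=2)
        assert res.predictions.shape == (1, 43)
        assert np.isfinite(res.predictions).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            kfold_cv(linear_table(n=5), "y", oracle_builder(), ["x"], folds=10)


class TestRepeatedCV:
    def test_single_repetition_equals_kfold(self):
        table = linear_table()
        a = repeated_cv(table, "y", linear_builder(), ["x"], repetitions=1, base_seed=3)
        b = kfold_cv(table, "y", linear_builder(), ["x"],
                     rng=np.random.default_rng(np.random.SeedSequence((3, 0))))
        assert a.r2cv[0] == b.r2cv[0]

    def test_deterministic_rerun(self):
        table = linear_table(noise=0.3)
        a = repeated_cv(table, "y", noisy_builder(), ["x"], repetitions=3, base_seed=5)
        b = repeated_cv(table, "y", noisy_builder(), ["x"], repetitions=3, base_seed=5)
        np.testing.assert_array_equal(a.r2cv, b.r2cv)

    def test_shuffling_sensitivity_gives_positive_sd(self):
        table = linear_table(noise=0.5)
        res = repeated_cv(table, "y", noisy_builder(0.5), ["x"], repetitions=5, base_seed=7)
        assert res.sd > 0


class TestExternalValidation:
    def test_oracle_perfect(self):
        table = linear_table()
        assert external_validation(lambda rows: rows["y"].to_numpy(), table, "y") == 1.0

    def test_constant_predictions_zero(self):
        with pytest.warns(UserWarning):
            assert external_validation(lambda rows: np.zeros(len(rows)),
                                       linear_table(), "y") == 0.0

    def test_refuses_tiny_external_set(self):
        with pytest.raises(ValueError):
            external_validation(lambda rows: rows["y"].to_numpy(), linear_table(n=2), "y")

    def test_same_law_split_tracks_cv(self, normalized_cohort, completer_split, fm_table):
        """Completer-trained models keep most of their accuracy on
        non-completers drawn from the same generative law."""
        from kinemark.cohort import assemble_training_records, subset_by_patients
        from kinemark.nets import predict, train_ensemble

        cohort, truth = normalized_cohort
        completers, non_completers = completer_split
        support = [f for f, _ in truth.support["FM"]]
        ens = train_ensemble(fm_table, "FM", support, NetworkConfig(), n_members=5, base_seed=0)
        ext = assemble_training_records(subset_by_patients(cohort, non_completers), "FM")
        ext_r2 = external_validation(lambda rows: predict(ens, rows), ext, "FM")
        cv = repeated_cv(fm_table, "FM", ensemble_builder(NetworkConfig(), 5),
                         support, repetitions=2, base_seed=1)
        assert abs(ext_r2 - cv.mean) < 0.15


class TestPlanArithmetic:
    def test_default_plan_network_count(self):
        assert count_planned_networks(ExperimentPlan()) == 462_000

    def test_minimal_plan(self):
        plan = ExperimentPlan(scales=("FM",), k_grid=(8,), h_grid=(2,),
                              ant_restarts=1, ensemble_size=1,
                              cv_repetitions=0, folds=1)
        assert count_planned_networks(plan) == 1

    def test_direct_product(self):
        plan = ExperimentPlan(scales=("FM", "NIH"), k_grid=(8,), h_grid=(2,),
                              ant_restarts=3, ensemble_size=5,
                              cv_repetitions=2, folds=10)
        assert count_planned_networks(plan) == 2 * 1 * 1 * 3 * 5 * 3 * 10

    def test_invalid_plan_rejected(self):
        with pytest.raises(ValueError):
            ExperimentPlan(scales=())


class TestExperimentGrid:
    def test_one_cell_one_row(self, fm_table):
        plan = ExperimentPlan(scales=("FM",), k_grid=(2,), h_grid=(2,),
                              ant_restarts=1, ensemble_size=2,
                              cv_repetitions=1, folds=5, n_ants=20)
        res = run_experiment_grid({"FM": fm_table}, plan, seed=0, epochs=30)
        assert len(res) == 1
        assert res["error"].iloc[0] == ""
        assert 0 <= res["r2cv_mean"].iloc[0] <= 1

    def test_capacity_grows_with_k_on_planted_truth(self, fm_table):
        """With a multi-feature generative support, K = 4 models are at
        least as good as K = 2 models (small tolerance), mirroring the
        rising portion of the accuracy-vs-K curve."""
        plan = ExperimentPlan(scales=("FM",), k_grid=(2, 4), h_grid=(2,),
                              ant_restarts=1, ensemble_size=3,
                              cv_repetitions=2, folds=10, n_ants=50)
        res = run_experiment_grid({"FM": fm_table}, plan, seed=1, epochs=60)
        r2 = res.set_index("K")["r2cv_mean"]
        assert r2[4] >= r2[2] - 0.05

    def test_accuracy_asymptotes_in_k(self, fm_table):
        """The K = 8 -> 12 gain is smaller than the K = 2 -> 8 gain
        (diminishing returns around the true support size)."""
        plan = ExperimentPlan(scales=("FM",), k_grid=(2, 8, 12), h_grid=(2,),
                              ant_restarts=1, ensemble_size=3,
                              cv_repetitions=2, folds=10, n_ants=60)
        res = run_experiment_grid({"FM": fm_table}, plan, seed=2, epochs=60)
        r2 = res.set_index("K")["r2cv_mean"]
        assert r2[12] - r2[8] < r2[8] - r2[2]


def importance_table(n=120, seed=0, duplicate=False):
    """Scale driven solely by feature A; B-E are independent noise."""
    rng = np.random.default_rng(seed)
    cols = {name: rng.uniform(0, 1, size=n) for name in "ABCDE"}
    if duplicate:
        cols["A2"] = cols["A"].copy()
    t = pd.DataFrame(cols)
    t["y"] = np.round(50 * (0.8 * t["A"] + 0.05 * rng.normal(size=n)) + 10, 1)
    return t


class TestFeatureImportance:
    KW = dict(K=2, h=2, n_ants=40, n_restarts=1, cv_repetitions=5,
              folds=5, ensemble_size=3, epochs=40, seed=0)

    def test_sole_driver_is_significant_with_largest_drop(self):
        res = feature_importance(importance_table(), "y", **self.KW)
        res = res.set_index("feature")
        drops = res.loc[list("ABCDE"), "r2cv_mean"].rsub(res.loc["<all>", "r2cv_mean"])
        assert drops.idxmax() == "A"
        assert res.loc["A", "significant"]

    def test_irrelevant_feature_not_significant(self):
        res = feature_importance(importance_table(), "y", **self.KW).set_index("feature")
        assert not res.loc[list("BCDE"), "significant"].any()

    def test_duplicated_driver_masks_importance(self):
        res = feature_importance(importance_table(duplicate=True), "y",
                                 **self.KW).set_index("feature")
        assert not res.loc["A", "significant"]

    def test_pool_must_exceed_k(self):
        with pytest.raises(ValueError):
            feature_importance(importance_table()[["A", "B", "y"]], "y", K=2)


class TestPipelineRecovery:
    def test_reduced_pipeline_recovers_planted_support(self, normalized_cohort, fm_table):
        """On the default synthetic cohort the reduced pipeline recovers
        the dominant generative features and approaches the noise
        ceiling (single seed; the multi-seed version lives in the
        acceptance suite)."""
        _, truth = normalized_cohort
        res = select_and_validate(fm_table, "FM", K=8, n_ants=300, n_restarts=2,
                                  cv_repetitions=3, seed=11)
        top4 = set(truth.top_features("FM", 4))
        assert len(top4 & set(res["subset"])) >= 3
        assert res["cv"].mean >= truth.ceiling["FM"] - 0.15
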