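"""Effect sizes, greedy/Newton composite optimization, holdout validation,
sample-size arithmetic and registry matching."""

import numpy as np
import pandas as pd
import pytest

from kinemark.composite import (
    Composite,
    DegenerateSpreadError,
    backward_eliminate,
    composite_d,
    effect_size_from_summary,
    effect_size_paired,
    evaluate_composite,
    exhaustive_grid_search,
    frequency_match_registry,
    greedy_forward,
    newton_optimize_weights,
    paired_changes,
    repeated_holdout,
    sample_size_reduction,
)

from conftest import make_tiny_cohort


def change_matrix(n=60, features=("f1", "f2", "f3"), shifts=None, seed=0, noise=1.0):
    """Per-patient change matrix with configurable planted mean shifts."""
    rng = np.random.default_rng(seed)
    shifts = shifts or {}
    data = {
        f: shifts.get(f, 0.0) + noise * rng.normal(size=n) for f in features
    }
    return pd.DataFrame(data, index=[f"P{i}" for i in range(n)])


class TestEffectSizes:
    def test_printed_registry_summary(self):
        assert effect_size_from_summary(2.1, 3.1) == pytest.approx(0.677, abs=0.001)

    def test_completer_summary_quotient(self):
        assert effect_size_from_summary(3.7, 3.3) == pytest.approx(1.121, abs=0.001)

    def test_zero_mean_change(self):
        assert effect_size_from_summary(0.0, 5.0) == 0.0

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            effect_size_from_summary(1.0, 0.0)

    def test_hand_computed_paired_d(self):
        res = effect_size_paired([0, 0, 0], [0, 2, 4])
        assert res.d == pytest.approx(1.0)
        assert res.n == 3

    def test_equal_changes_degenerate(self):
        with pytest.raises(DegenerateSpreadError):
            effect_size_paired([1, 2, 3], [2, 3, 4])

    def test_recovers_generating_ratio_in_monte_carlo(self):
        rng = np.random.default_rng(0)
        pre = rng.normal(size=10_000)
        post = pre + rng.normal(1.5, 2.0, size=10_000)
        assert effect_size_paired(pre, post).d == pytest.approx(0.75, abs=0.03)


class TestEvaluateComposite:
    def test_zero_weights_give_zero(self, tiny_cohort):
        comp = Composite(weights={}, pool=tiny_cohort.schema.features)
        vals = evaluate_composite(comp, tiny_cohort)
        assert (vals == 0).all().all()

    def test_single_unit_weight_projects_feature(self, tiny_cohort):
        comp = Composite(weights={"Aim Aff": 1.0}, pool=tiny_cohort.schema.features)
        vals = evaluate_composite(comp, tiny_cohort)
        for pid in tiny_cohort.patients:
            assert vals.loc[pid, "c_day7"] == pytest.approx(
                float(tiny_cohort.rows_for(pid, 7).iloc[0]["Aim Aff"])
            )

    def test_weighted_difference_arithmetic(self):
        cohort = make_tiny_cohort(n_patients=1)
        cohort.data.loc[cohort.data["day"] == 7, ["Aim Aff", "Deviation Aff"]] = [0.8, 0.2]
        comp = Composite(weights={"Aim Aff": 0.5, "Deviation Aff": -0.5},
                         pool=cohort.schema.features)
        vals = evaluate_composite(comp, cohort, ["P00"])
        assert vals.loc["P00", "c_day7"] == pytest.approx(0.3)

    def test_missing_value_names_patient_feature_day(self):
        cohort = make_tiny_cohort(missing=[(0, 90, "Aim Aff")])
        comp = Composite(weights={"Aim Aff": 1.0}, pool=cohort.schema.features)
        with pytest.raises(ValueError, match="P00.*Aim Aff.*90"):
            evaluate_composite(comp, cohort, ["P00"])

    def test_weight_budget_enforced(self):
        with pytest.raises(ValueError):
            Composite(weights={f"f{i}": 1.0 for i in range(9)},
                      pool=tuple(f"f{i}" for i in range(9)), max_features=8)


class TestGreedyForward:
    def test_selects_planted_feature(self):
        changes = change_matrix(shifts={"f1": 2.0}, noise=1.0)
        comps, ds = greedy_forward(changes, max_features=1)
        assert comps[0].weights.get("f1") == 1.0
        assert ds[0] == pytest.approx(composite_d(changes, {"f1": 1.0}))

    def test_train_d_monotone_in_size(self):
        for seed in range(5):
            changes = change_matrix(n=40, features=tuple(f"f{i}" for i in range(6)),
                                    shifts={"f0": 1.0, "f1": -0.5}, seed=seed)
            _, ds = greedy_forward(changes, max_features=6)
            assert all(b >= a - 1e-12 for a, b in zip(ds, ds[1:]))

    def test_negative_shift_gets_negative_weight(self):
        changes = change_matrix(shifts={"f1": -2.0})
        comps, ds = greedy_forward(changes, max_features=1)
        assert comps[0].weights["f1"] == -1.0
        assert ds[0] > 0

    def test_matches_exhaustive_grid_on_two_features(self):
        for seed in range(5):
            changes = change_matrix(n=50, features=("a", "b"),
                                    shifts={"a": 0.8, "b": 0.5}, seed=seed)
            _, dmax = exhaustive_grid_search(changes, ["a", "b"])
            _, ds = greedy_forward(changes, ["a", "b"], max_features=2)
            assert ds[-1] >= 0.95 * dmax

    def test_degenerate_candidates_skipped(self):
        changes = change_matrix(n=30, features=("a", "b"), shifts={"a": 1.0})
        changes["b"] = 0.0  # zero spread
        comps, ds = greedy_forward(changes, max_features=2)
        assert comps[0].weights.get("a") is not None


class TestScaleInvariance:
    def test_d_homogeneous_degree_zero(self):
        changes = change_matrix(shifts={"f1": 1.0, "f2": 0.4})
        w = {"f1": 0.6, "f2": -0.3, "f3": 0.1}
        base = composite_d(changes, w)
        for alpha in (0.5, 2.0, 7.3):
            scaled = {k: alpha * v for k, v in w.items()}
            assert composite_d(changes, scaled) == pytest.approx(base)
            negated = {k: -alpha * v for k, v in w.items()}
            assert composite_d(changes, negated) == pytest.approx(-base)


class TestBackwardElimination:
    def test_single_feature_pool(self):
        changes = change_matrix(features=("a",), shifts={"a": 1.0})
        comp, d = backward_eliminate(changes, ["a"])
        assert abs(comp.weights["a"]) == pytest.approx(1.0)
        assert d == pytest.approx(abs(composite_d(changes, {"a": 1.0})))

    def test_near_parity_with_greedy_on_two_features(self):
        changes = change_matrix(n=50, features=("a", "b"),
                                shifts={"a": 0.8, "b": 0.5}, seed=3)
        _, greedy_ds = greedy_forward(changes, ["a", "b"], max_features=2)
        _, newton_d = backward_eliminate(changes, ["a", "b"])
        assert newton_d >= greedy_ds[-1] - 0.05

    def test_newton_reaches_closed_form_optimum(self):
        """The continuous maximizer of d is proportional to S^-1 mu (a
        generalized Rayleigh quotient); Newton-Raphson must reach it."""
        changes = change_matrix(n=80, features=("a", "b", "c"),
                                shifts={"a": 0.7, "b": 0.3, "c": -0.2}, seed=4)
        mu = changes.mean().to_numpy()
        S = np.cov(changes.to_numpy(), rowvar=False)
        w_star = np.linalg.solve(S, mu)
        d_star = float(mu @ w_star / np.sqrt(w_star @ S @ w_star))
        _, d = newton_optimize_weights(changes, list(changes.columns))
        assert d == pytest.approx(d_star, abs=1e-6)


class TestRepeatedHoldout:
    def test_reproducible_with_fixed_seed(self):
        changes = change_matrix(n=30, shifts={"f1": 1.0})
        a = repeated_holdout(changes, repeats=3, seed=5, max_features=3)
        b = repeated_holdout(changes, repeats=3, seed=5, max_features=3)
        np.testing.assert_array_equal(a.validation_d, b.validation_d)

    def test_validation_optimism_gap(self):
        changes = change_matrix(n=50, features=tuple(f"f{i}" for i in range(6)),
                                shifts={"f0": 0.8, "f1": 0.5}, seed=6)
        res = repeated_holdout(changes, repeats=50, seed=0, max_features=6)
        assert np.nanmean(res.mean_validation) <= np.nanmean(res.mean_train)

    def test_curve_rises_then_plateaus_with_planted_support(self):
        """Four informative features: the validation curve climbs up to
        size ~4 and gains little beyond."""
        shifts = {"f0": 1.0, "f1": 0.8, "f2": 0.7, "f3": 0.6}
        changes = change_matrix(n=80, features=tuple(f"f{i}" for i in range(8)),
                                shifts=shifts, seed=7)
        res = repeated_holdout(changes, repeats=40, seed=1, max_features=8)
        v = res.mean_validation
        assert v[3] > v[0]
        assert v[3] - v[0] > abs(v[7] - v[3])

    def test_requires_enough_patients(self):
        with pytest.raises(ValueError):
            repeated_holdout(change_matrix(n=5), repeats=2)


class TestSampleSizeArithmetic:
    @pytest.mark.parametrize("ratio,expected", [(1.83, 70.1), (1.0, 0.0), (2.0, 75.0)])
    def test_inverse_square_scaling(self, ratio, expected):
        assert sample_size_reduction(ratio) == pytest.approx(expected, abs=0.05)

    def test_ratio_below_one_is_negative(self):
        assert sample_size_reduction(0.5) == pytest.approx(-300.0)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            sample_size_reduction(0.0)


def toy_registry(score_counts, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for score, count in score_counts.items():
        for i in range(count):
            rows.append({"subject_id": f"S{score}_{i}", "nih_day7": score,
                         "nih_day90": max(score - int(rng.integers(0, 4)), 0)})
    return pd.DataFrame(rows)


class TestFrequencyMatching:
    def test_single_stratum(self):
        reg = toy_registry({5: 20})
        matched = frequency_match_registry([5, 5], reg, ratio=3)
        assert len(matched) == 6
        assert (matched["nih_day7"] == 5).all()

    def test_histogram_proportionality(self):
        reg = toy_registry({0: 30, 5: 30})
        matched = frequency_match_registry([0, 0, 5], reg, ratio=3, seed=1)
        counts = matched["nih_day7"].value_counts()
        assert counts[0] == 6 and counts[5] == 3

    def test_exact_proportionality_for_any_seed(self):
        reg = toy_registry({0: 50, 3: 50, 7: 50})
        index = [0, 0, 3, 7, 7, 7]
        for seed in range(5):
            matched = frequency_match_registry(index, reg, ratio=5, seed=seed)
            counts = matched["nih_day7"].value_counts()
            index_counts = pd.Series(index).value_counts()
            for score in index_counts.index:
                assert counts[score] == 5 * index_counts[score]

    def test_shortfall_names_score(self):
        reg = toy_registry({5: 4})
        with pytest.raises(ValueError, match="score 5.*shortfall 2"):
            frequency_match_registry([5, 5], reg, ratio=3)


class TestPairedChanges:
    def test_changes_are_day90_minus_day7(self, tiny_cohort):
        changes = paired_changes(tiny_cohort, ["Aim Aff"])
        for pid in tiny_cohort.patients:
            expect = (float(tiny_cohort.rows_for(pid, 90).iloc[0]["Aim Aff"])
                      - float(tiny_cohort.rows_for(pid, 7).iloc[0]["Aim Aff"]))
            assert changes.loc[pid, "Aim Aff"] == pytest.approx(expect)

    def test_missing_value_rejected_with_location(self):
        cohort = make_tiny_cohort(missing=[(1, 7, "Aim Aff")])
        with pytest.raises(ValueError, match="P01.*Aim Aff.*7"):
            paired_changes(cohort, ["Aim Aff"])
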