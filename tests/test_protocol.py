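"""Partitioning, calibration, metrics, lock-box guard, and inference."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from neuromontage.models import ModelSpec, build_lightweight
from neuromontage.protocol import (GuardedLabels, LockBoxViolation,
                                   apply_calibration, balanced_partition,
                                   baseline_logistic, class_weighted_bce,
                                   compute_metrics, corrected_t_test,
                                   fdr_adjust, inverse_frequency_weights,
                                   platt_calibrate, run_protocol,
                                   select_epoch, threshold_sweep)


def make_table(n, prevalence=0.34, seed=0):
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * prevalence))
    outcome = np.zeros(n, dtype=int)
    outcome[:n_pos] = 1
    rng.shuffle(outcome)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "initial_severity": rng.choice(
            ["severe", "moderate", "mild", "normal", "unknown"], n),
        "left_lesion_size": rng.integers(0, 3000, n),
        "recovery_time_months": rng.lognormal(3.4, 0.9, n),
        "outcome": outcome})


class TestBalancedPartition:
    def test_five_groups_of_twenty_with_balanced_prevalence(self):
        table = make_table(100)
        plan = balanced_partition(table, seed=3)
        for g in range(1, 6):
            idx = plan.indices(g)
            assert len(idx) == 20
            assert table["outcome"].to_numpy()[idx].sum() in {6, 7, 8}

    def test_single_group_degenerate(self):
        table = make_table(30)
        plan = balanced_partition(table, k=1, seed=0)
        assert len(plan.indices(1)) == 30

    def test_deterministic_given_seed(self):
        table = make_table(80)
        a = balanced_partition(table, seed=5)
        b = balanced_partition(table, seed=5)
        np.testing.assert_array_equal(a.groups, b.groups)

    def test_groups_disjoint_exhaustive_sizes_within_one(self):
        table = make_table(103)
        plan = balanced_partition(table, seed=1)
        sizes = [len(plan.indices(g)) for g in range(1, 6)]
        assert sum(sizes) == 103
        assert max(sizes) - min(sizes) <= 1

    def test_prevalence_within_five_points_for_n_100(self):
        table = make_table(100, seed=7)
        plan = balanced_partition(table, seed=7)
        overall = table["outcome"].mean()
        for g in range(1, 6):
            rate = table["outcome"].to_numpy()[plan.indices(g)].mean()
            assert abs(rate - overall) <= 0.05

    def test_lockbox_never_in_folds(self):
        table = make_table(60)
        plan = balanced_partition(table, seed=2)
        lb = set(plan.lockbox_indices)
        for f in range(plan.n_folds):
            train, val = plan.fold(f)
            assert not lb & set(train)
            assert not lb & set(val)

    def test_too_many_groups_rejected(self):
        with pytest.raises(ValueError):
            balanced_partition(make_table(3), k=5)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            balanced_partition(make_table(0))


class TestClassWeightedBCE:
    def test_perfect_predictions_approach_zero(self):
        y = np.array([1, 0, 1])
        p = np.array([1 - 1e-9, 1e-9, 1 - 1e-9])
        assert class_weighted_bce(p, y) < 1e-5

    def test_unit_weights_reduce_to_plain_bce(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 50)
        y = rng.integers(0, 2, 50)
        plain = -np.mean(y * np.log(p) + (1 - y) * np.log1p(-p))
        assert class_weighted_bce(p, y, {0: 1.0, 1: 1.0}) == \
            pytest.approx(plain)

    def test_coin_flip_probabilities_give_ln2(self):
        y = np.array([0, 1, 0, 1, 1])
        assert class_weighted_bce(np.full(5, 0.5), y, {0: 1.0, 1: 1.0}) == \
            pytest.approx(np.log(2))

    def test_inverse_frequency_weights_mean_one(self):
        y = np.array([1] * 34 + [0] * 66)
        w = inverse_frequency_weights(y)
        assert 0.34 * w[1] + 0.66 * w[0] == pytest.approx(1.0)
        assert w[1] > w[0]


class TestPlatt:
    def test_calibrated_input_gives_temperature_near_one(self):
        rng = np.random.default_rng(1)
        z = rng.normal(0, 2, 2000)
        y = (rng.random(2000) < expit(z)).astype(int)
        assert abs(platt_calibrate(expit(z), y) - 1.0) < 0.1

    def test_overconfident_input_recovers_scale_three(self):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 2, 2000)
        y = (rng.random(2000) < expit(z)).astype(int)
        assert platt_calibrate(expit(3 * z), y) == pytest.approx(3.0,
                                                                 abs=0.3)

    def test_temperature_preserves_ranking_and_auc(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.01, 0.99, 200)
        y = rng.integers(0, 2, 200)
        q = apply_calibration(2.5, p)
        assert np.array_equal(np.argsort(p), np.argsort(q))
        assert compute_metrics(p, y)["auc"] == \
            pytest.approx(compute_metrics(q, y)["auc"], abs=1e-12)

    def test_single_class_validation_rejected(self):
        with pytest.raises(ValueError):
            platt_calibrate(np.array([0.2, 0.8]), np.array([1, 1]))


class TestSelectEpoch:
    def test_argmin_of_trace(self):
        assert select_epoch([0.9, 0.5, 0.7, 0.4, 0.6]) == 3

    def test_tie_breaks_to_first_minimum(self):
        assert select_epoch([0.8, 0.3, 0.5, 0.3]) == 1

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            select_epoch([])


class TestComputeMetrics:
    def test_balanced_accuracy_is_mean_of_sens_spec(self):
        # sensitivity 0.8 (4/5 positives), specificity 0.6 (3/5 negatives)
        y = np.array([1] * 5 + [0] * 5)
        p = np.array([.9, .9, .9, .9, .1, .8, .8, .2, .2, .2])
        m = compute_metrics(p, y)
        assert m["balanced_accuracy"] == pytest.approx(0.7)

    def test_f1_from_hand_confusion_matrix(self):
        # TP=3, FP=1, FN=1 → precision = recall = F1 = 0.75
        y = np.array([1, 1, 1, 1, 0, 0])
        p = np.array([.9, .9, .9, .1, .9, .1])
        m = compute_metrics(p, y)
        assert m["f1"] == pytest.approx(0.75)

    def test_auc_boundary_cases(self):
        y = np.array([0, 0, 1, 1])
        assert compute_metrics(np.array([.1, .2, .8, .9]), y)["auc"] == 1.0
        assert compute_metrics(np.full(4, 0.5), y)["auc"] == 0.5

    def test_single_class_auc_flagged_not_zero(self):
        m = compute_metrics(np.array([.2, .8]), np.array([1, 1]))
        assert not m["auc_defined"]
        assert np.isnan(m["auc"])

    def test_subgroup_restriction(self):
        y = np.array([1, 0, 1, 0])
        p = np.array([.9, .1, .1, .9])
        mask = np.array([True, True, False, False])
        assert compute_metrics(p, y, subgroup_mask=mask)["accuracy"] == 1.0

    def test_threshold_sweep_has_nine_cells(self):
        rng = np.random.default_rng(4)
        sweep = threshold_sweep(rng.random(50), rng.integers(0, 2, 50))
        assert len(sweep) == 9
        np.testing.assert_allclose(sweep["threshold"],
                                   np.arange(0.1, 0.95, 0.1))


class TestCorrectedTTest:
    def test_identical_vectors_give_null(self):
        r = corrected_t_test([.8, .7, .9], [.8, .7, .9], 60, 20)
        assert r.t_statistic == 0.0
        assert r.p_value == 1.0

    def test_correction_widens_interval(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.8, 0.05, 12)
        b = rng.normal(0.78, 0.05, 12)
        pc = corrected_t_test(a, b, 60, 20).p_value
        pn = corrected_t_test(a, b, 60, 20, corrected=False).p_value
        assert pc >= pn

    def test_bh_adjustment_matches_hand_computation(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.2]),
                                   [0.03, 0.03, 0.2])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 10)
        assert np.all(fdr_adjust(p) >= p)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            corrected_t_test([0.8], [0.7], 60, 20)


class TestGuardedLabels:
    def test_pre_unlock_read_raises(self):
        guard = GuardedLabels(np.array([0, 1, 1]))
        with pytest.raises(LockBoxViolation):
            guard.reveal()

    def test_unlock_allows_and_counts_access(self):
        guard = GuardedLabels(np.array([0, 1, 1]))
        guard.unlock()
        np.testing.assert_array_equal(guard.reveal(), [0, 1, 1])
        assert guard.access_count == 1


class TestRunProtocol:
    @staticmethod
    def separable_dataset(n=100, seed=0):
        rng = np.random.default_rng(seed)
        images = rng.random((n, 64, 64)) * 0.2
        labels = (rng.random(n) < 0.4).astype(int)
        images[labels == 1, 20:40, 20:40] += 0.7
        table = make_table(n, seed=seed)
        table["outcome"] = labels
        return {"images": images, "labels": labels}, table

    @staticmethod
    def builder(seed):
        return build_lightweight(ModelSpec(
            "lightweight", input_side=64, widths=(4, 8, 8, 16, 16, 16),
            seed=seed, learning_rate=1e-3))

    def test_single_cell_produces_four_runs(self):
        dataset, table = self.separable_dataset()
        plan = balanced_partition(table, seed=0)
        report = run_protocol(dataset, self.builder, plan,
                              learning_rates=[1e-3], seeds=[0],
                              max_epochs=2, batch_size=16)
        assert len(report.runs) == 4
        assert report.lockbox_access_count == 1

    def test_separable_problem_reaches_high_balanced_accuracy(self):
        dataset, table = self.separable_dataset(seed=1)
        plan = balanced_partition(table, seed=1)
        report = run_protocol(dataset, self.builder, plan,
                              learning_rates=[1e-3], seeds=[0],
                              max_epochs=8, batch_size=16, folds=[0])
        bal = report.metrics_table["balanced_accuracy"].mean()
        assert bal >= 0.95

    def test_selected_epoch_is_argmin_of_trace(self):
        dataset, table = self.separable_dataset(seed=2)
        plan = balanced_partition(table, seed=2)
        report = run_protocol(dataset, self.builder, plan,
                              learning_rates=[1e-3], seeds=[0],
                              max_epochs=4, batch_size=16, folds=[0])
        run = report.runs[0]
        assert run.selected_epoch == int(np.argmin(run.val_losses))


def test_baseline_logistic_learns_tabular_signal():
    rng = np.random.default_rng(8)
    table = make_table(400, seed=8)
    from neuromontage.models import encode_tabular

    x = encode_tabular(table)
    eta = 2.0 * x[:, 0] + 1.0 * x[:, 1] - 0.5
    table["outcome"] = (rng.random(400) < expit(eta)).astype(int)
    probs = baseline_logistic(table, x)
    m = compute_metrics(probs, table["outcome"].to_numpy())
    assert m["auc"] > 0.75
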