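"""Perturbation engine: anchors, surrogate recovery, counterfactuals."""

import numpy as np
import pytest
from scipy.special import expit

from neuromontage.clear_image import (PerturbationRecord,
                                      build_perturbation_dataset, explain,
                                      find_counterfactuals, fit_surrogate,
                                      perturb, select_contrast)
from neuromontage.roi_image import RegionMaskSet


def grid_masks(side=40, n=4):
    """n disjoint square regions tiling the left half of a canvas."""
    canvas = np.zeros((side, side), dtype=np.int32)
    size = side // n
    for i in range(n):
        canvas[i * size:(i + 1) * size, :side // 2] = i + 1
    return RegionMaskSet(canvas, tuple(range(1, n + 1)))


MASKS = grid_masks()
TARGET = np.full((40, 40), 0.8)
CONTRAST = np.full((40, 40), 0.2)


def region_mean_classifier(weights, bias=0.0):
    """Transparent model: logistic in the per-region mean intensities."""
    def fn(batch):
        b = np.asarray(batch, dtype=float)
        if b.ndim == 2:
            b = b[None]
        z = np.full(len(b), bias)
        for rid, w in weights.items():
            m = MASKS.mask(rid)
            z += w * b[:, m].mean(axis=1)
        return expit(z)
    return fn


class TestSelectContrast:
    def test_lowest_probability_wins(self):
        def clf(img):
            return np.array([float(img[0, 0])])

        pool = [np.full((4, 4), v) for v in (0.9, 0.4, 0.01)]
        idx, img = select_contrast(clf, pool)
        assert idx == 2

    def test_singleton_pool_returns_member(self):
        def clf(img):
            return np.array([0.8])

        pool = [np.zeros((4, 4))]
        idx, img = select_contrast(clf, pool)
        assert idx == 0

    def test_tie_breaks_to_lowest_index(self):
        def clf(img):
            return np.array([0.5])

        pool = [np.zeros((4, 4)), np.ones((4, 4))]
        idx, _ = select_contrast(clf, pool)
        assert idx == 0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            select_contrast(lambda im: np.array([0.5]), [])


class TestPerturb:
    def test_empty_set_is_identity(self):
        out = perturb(TARGET, CONTRAST, MASKS, frozenset())
        np.testing.assert_array_equal(out, TARGET)

    def test_full_set_takes_contrast_inside_union(self):
        out = perturb(TARGET, CONTRAST, MASKS, frozenset(MASKS.region_ids))
        union = MASKS.union_mask()
        np.testing.assert_array_equal(out[union], CONTRAST[union])
        np.testing.assert_array_equal(out[~union], TARGET[~union])

    def test_single_region_swap_is_local(self):
        out = perturb(TARGET, CONTRAST, MASKS, frozenset({2}))
        diff = out != TARGET
        np.testing.assert_array_equal(diff, MASKS.mask(2))

    def test_idempotent(self):
        once = perturb(TARGET, CONTRAST, MASKS, frozenset({1, 3}))
        np.testing.assert_array_equal(
            perturb(once, CONTRAST, MASKS, frozenset({1, 3})), once)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            perturb(TARGET, np.zeros((8, 8)), MASKS, frozenset({1}))


class TestPerturbationDataset:
    CLF = staticmethod(region_mean_classifier({1: 6.0, 2: -4.0}, bias=-1.0))

    def test_default_n_gives_at_least_1000_records(self):
        records = build_perturbation_dataset(self.CLF, TARGET, CONTRAST,
                                             MASKS, seed=0)
        assert len(records) >= 1000

    def test_identity_anchors_match_direct_calls(self):
        # the perturbed images themselves are exact: ∅ reproduces the
        # target bit-for-bit (TestPerturb); probabilities agree to float
        # summation order across batch shapes
        records = build_perturbation_dataset(self.CLF, TARGET, CONTRAST,
                                             MASKS, n=50, seed=1)
        by_set = {r.replaced_set: r.probability for r in records}
        assert by_set[frozenset()] == \
            pytest.approx(float(self.CLF(TARGET)[0]), abs=1e-12)
        full = frozenset(MASKS.region_ids)
        assert by_set[full] == pytest.approx(
            float(self.CLF(perturb(TARGET, CONTRAST, MASKS, full))[0]),
            abs=1e-12)

    def test_deterministic_given_seed(self):
        a = build_perturbation_dataset(self.CLF, TARGET, CONTRAST, MASKS,
                                       n=100, seed=3)
        b = build_perturbation_dataset(self.CLF, TARGET, CONTRAST, MASKS,
                                       n=100, seed=3)
        assert [(r.replaced_set, r.probability) for r in a] == \
            [(r.replaced_set, r.probability) for r in b]

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            PerturbationRecord(frozenset(), 1.4)


class TestSurrogate:
    def test_generate_and_recover_known_coefficients(self):
        rng = np.random.default_rng(0)
        beta_true = np.array([1.5, -2.0, 0.8, 0.0])
        records = []
        for _ in range(2000):
            x = rng.integers(0, 2, 4)
            p = expit(float(x @ beta_true) - 0.3)
            records.append(PerturbationRecord(
                frozenset(int(r) + 1 for r in np.where(x)[0]), p))
        exp = fit_surrogate(records, (1, 2, 3, 4))
        fitted = np.array([exp.coefficients[r] for r in (1, 2, 3, 4)])
        np.testing.assert_allclose(fitted, beta_true, atol=0.1)
        assert exp.intercept == pytest.approx(-0.3, abs=0.1)

    def test_constant_response_gives_null_coefficients(self):
        rng = np.random.default_rng(1)
        records = [PerturbationRecord(
            frozenset(int(r) + 1 for r in np.where(rng.integers(0, 2, 4))[0]),
            0.5) for _ in range(200)]
        exp = fit_surrogate(records, (1, 2, 3, 4))
        assert all(abs(c) < 1e-3 for c in exp.coefficients.values())
        assert exp.mean_fidelity_error < 1e-6

    def test_inert_region_gets_null_coefficient(self):
        clf = region_mean_classifier({1: 8.0}, bias=-2.0)
        records = build_perturbation_dataset(clf, TARGET, CONTRAST, MASKS,
                                             n=500, seed=2)
        exp = fit_surrogate(records, MASKS.region_ids)
        assert abs(exp.coefficients[1]) > 10 * abs(exp.coefficients[4])
        assert abs(exp.coefficients[4]) < 0.05

    def test_degenerate_design_rejected(self):
        records = [PerturbationRecord(frozenset(), 0.5)] * 5
        with pytest.raises(ValueError):
            fit_surrogate(records, (1, 2))


class TestCounterfactuals:
    CLF = staticmethod(region_mean_classifier({1: 40.0}, bias=-18.0))
    # target: region-1 mean 0.8 → z = 14 → class 1; replacing region 1
    # alone drops mean to 0.2 → z = −10 → class 0

    def test_single_causal_region_is_minimal_counterfactual(self):
        records = build_perturbation_dataset(self.CLF, TARGET, CONTRAST,
                                             MASKS, n=200, seed=4)
        cfs = find_counterfactuals(records)
        assert frozenset({1}) in cfs
        assert all(1 in s for s in cfs)
        assert min(len(s) for s in cfs) == 1

    def test_minimality_removing_any_region_breaks_flip(self):
        def prober(subset):
            return float(self.CLF(
                perturb(TARGET, CONTRAST, MASKS, subset))[0])

        records = build_perturbation_dataset(self.CLF, TARGET, CONTRAST,
                                             MASKS, n=200, seed=5)
        for s in find_counterfactuals(records, prober=prober):
            base = int(prober(frozenset()) >= 0.5)
            for rid in s:
                assert int(prober(s - {rid}) >= 0.5) == base

    def test_no_flip_gives_empty_list(self):
        clf = region_mean_classifier({}, bias=2.0)    # constant class 1
        records = build_perturbation_dataset(clf, TARGET, CONTRAST, MASKS,
                                             n=100, seed=6)
        assert find_counterfactuals(records) == []

    def test_missing_empty_set_rejected(self):
        with pytest.raises(ValueError):
            find_counterfactuals([PerturbationRecord(frozenset({1}), 0.9)])


class TestImportanceMap:
    def test_regions_take_normalised_scores(self):
        from neuromontage.clear_image import importance_map

        m = importance_map(MASKS, {1: 2.0, 2: -1.0, 3: 0.0, 4: 0.0})
        assert m[MASKS.mask(1)].max() == 1.0
        assert m[MASKS.mask(2)].min() == -0.5
        assert not m[MASKS.mask(3)].any()
        assert not m[~MASKS.union_mask()].any()

    def test_all_zero_scores_give_zero_canvas(self):
        from neuromontage.clear_image import importance_map

        assert not importance_map(MASKS, {1: 0.0, 2: 0.0}).any()


class TestExplain:
    def test_full_explanation_is_faithful_on_transparent_model(self):
        clf = region_mean_classifier({1: 6.0, 3: -5.0}, bias=-0.4)
        exp = explain(clf, TARGET, CONTRAST, MASKS, n=400, seed=7)
        order = sorted(exp.coefficients,
                       key=lambda r: abs(exp.coefficients[r]), reverse=True)
        assert set(order[:2]) == {1, 3}
        assert exp.mean_fidelity_error < 0.05
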