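import numpy as np
import pytest

from marsa._pairs import n_pairs
from marsa.exceptions import InvalidArgumentError, UndefinedCorrelationError
from marsa.rdm import RDMStack, devectorize
from marsa.reweight import (
    crossval_reweight,
    field_reweight,
    make_folds,
    nnls_fit,
    pair_partition,
    predict_and_score,
    variance_partition,
)
from marsa.searchlight import BrainRDMField


class TestMakeFolds:
    def test_default_split_of_100_items(self):
        plan = make_folds(100, seed=1)
        assert len(plan.folds) == 10
        for train, test in plan.folds:
            assert train.size == 70 and test.size == 30
            assert np.intersect1d(train, test).size == 0
            assert np.union1d(train, test).size == 100

    def test_small_split(self):
        plan = make_folds(10, train_frac=0.7, n_folds=3, seed=0)
        for train, test in plan.folds:
            assert train.size == 7 and test.size == 3

    def test_determinism(self):
        a = make_folds(30, seed=5)
        b = make_folds(30, seed=5)
        for (ta, sa), (tb, sb) in zip(a.folds, b.folds):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)

    @pytest.mark.parametrize("kwargs", [dict(train_frac=0.0), dict(train_frac=0.98), dict(n_folds=0)])
    def test_invalid_plans_rejected(self, kwargs):
        with pytest.raises(InvalidArgumentError):
            make_folds(30, **kwargs)


class TestPairPartition:
    def test_counts_for_70_30_split(self):
        plan = make_folds(100, seed=2)
        train_pairs, test_pairs = pair_partition(plan.folds[0], 100)
        assert train_pairs.size == 70 * 69 // 2 == 2415
        assert test_pairs.size == 30 * 29 // 2 == 435

    def test_all_items_in_train_gives_all_pairs(self):
        fold = (np.arange(100), np.array([], dtype=int))
        train_pairs, test_pairs = pair_partition(fold, 100)
        assert train_pairs.size == 4950 and test_pairs.size == 0

    def test_conservation_with_mixed_pairs(self):
        plan = make_folds(30, seed=3)
        train, test = plan.folds[0]
        train_pairs, test_pairs = pair_partition(plan.folds[0], 30)
        mixed = n_pairs(30) - train_pairs.size - test_pairs.size
        assert mixed == train.size * test.size


class TestNNLS:
    def test_single_predictor_scaling(self, rng):
        p = rng.uniform(0.1, 1, size=(50, 1))
        w = nnls_fit(p, 2.0 * p[:, 0])
        assert w[0] == pytest.approx(2.0, abs=1e-10)

    def test_recovers_sparse_nonnegative_mixture(self, rng):
        basis = np.linalg.qr(rng.normal(size=(60, 3)))[0]  # orthonormal predictors
        target = 1.5 * basis[:, 0] + 0.5 * basis[:, 2]
        w = nnls_fit(basis, target)
        np.testing.assert_allclose(w, [1.5, 0.0, 0.5], atol=1e-8)

    def test_orthogonal_target_gets_zero_weight(self):
        # 3-pair toy: predictor along (1,1,0), target along (0,0,1)
        p = np.array([[1.0], [1.0], [0.0]])
        target = np.array([0.0, 0.0, 1.0])
        np.testing.assert_allclose(nnls_fit(p, target), [0.0])

    def test_optimality_against_random_weights(self, rng):
        """Small-instance oracle: the convex optimum beats 1000 random
        nonnegative weight vectors."""
        p = rng.uniform(size=(30, 4))
        target = rng.uniform(size=30)
        w = nnls_fit(p, target)
        best = np.sum((p @ w - target) ** 2)
        candidates = rng.uniform(0, 2, size=(1000, 4))
        objs = np.sum((candidates @ p.T - target) ** 2, axis=1)
        assert best <= objs.min() + 1e-12

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidArgumentError):
            nnls_fit(np.array([[np.nan]]), np.array([1.0]))


class TestScoring:
    def test_exact_reproduction_scores_one(self, rng):
        p = rng.uniform(size=(20, 2))
        w = np.array([0.5, 1.5])
        assert predict_and_score(w, p, p @ w) == pytest.approx(1.0)

    def test_sign_flip_scores_minus_one(self, rng):
        p = rng.uniform(size=(20, 2))
        w = np.array([0.5, 1.5])
        assert predict_and_score(w, p, -(p @ w)) == pytest.approx(-1.0)

    def test_random_weights_near_zero_on_independent_target(self, rng):
        rs = [
            predict_and_score(
                rng.uniform(size=3), rng.uniform(size=(435, 3)), rng.uniform(size=435)
            )
            for _ in range(50)
        ]
        assert abs(np.mean(rs)) < 0.05

    def test_constant_prediction_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            predict_and_score(np.zeros(1), np.ones((5, 1)), np.arange(5.0))


class TestCrossvalReweight:
    def test_single_subject_predicting_itself(self, cohort12):
        one = RDMStack(cohort12.n_items, cohort12.vectors[:1])
        plan = make_folds(30, seed=4)
        res = crossval_reweight(one, devectorize(cohort12.vectors[0], 30), plan)
        assert res.mean_r == pytest.approx(1.0, abs=1e-10)

    def test_noiseless_mixture_recovery(self, cohort12, rng):
        w_true = rng.uniform(0.1, 1.0, cohort12.n_rows)
        target = devectorize(cohort12.vectors.T @ w_true, 30)
        plan = make_folds(30, seed=4)
        res = crossval_reweight(cohort12, target, plan)
        assert res.mean_r >= 0.999
        w_hat = res.weights.mean(axis=0)
        cos = w_true @ w_hat / (np.linalg.norm(w_true) * np.linalg.norm(w_hat))
        assert cos >= 0.99

    def test_weights_are_nonnegative(self, cohort12, rng):
        target = devectorize(np.abs(rng.normal(size=n_pairs(30))), 30)
        res = crossval_reweight(cohort12, target, make_folds(30, seed=1))
        assert np.all(res.weights >= 0)

    def test_no_leakage_from_test_items(self, cohort12, rng):
        """Deleting the test items entirely before fitting leaves the fold's
        weights bit-for-bit unchanged."""
        from marsa._pairs import pair_indices
        from marsa.reweight import nnls_fit, pair_partition

        target = cohort12.vectors.T @ rng.uniform(0.1, 1.0, cohort12.n_rows)
        plan = make_folds(30, seed=6, n_folds=3)
        for fold in plan.folds:
            train_pairs, _ = pair_partition(fold, 30)
            w_full = nnls_fit(cohort12.vectors.T[train_pairs], target[train_pairs])
            # rebuild the problem with the test items physically removed
            reduced_pairs = pair_indices(fold[0], 30)
            w_reduced = nnls_fit(cohort12.vectors.T[reduced_pairs], target[reduced_pairs])
            np.testing.assert_array_equal(w_full, w_reduced)

    def test_item_count_mismatch_rejected(self, cohort12):
        with pytest.raises(InvalidArgumentError):
            crossval_reweight(cohort12, np.zeros((10, 10)), make_folds(10, seed=0))


class TestFieldReweight:
    def test_single_center_field_equals_crossval(self, cohort12, rng):
        target = cohort12.vectors.T @ rng.uniform(0.1, 1.0, cohort12.n_rows)
        field = BrainRDMField(
            n_items=30, centers=np.array([[0, 0, 0]]), vectors=target[None, :]
        )
        plan = make_folds(30, seed=2)
        fits, skipped = field_reweight(cohort12, field, plan)
        assert not skipped
        assert fits[0] == pytest.approx(crossval_reweight(cohort12, target, plan).mean_r)

    def test_degenerate_center_skipped_leniently(self, cohort12):
        field = BrainRDMField(
            n_items=30,
            centers=np.array([[0, 0, 0], [1, 1, 1]]),
            vectors=np.vstack([cohort12.vectors[0], np.ones(n_pairs(30))]),
        )
        fits, skipped = field_reweight(cohort12, field, make_folds(30, seed=2))
        assert np.isfinite(fits[0]) and np.isnan(fits[1])
        assert skipped == [(1, 1, 1)]


class TestVariancePartition:
    def test_identical_stacks_have_zero_unique(self, cohort12, rng):
        target = devectorize(cohort12.vectors.T @ rng.uniform(0.1, 1.0, 12), 30)
        plan = make_folds(30, seed=8)
        vp = variance_partition(cohort12, cohort12, target, plan)
        assert vp.r2_joint == pytest.approx(vp.r2_visual)
        assert vp.r2_joint == pytest.approx(vp.r2_linguistic)
        assert vp.unique_linguistic == pytest.approx(0.0, abs=1e-12)
        assert vp.unique_visual == pytest.approx(0.0, abs=1e-12)

    def test_shared_only_target_has_small_unique_terms(self, gt3d):
        from marsa.synthetic import TwoModalitySpec, simulate_two_modalities

        spec = TwoModalitySpec(1.0, 0.0, 0.0, noise_sd=0.1, seed=21)
        vis, lin, sources = simulate_two_modalities(gt3d, spec, 12)
        plan = make_folds(30, seed=3)
        vp = variance_partition(vis, lin, sources["shared"], plan)
        assert abs(vp.unique_linguistic) < 0.05
        assert abs(vp.unique_visual) < 0.05

    def test_planted_unique_source_detected(self, gt3d):
        from marsa.synthetic import TwoModalitySpec, simulate_two_modalities

        spec = TwoModalitySpec(1.0, 0.0, 0.5, noise_sd=0.1, seed=22)
        vis, lin, sources = simulate_two_modalities(gt3d, spec, 12)
        target = sources["shared"] + 0.5 * sources["unique_linguistic"]
        vp = variance_partition(vis, lin, target, make_folds(30, seed=5))
        assert vp.unique_linguistic > vp.unique_visual
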