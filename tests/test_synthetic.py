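import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr

from marsa.exceptions import InvalidArgumentError
from marsa.rdm import corrdist_rdm, fixed_effects_rsa, vectorize
from marsa.synthetic import (
    CohortSpec,
    RegionSpec,
    TwoModalitySpec,
    ball_region,
    make_ground_truth,
    simulate_arrangement_positions,
    simulate_brain,
    simulate_subject_rdm,
    simulate_two_modalities,
    unit_rms,
)


class TestGroundTruth:
    def test_rdm_invariants(self):
        gt = make_ground_truth(4, 2, n_categories=1, cat_separation=0, seed=1)
        assert gt.true_rdm.shape == (4, 4)
        np.testing.assert_array_equal(gt.true_rdm, gt.true_rdm.T)
        np.testing.assert_array_equal(np.diag(gt.true_rdm), np.zeros(4))
        np.testing.assert_allclose(gt.true_rdm, squareform(pdist(gt.coords)))

    def test_hundred_items_have_4950_pairs(self):
        gt = make_ground_truth(100, 3, n_categories=4, cat_separation=1.0, seed=0)
        assert vectorize(gt.true_rdm).size == 4950

    def test_category_separation_dominates_within_spread(self):
        gt = make_ground_truth(
            60, 3, n_categories=4, cat_separation=10.0, seed=2, within_sd=0.1
        )
        same = gt.categories[:, None] == gt.categories[None, :]
        iu = np.triu_indices(60, k=1)
        within = gt.true_rdm[iu][same[iu]]
        between = gt.true_rdm[iu][~same[iu]]
        assert between.mean() > within.mean()

    def test_determinism(self):
        a = make_ground_truth(10, 2, 2, 1.0, seed=5)
        b = make_ground_truth(10, 2, 2, 1.0, seed=5)
        np.testing.assert_array_equal(a.coords, b.coords)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_items=2, n_dims=2), dict(n_items=5, n_dims=0), dict(n_items=5, n_dims=2, n_categories=9)],
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(InvalidArgumentError):
            make_ground_truth(**kwargs)


class TestSubjectRDM:
    def test_pure_shared_noiseless_reproduces_truth(self, gt3d):
        spec = CohortSpec(n_subjects=2, shared_w=1.0, idio_w=0.0, noise_sd=0.0, seed=1)
        rdm = simulate_subject_rdm(gt3d, spec, 0)
        assert spearmanr(vectorize(rdm), vectorize(gt3d.true_rdm))[0] == pytest.approx(1.0)

    def test_pure_idiosyncratic_subjects_are_uncorrelated(self, gt3d):
        rhos = []
        for rep in range(100):
            spec = CohortSpec(n_subjects=2, shared_w=0.0, idio_w=1.0, noise_sd=0.0, seed=rep)
            a = simulate_subject_rdm(gt3d, spec, 0)
            b = simulate_subject_rdm(gt3d, spec, 1)
            rhos.append(spearmanr(vectorize(a), vectorize(b))[0])
        assert abs(np.mean(rhos)) < 0.04

    def test_recovery_degrades_monotonically_with_noise(self, gt3d):
        means = []
        for noise in (0.1, 0.5, 1.5):
            rhos = []
            for rep in range(30):
                spec = CohortSpec(2, shared_w=1.0, idio_w=0.0, noise_sd=noise, seed=rep)
                rdm = simulate_subject_rdm(gt3d, spec, 0)
                rhos.append(spearmanr(vectorize(rdm), vectorize(gt3d.true_rdm))[0])
            m = np.mean(rhos)
            assert 0 < m < 1
            means.append(m)
        assert means[0] > means[1] > means[2]

    def test_mixture_recovery_monotone_in_source_weight(self, gt3d):
        """Correlation with the shared source rises with its mixture weight."""
        grid_means = []
        for w in (0.2, 1.0, 3.0):
            rhos = []
            for rep in range(50):
                spec = CohortSpec(2, shared_w=w, idio_w=1.0, noise_sd=0.05, seed=1000 + rep)
                rdm = simulate_subject_rdm(gt3d, spec, 0)
                rhos.append(spearmanr(vectorize(rdm), vectorize(gt3d.true_rdm))[0])
            grid_means.append(np.mean(rhos))
        assert grid_means[0] < grid_means[1] < grid_means[2]

    def test_invalid_spec_rejected(self):
        with pytest.raises(InvalidArgumentError):
            CohortSpec(n_subjects=2, shared_w=0.0, idio_w=0.0)


class TestTwoModalities:
    def test_no_unique_no_noise_gives_identical_averages(self, gt3d):
        spec = TwoModalitySpec(shared_w=1.0, noise_sd=0.0, seed=3)
        vis, lin, _ = simulate_two_modalities(gt3d, spec, 4)
        assert fixed_effects_rsa(vis, lin) == pytest.approx(1.0)

    def test_unique_sources_reduce_cross_modal_agreement(self, gt3d):
        spec = TwoModalitySpec(
            shared_w=1.0, unique_visual_w=0.5, unique_linguistic_w=0.5, noise_sd=0.1, seed=3
        )
        vis, lin, _ = simulate_two_modalities(gt3d, spec, 20)
        from marsa.rdm import RDMStack

        cross = fixed_effects_rsa(vis, lin)
        half_a = RDMStack(vis.n_items, vis.vectors[:10])
        half_b = RDMStack(vis.n_items, vis.vectors[10:])
        within = fixed_effects_rsa(half_a, half_b)
        assert cross < within

    def test_sources_are_returned_and_independent(self, gt3d):
        spec = TwoModalitySpec(1.0, 0.5, 0.5, 0.0, seed=9)
        _, _, sources = simulate_two_modalities(gt3d, spec, 3)
        rho = spearmanr(
            vectorize(sources["unique_visual"]), vectorize(sources["unique_linguistic"])
        )[0]
        assert abs(rho) < 0.35

    def test_determinism_bitwise(self, gt3d):
        spec = TwoModalitySpec(1.0, 0.3, 0.3, 0.1, seed=4)
        v1, l1, _ = simulate_two_modalities(gt3d, spec, 5)
        v2, l2, _ = simulate_two_modalities(gt3d, spec, 5)
        np.testing.assert_array_equal(v1.vectors, v2.vectors)
        np.testing.assert_array_equal(l1.vectors, l2.vectors)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(InvalidArgumentError):
            TwoModalitySpec(shared_w=0.0, unique_visual_w=0.0, unique_linguistic_w=0.0)


class TestArrangementPositions:
    def test_equilateral_dissimilarities_give_equal_distances(self):
        d = np.ones((3, 3)) - np.eye(3)
        pos = simulate_arrangement_positions(d, arena_radius=1.0, placement_noise=0.0)
        dists = pdist(pos)
        np.testing.assert_allclose(dists, dists[0], atol=1e-10)

    def test_embeddable_rdm_reproduced_up_to_scale(self, gt2d):
        pos = simulate_arrangement_positions(gt2d.true_rdm, 1.0, 0.0)
        r = pearsonr(pdist(pos), vectorize(gt2d.true_rdm))[0]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_positions_stay_in_arena(self, gt2d):
        pos = simulate_arrangement_positions(gt2d.true_rdm, 1.0, placement_noise=0.5, seed=3)
        assert np.all(np.linalg.norm(pos, axis=1) <= 1.0 + 1e-9)

    def test_determinism(self, gt2d):
        a = simulate_arrangement_positions(gt2d.true_rdm, 1.0, 0.2, seed=8)
        b = simulate_arrangement_positions(gt2d.true_rdm, 1.0, 0.2, seed=8)
        np.testing.assert_array_equal(a, b)

    def test_invalid_radius_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simulate_arrangement_positions(np.zeros((3, 3)), arena_radius=0.0)


class TestSimulateBrain:
    def test_noiseless_plant_preserves_source_rank_order(self, gt3d):
        src = unit_rms(gt3d.true_rdm)
        region = ball_region((5, 5, 5), 2.0, (10, 10, 10))
        brain = simulate_brain(
            [src], (10, 10, 10), [RegionSpec(region, 0)], 0.0, 1, seed=2, n_items=30
        )[0]
        lin = -np.ones((10, 10, 10), int)
        lin[brain.mask] = np.arange(brain.mask.sum())
        cols = lin[region[:, 0], region[:, 1], region[:, 2]]
        prdm = corrdist_rdm(brain.patterns[:, cols])
        assert spearmanr(vectorize(prdm), vectorize(src))[0] >= 0.95

    def test_overlapping_regions_rejected(self, gt3d):
        src = unit_rms(gt3d.true_rdm)
        a = ball_region((4, 4, 4), 2.0, (8, 8, 8))
        b = ball_region((5, 5, 5), 2.0, (8, 8, 8))
        with pytest.raises(InvalidArgumentError):
            simulate_brain([src], (8, 8, 8), [RegionSpec(a, 0), RegionSpec(b, 0)], 0.1, 1)

    def test_region_outside_grid_rejected(self, gt3d):
        src = unit_rms(gt3d.true_rdm)
        region = ball_region((7, 7, 7), 2.0, (10, 10, 10))  # valid in 10^3 ...
        with pytest.raises(InvalidArgumentError):
            simulate_brain([src], (6, 6, 6), [RegionSpec(region, 0)], 0.1, 1)  # ... not 6^3

    def test_identical_seeds_identical_volumes(self, gt3d):
        src = unit_rms(gt3d.true_rdm)
        region = ball_region((3, 3, 3), 1.5, (7, 7, 7))
        kw = dict(noise_sd=0.3, n_subjects=2, seed=5, n_items=30)
        b1 = simulate_brain([src], (7, 7, 7), [RegionSpec(region, 0)], **kw)
        b2 = simulate_brain([src], (7, 7, 7), [RegionSpec(region, 0)], **kw)
        for x, y in zip(b1, b2):
            np.testing.assert_array_equal(x.patterns, y.patterns)

    def test_subjects_differ(self, gt3d):
        src = unit_rms(gt3d.true_rdm)
        b = simulate_brain([src], (6, 6, 6), [], 1.0, 2, seed=1, n_items=30)
        assert not np.array_equal(b[0].patterns, b[1].patterns)


def test_unit_rms_normalizes_offdiagonal(gt3d):
    scaled = unit_rms(gt3d.true_rdm)
    iu = np.triu_indices(30, k=1)
    assert np.sqrt(np.mean(scaled[iu] ** 2)) == pytest.approx(1.0)
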