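"""Vote casting, Gaussian-transform aggregation and HMM chain decoding."""

import numpy as np
import pytest

from spinevb.errors import (
    DecodingError,
    InsufficientDataError,
    SamplingError,
    TrainingError,
)
from spinevb.features import FeatureConfig
from spinevb.localization import (
    AggregationConfig,
    ChainPrior,
    ForestConfig,
    GridSpec,
    ResponseVolume,
    VoteSet,
    aggregate_votes_exact,
    aggregate_votes_ifgt,
    cast_votes,
    decode_center_chain,
    learn_chain_prior,
    sample_localization_patches,
    train_center_regressor,
)
from spinevb.volume_io import CenterAnnotation, Volume3D

from _oracles import brute_force_chain


def make_volume(rng, shape=(20, 24, 24), spacing=(1.0, 1.0, 1.0)):
    return Volume3D(rng.random(shape), spacing=spacing)


FCFG = FeatureConfig(patch_size=(8, 8, 8), modality="mr")


class TestPatchSampling:
    def test_centers_lie_in_region_and_valid_area(self, rng):
        vol = make_volume(rng)
        region = (np.array([2, 3, 0]), np.array([15, 20, 24]))
        s = sample_localization_patches(
            vol, (10.0, 10.0, 10.0), 200, region=region, cfg=FCFG, seed=3
        )
        # patch [c-4, c+4) must fit: c in [4, shape-4]
        for c in s.patch_centers:
            assert all(
                max(region[0][a], 4) <= c[a] <= min(region[1][a] - 1,
                                                    vol.shape[a] - 4)
                for a in range(3)
            )

    def test_patch_at_gt_center_has_zero_displacement(self, rng):
        vol = make_volume(rng)
        gt = vol.physical((10, 12, 12))
        s = sample_localization_patches(vol, gt, 500, cfg=FCFG, seed=0)
        match = np.all(s.patch_centers == (10, 12, 12), axis=1)
        if match.any():
            np.testing.assert_allclose(s.displacements[match], 0.0, atol=1e-12)
        # displacement definition holds everywhere
        np.testing.assert_allclose(
            s.displacements, gt - vol.physical(s.patch_centers), atol=1e-12
        )

    def test_empty_region_raises(self, rng):
        vol = make_volume(rng)
        with pytest.raises(SamplingError):
            sample_localization_patches(
                vol, (0.0, 0.0, 0.0), 10,
                region=(np.array([0, 0, 0]), np.array([2, 2, 2])),
                cfg=FCFG, seed=0,
            )

    def test_production_sample_counts(self):
        from spinevb.pipeline import PipelineConfig

        cfg = PipelineConfig()
        assert cfg.n_train == 15000
        assert cfg.n_test == 10000


class TestRegressionForest:
    def test_identical_displacements_are_reproduced(self, rng):
        vol = make_volume(rng)
        s = sample_localization_patches(vol, (5.0, 5.0, 5.0), 300, cfg=FCFG, seed=1)
        s.displacements = np.tile([1.5, -2.0, 0.5], (len(s.features), 1))
        forest = train_center_regressor(s, ForestConfig(n_trees=5, seed=0))
        pred = forest.predict(s.features[:20])
        np.testing.assert_allclose(pred, np.tile([1.5, -2.0, 0.5], (20, 1)),
                                   atol=1e-9)

    def test_root_only_tree_predicts_training_mean(self, rng):
        vol = make_volume(rng)
        s = sample_localization_patches(vol, (5.0, 5.0, 5.0), 200, cfg=FCFG, seed=1)
        forest = train_center_regressor(
            s, ForestConfig(n_trees=1, max_depth=0, bootstrap=False, seed=0)
        )
        pred = forest.predict(s.features[:7])
        expected = s.displacements.mean(axis=0)
        np.testing.assert_allclose(pred, np.tile(expected, (7, 1)), atol=1e-9)

    def test_same_seed_gives_identical_forests(self, rng):
        vol = make_volume(rng)
        s = sample_localization_patches(vol, (5.0, 5.0, 5.0), 300, cfg=FCFG, seed=1)
        cfg = ForestConfig(n_trees=4, seed=77)
        f1 = train_center_regressor(s, cfg)
        f2 = train_center_regressor(s, cfg)
        probe = np.random.default_rng(0).random((50, FCFG.d_f))
        np.testing.assert_array_equal(
            f1.predict_per_tree(probe), f2.predict_per_tree(probe)
        )

    def test_empty_training_set_raises(self):
        with pytest.raises(TrainingError):
            train_center_regressor([], ForestConfig())


class TestCastVotes:
    def test_constant_forest_votes_at_center_plus_displacement(self, rng):
        vol = make_volume(rng)
        s = sample_localization_patches(vol, (5.0, 5.0, 5.0), 200, cfg=FCFG, seed=1)
        d0 = np.array([2.0, -1.0, 3.0])
        s.displacements = np.tile(d0, (len(s.features), 1))
        forest = train_center_regressor(s, ForestConfig(n_trees=3, seed=0))
        votes = cast_votes(forest, vol, 50, cfg=FCFG, seed=9)
        assert len(votes) == 50 * 3
        # every vote is its patch center plus d0
        offsets = votes.votes.reshape(3, 50, 3) - d0
        base = offsets[0]
        for t in range(3):
            np.testing.assert_allclose(offsets[t], base, atol=1e-9)

    @pytest.mark.parametrize("n_trees", [1, 5, 20])
    def test_vote_count_is_patches_times_trees(self, rng, n_trees):
        vol = make_volume(rng)
        s = sample_localization_patches(vol, (5.0, 5.0, 5.0), 100, cfg=FCFG, seed=1)
        forest = train_center_regressor(s, ForestConfig(n_trees=n_trees, seed=0))
        votes = cast_votes(forest, vol, 40, cfg=FCFG, seed=2)
        assert len(votes) == 40 * n_trees


class TestExactAggregation:
    def test_single_vote_peaks_at_its_node(self):
        votes = VoteSet(np.array([[3.0, 4.0, 5.0]]), np.ones(1))
        grid = GridSpec((8, 8, 8), np.ones(3), np.zeros(3))
        resp = aggregate_votes_exact(votes, grid)
        assert resp.data[3, 4, 5] == pytest.approx(1.0)
        flat = resp.data.ravel()
        assert np.argmax(flat) == np.ravel_multi_index((3, 4, 5), (8, 8, 8))
        assert np.sum(flat == flat.max()) == 1

    def test_coincident_votes_add(self):
        votes = VoteSet(np.array([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]]), np.ones(2))
        grid = GridSpec((5, 5, 5), np.ones(3), np.zeros(3))
        resp = aggregate_votes_exact(votes, grid)
        assert resp.data[2, 2, 2] == pytest.approx(2.0)

    def test_matches_independent_double_loop(self, rng):
        votes = VoteSet(rng.uniform(0, 7, (100, 3)), rng.uniform(0.5, 2, 100))
        grid = GridSpec((8, 8, 8), np.array([2.0, 1.0, 1.0]),
                        np.array([1.0, 0.0, -2.0]))
        agg = AggregationConfig(h=1.5)
        resp = aggregate_votes_exact(votes, grid, agg)
        u = (votes.votes - grid.origin) / grid.spacing
        expected = np.zeros((8, 8, 8))
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    for (vx, vy, vz), w in zip(u, votes.weights):
                        d2 = (i - vx) ** 2 + (j - vy) ** 2 + (k - vz) ** 2
                        expected[i, j, k] += w * np.exp(-d2 / agg.h**2)
        np.testing.assert_allclose(resp.data, expected, rtol=1e-12, atol=1e-12)

    def test_translation_equivariance(self, rng):
        # dyadic coordinates make the one-voxel shift exact in floats
        votes = rng.integers(8, 48, (40, 3)) / 8.0
        w = np.ones(40)
        grid1 = GridSpec((8, 8, 8), np.ones(3), np.zeros(3))
        grid2 = GridSpec((8, 8, 8), np.ones(3), np.ones(3))
        r1 = aggregate_votes_exact(VoteSet(votes, w), grid1)
        r2 = aggregate_votes_exact(VoteSet(votes + 1.0, w), grid2)
        np.testing.assert_array_equal(r1.data, r2.data)


class TestIFGT:
    def test_single_vote_single_cluster_matches_exact(self):
        votes = VoteSet(np.array([[3.3, 2.7, 4.1]]), np.ones(1))
        grid = GridSpec((8, 8, 8), np.ones(3), np.zeros(3))
        agg = AggregationConfig(ifgt_order=25, ifgt_clusters=1)
        exact = aggregate_votes_exact(votes, grid, agg)
        fast = aggregate_votes_ifgt(votes, grid, agg)
        np.testing.assert_allclose(fast.data, exact.data, rtol=1e-8, atol=1e-12)

    def test_relative_error_within_epsilon_on_random_votes(self, rng):
        votes = VoteSet(rng.normal(6, 2.0, (500, 3)), rng.uniform(0.5, 2, 500))
        grid = GridSpec((12, 12, 12), np.ones(3), np.zeros(3))
        agg = AggregationConfig()
        exact = aggregate_votes_exact(votes, grid, agg)
        fast = aggregate_votes_ifgt(votes, grid, agg)
        sig = exact.data > 1e-6 * exact.data.max()
        rel = np.abs(fast.data[sig] - exact.data[sig]) / exact.data[sig]
        assert rel.max() <= agg.ifgt_epsilon

    def test_forced_expansion_is_accurate(self, rng):
        votes = VoteSet(rng.normal(5, 1.0, (200, 3)), np.ones(200))
        grid = GridSpec((10, 10, 10), np.ones(3), np.zeros(3))
        agg = AggregationConfig(ifgt_order=30, ifgt_clusters=16)
        exact = aggregate_votes_exact(votes, grid, agg)
        fast = aggregate_votes_ifgt(votes, grid, agg)
        sig = exact.data > 1e-6 * exact.data.max()
        rel = np.abs(fast.data[sig] - exact.data[sig]) / exact.data[sig]
        assert rel.max() <= 1e-2

    def test_error_decreases_with_expansion_order(self, rng):
        # compact votes and a tight target box keep the expansion in its
        # monotone regime
        votes = VoteSet(4.0 + rng.uniform(-1, 1, (50, 3)), np.ones(50))
        grid = GridSpec((9, 9, 9), np.ones(3), np.zeros(3))
        exact = aggregate_votes_exact(votes, grid, AggregationConfig())
        errors = []
        for order in (4, 6, 8, 10, 12):
            agg = AggregationConfig(ifgt_order=order, ifgt_clusters=4)
            fast = aggregate_votes_ifgt(votes, grid, agg)
            errors.append(np.abs(fast.data - exact.data).max())
        for a, b in zip(errors, errors[1:]):
            assert b <= a + 1e-12


class TestChainPrior:
    def test_identical_offsets_give_floored_identity(self):
        ann = CenterAnnotation(
            centers=[[0, 0, 0], [0, 20, 0], [0, 40, 0]], vb_names=list("abc")
        )
        prior = learn_chain_prior([ann, ann, ann], variance_floor=1.0)
        np.testing.assert_allclose(prior.means, [[0, 20, 0], [0, 20, 0]])
        for cov in prior.covs:
            np.testing.assert_allclose(cov, np.eye(3), atol=1e-9)

    def test_statistics_match_brute_force(self, rng):
        anns = []
        offsets = rng.normal([0, 22, 1], [2.0, 3.0, 2.0], size=(8, 3))
        for o in offsets:
            c0 = rng.normal(0, 5, 3)
            anns.append(CenterAnnotation(centers=[c0, c0 + o], vb_names=["a", "b"]))
        prior = learn_chain_prior(anns, variance_floor=1.0)
        np.testing.assert_allclose(prior.means[0], offsets.mean(axis=0), atol=1e-9)
        cov = np.cov(offsets.T, ddof=1)
        cov = cov + np.diag(np.maximum(1.0 - np.diag(cov), 0.0))
        np.testing.assert_allclose(prior.covs[0], cov, atol=1e-6)

    def test_chain_structure(self):
        anns = [
            CenterAnnotation(centers=np.cumsum(np.ones((5, 3)) * 10, axis=0),
                             vb_names=list("abcde"))
            for _ in range(2)
        ]
        assert learn_chain_prior(anns).n_pairs == 4

    def test_insufficient_annotations_raise(self):
        ann = CenterAnnotation(centers=[[0, 0, 0], [0, 1, 0]], vb_names=["a", "b"])
        with pytest.raises(InsufficientDataError):
            learn_chain_prior([ann])


class TestDecodeChain:
    def _random_instance(self, rng, m, shape=(6, 6, 6)):
        responses = [
            ResponseVolume(rng.random(shape), np.ones(3), np.zeros(3))
            for _ in range(m)
        ]
        means = rng.normal([0, 3, 0], 1.0, size=(m - 1, 3)) if m > 1 else np.zeros((0, 3))
        covs = np.stack([np.diag(rng.uniform(1, 4, 3)) for _ in range(m - 1)]) \
            if m > 1 else np.zeros((0, 3, 3))
        return responses, ChainPrior(means, covs)

    def test_single_vb_returns_global_argmax(self, rng):
        resp = ResponseVolume(rng.random((7, 7, 7)), np.ones(3), np.zeros(3))
        prior = ChainPrior(np.zeros((0, 3)), np.zeros((0, 3, 3)))
        ann = decode_center_chain([resp], prior, k_candidates=200)
        peak = np.unravel_index(np.argmax(resp.data), resp.data.shape)
        np.testing.assert_allclose(ann.centers[0], np.asarray(peak, dtype=float))

    def test_flat_responses_follow_prior_offsets(self):
        responses = [
            ResponseVolume(np.ones((1, 10, 1)), np.ones(3), np.zeros(3))
            for _ in range(3)
        ]
        prior = ChainPrior(
            means=[[0, 3, 0], [0, 3, 0]],
            covs=np.stack([0.01 * np.eye(3)] * 2),
        )
        ann = decode_center_chain(responses, prior, k_candidates=10)
        np.testing.assert_allclose(
            ann.centers, [[0, 0, 0], [0, 3, 0], [0, 6, 0]]
        )

    @pytest.mark.parametrize("m,k", [(3, 5), (2, 6), (4, 4)])
    def test_dp_equals_exhaustive_enumeration(self, rng, m, k):
        for _ in range(5):
            responses, prior = self._random_instance(rng, m)
            got = decode_center_chain(responses, prior, k_candidates=k)
            expected = brute_force_chain(responses, prior, k)
            np.testing.assert_allclose(got.centers, expected)

    def test_invariant_to_rescaling_one_response(self, rng):
        responses, prior = self._random_instance(rng, 3)
        base = decode_center_chain(responses, prior, k_candidates=5)
        responses[1] = ResponseVolume(
            responses[1].data * 37.5, responses[1].spacing, responses[1].origin
        )
        scaled = decode_center_chain(responses, prior, k_candidates=5)
        np.testing.assert_allclose(base.centers, scaled.centers)

    def test_empty_candidate_request_raises(self, rng):
        responses, prior = self._random_instance(rng, 2)
        with pytest.raises(DecodingError):
            decode_center_chain(responses, prior, k_candidates=0)
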