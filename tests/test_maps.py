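import numpy as np
import pytest

import mapfactors as mf
from mapfactors.exceptions import (
    DegenerateSplitError,
    EmptySubsetError,
    InsufficientDataError,
)
from mapfactors.maps import pooled_t

from conftest import make_dataset


class TestTaskMap:
    def test_arithmetic_mean(self):
        ds = make_dataset(
            betas=[[[1.0, 2.0], [3.0, 4.0]]], rt=[[0.5, 0.7]], confidence=[[1, 2]]
        )
        np.testing.assert_allclose(mf.task_map(ds, 0).values, [2.0, 3.0])

    def test_noise_only_map_near_zero(self, noise_dataset):
        values = mf.task_map(noise_dataset, 0).values
        # CLT: SD of a 64-trial mean is 1/8
        assert np.abs(values).mean() < 3 / np.sqrt(noise_dataset.n_trials)

    def test_zero_noise_halves_identical(self, small_zbehavior, small_factor_maps):
        w = mf.FactorWeights(w_task_group=0.3, w_task_subj=0.2, w_noise=0.0)
        ds = mf.simulate_dataset(w, small_factor_maps, small_zbehavior, seed=0)
        np.testing.assert_allclose(
            mf.task_map(ds, 1, "odd").values, mf.task_map(ds, 1, "even").values, atol=1e-12
        )

    def test_all_equals_weighted_average_of_halves(self, small_dataset):
        odd, even = mf.split_odd_even(small_dataset.n_trials)
        for s in range(small_dataset.n_subjects):
            combined = (
                len(odd) * mf.task_map(small_dataset, s, "odd").values
                + len(even) * mf.task_map(small_dataset, s, "even").values
            ) / small_dataset.n_trials
            np.testing.assert_allclose(
                combined, mf.task_map(small_dataset, s, "all").values, atol=1e-12
            )

    def test_empty_subset_rejected(self, small_dataset):
        with pytest.raises(EmptySubsetError):
            mf.task_map(small_dataset, 0, np.array([], dtype=int))


class TestContrastMap:
    def test_hand_computed_t(self):
        # high-group betas (1,3), low-group (0,2): means 2 vs 1, pooled SD sqrt(2)
        ds = make_dataset(
            betas=[[[1.0], [3.0], [0.0], [2.0]]],
            rt=[[2.0, 2.0, 1.0, 1.0]],
            confidence=[[1, 2, 1, 2]],
        )
        t = mf.contrast_map(ds, 0, "rt").values
        np.testing.assert_allclose(t, [1 / np.sqrt(2)], atol=1e-12)

    def test_null_contrast_small(self, noise_dataset):
        t = mf.contrast_map(noise_dataset, 0, "rt").values
        assert abs(t.mean()) < 0.3  # ~N(0, 1/sqrt(V)) under the null

    def test_label_swap_negates(self):
        rng = np.random.default_rng(0)
        high = rng.standard_normal((5, 7))
        low = rng.standard_normal((6, 7))
        np.testing.assert_allclose(pooled_t(high, low), -pooled_t(low, high), atol=1e-12)

    def test_constant_shift_invariance(self, small_dataset):
        shifted = mf.TrialDataset(
            betas=small_dataset.betas + 7.5,
            behavior=small_dataset.behavior,
            design=small_dataset.design,
        )
        np.testing.assert_allclose(
            mf.contrast_map(shifted, 2, "confidence").values,
            mf.contrast_map(small_dataset, 2, "confidence").values,
            atol=1e-9,
        )

    def test_degenerate_split_raises(self):
        ds = make_dataset(
            betas=np.zeros((1, 4, 2)), rt=[[1.0, 1.0, 1.0, 1.0]], confidence=[[2, 2, 2, 2]]
        )
        with pytest.raises(DegenerateSplitError):
            mf.contrast_map(ds, 0, "confidence")


class TestSplitOddEven:
    @pytest.mark.parametrize("n,expected", [(768, (384, 384)), (5, (3, 2))])
    def test_sizes(self, n, expected):
        odd, even = mf.split_odd_even(n)
        assert (len(odd), len(even)) == expected

    def test_partition(self):
        odd, even = mf.split_odd_even(11)
        assert np.intersect1d(odd, even).size == 0
        np.testing.assert_array_equal(np.union1d(odd, even), np.arange(11))

    def test_chronological_convention(self):
        odd, _ = mf.split_odd_even(4)
        np.testing.assert_array_equal(odd, [0, 2])  # 1st and 3rd trials


class TestBlockAggregate:
    def test_block_count(self, small_dataset):
        agg = mf.block_aggregate(small_dataset)
        assert agg.n_trials == 8  # 2 runs x 4 blocks
        assert agg.n_subjects == small_dataset.n_subjects

    def test_constant_block_preserved(self):
        betas = np.ones((1, 8, 3)) * 2.5
        ds = make_dataset(
            betas=betas,
            rt=[np.linspace(0.5, 1.2, 8)],
            confidence=[[1, 2, 3, 4, 1, 2, 3, 4]],
            trials_per_block=4,
        )
        agg = mf.block_aggregate(ds)
        np.testing.assert_allclose(agg.betas, 2.5)

    def test_noise_variance_shrinks_by_block_size(self, noise_dataset):
        agg = mf.block_aggregate(noise_dataset)  # blocks of 8 trials
        ratio = agg.betas.var(axis=1).mean() / noise_dataset.betas.var(axis=1).mean()
        assert ratio == pytest.approx(1 / 8, rel=0.35)

    def test_task_map_identity_with_equal_blocks(self, small_dataset):
        agg = mf.block_aggregate(small_dataset)
        for s in (0, 3):
            np.testing.assert_allclose(
                mf.task_map(agg, s).values, mf.task_map(small_dataset, s).values, atol=1e-12
            )


class TestGroupTmap:
    def test_identical_maps_flagged_degenerate(self):
        maps = np.tile(np.array([1.0, -2.0, 0.0]), (4, 1))
        with pytest.warns(RuntimeWarning):
            t, q, mask = mf.group_tmap(maps)
        assert t[0] == np.inf and t[1] == -np.inf and t[2] == 0
        np.testing.assert_array_equal(mask, [True, True, False])

    def test_fdr_under_global_null(self):
        rng = np.random.default_rng(0)
        discovered = sum(
            mf.group_tmap(rng.standard_normal((50, 2000)))[2].sum() for _ in range(3)
        )
        assert discovered / 6000 < 0.001

    def test_positive_signal_sign(self):
        rng = np.random.default_rng(1)
        maps = 1.0 + 0.01 * rng.standard_normal((4, 1))
        t, _, _ = mf.group_tmap(maps)
        assert t[0] > 0

    def test_requires_two_subjects(self):
        with pytest.raises(InsufficientDataError):
            mf.group_tmap(np.ones((1, 5)))
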