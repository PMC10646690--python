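import math

import numpy as np
import pytest

import mapfactors as mf
from mapfactors.consistency import _max_overlap_one
from mapfactors.exceptions import EmptyInputError, InvalidParameterError


class TestSignConsistency:
    def test_all_positive(self):
        result = mf.sign_consistency(np.ones((50, 3)))
        np.testing.assert_allclose(result.c_raw, 100)
        np.testing.assert_allclose(result.c_folded, 100)
        assert (result.sign_label == "positive-consistent").all()

    def test_split_and_minority_positive(self):
        maps = np.vstack([np.ones((10, 1)), -np.ones((40, 1))])
        result = mf.sign_consistency(maps)
        assert result.c_raw[0] == 20
        assert result.c_folded[0] == 80
        assert result.sign_label[0] == "negative-consistent"

        even = np.vstack([np.ones((25, 1)), -np.ones((25, 1))])
        assert mf.sign_consistency(even).c_folded[0] == 50

    def test_folding_idempotent_and_bounded(self):
        rng = np.random.default_rng(0)
        result = mf.sign_consistency(rng.standard_normal((11, 200)))
        assert (result.c_folded >= 50).all()
        np.testing.assert_allclose(
            result.c_folded, np.maximum(result.c_raw, 100 - result.c_raw)
        )
        np.testing.assert_allclose(
            np.maximum(result.c_folded, 100 - result.c_folded), result.c_folded
        )

    def test_zero_values_excluded(self):
        maps = np.array([[0.0, 1.0], [0.0, -1.0], [0.0, 1.0]])
        with pytest.raises(EmptyInputError):
            mf.sign_consistency(maps[:, :1])
        result = mf.sign_consistency(maps)
        assert np.isnan(result.c_raw[0])
        assert result.c_raw[1] == pytest.approx(200 / 3)

    def test_single_subject_always_consistent(self):
        result = mf.sign_consistency(np.random.default_rng(1).standard_normal((1, 50)))
        np.testing.assert_allclose(result.c_folded, 100)


class TestTopFractionOverlap:
    def test_identical_maps(self):
        rng = np.random.default_rng(0)
        maps = np.tile(rng.standard_normal(50), (7, 1))
        freq = mf.top_fraction_overlap(maps, 0.1)
        k = math.ceil(0.1 * 50)
        assert ((freq == 0) | (freq == 100)).all()
        assert (freq == 100).sum() == k

    def test_mean_frequency_conservation(self):
        rng = np.random.default_rng(1)
        maps = rng.standard_normal((9, 123))
        for fraction in (0.1, 0.33, 1.0):
            freq = mf.top_fraction_overlap(maps, fraction)
            k = math.ceil(fraction * 123)
            assert freq.mean() == pytest.approx(100 * k / 123)
            assert (freq * 9 / 100).sum() == pytest.approx(9 * k)

    def test_modal_frequency_matches_binomial_mode(self):
        maps = np.random.default_rng(2).standard_normal((50, 10_000))
        freq = mf.top_fraction_overlap(maps, 0.1)
        values, counts = np.unique(freq, return_counts=True)
        assert values[np.argmax(counts)] == pytest.approx(10.0)  # Binomial(50,.1) mode


class TestNulls:
    def test_consistency_null_single_voxel_matches_exact_binomial(self):
        exact = mf.expected_max_folded_consistency(50, 1)
        assert exact == pytest.approx(55.61, abs=0.01)
        null = mf.random_null_consistency(50, 1, n_iterations=3000, seed=0)
        assert null.mean == pytest.approx(exact, abs=0.35)

    def test_consistency_null_single_subject(self):
        null = mf.random_null_consistency(1, 100, n_iterations=10, seed=0)
        np.testing.assert_allclose(null.maxima, 100)

    def test_consistency_null_matches_exact_small_instance(self):
        exact = mf.expected_max_folded_consistency(20, 2000)
        null = mf.random_null_consistency(20, 2000, n_iterations=400, seed=1)
        assert null.mean == pytest.approx(exact, abs=1.0)

    def test_overlap_null_single_subject_and_full_fraction(self):
        assert mf.random_null_overlap(1, 50, 0.1, n_iterations=5, seed=0).mean == 100
        assert mf.random_null_overlap(6, 40, 1.0, n_iterations=5, seed=0).mean == 100

    def test_overlap_null_matches_order_statistic_oracle(self):
        # independent-binomial order-statistic expectation at the study scale
        exact = mf.expected_max_overlap(50, 10_000, 0.1)
        null = mf.random_null_overlap(50, 10_000, 0.1, n_iterations=200, seed=2)
        assert null.mean == pytest.approx(exact, abs=2.0)

    def test_null_statistics_scale_invariant(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((10, 500))
        pos = (x >= 0).sum(axis=0)
        folded = np.maximum(pos, 10 - pos)
        pos2 = (3.7 * x >= 0).sum(axis=0)
        np.testing.assert_array_equal(folded, np.maximum(pos2, 10 - pos2))
        assert _max_overlap_one(x, 50) == _max_overlap_one(3.7 * x, 50)

    def test_invalid_counts(self):
        with pytest.raises(InvalidParameterError):
            mf.random_null_consistency(0, 10, 5, 0)
        with pytest.raises(InvalidParameterError):
            mf.expected_max_overlap(10, 100, 0.0)

    def test_null_determinism(self):
        a = mf.random_null_consistency(10, 200, 20, seed=9)
        b = mf.random_null_consistency(10, 200, 20, seed=9)
        np.testing.assert_array_equal(a.maxima, b.maxima)
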