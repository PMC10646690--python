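import numpy as np
import pytest

import mapfactors as mf
from mapfactors.exceptions import InvalidParameterError, UndefinedCorrelationError
from mapfactors.reliability import DEFAULT_FRACTIONS

from conftest import make_dataset


class TestSelectTopFraction:
    def test_largest_magnitudes(self):
        idx = mf.select_top_fraction(np.array([0.1, -5.0, 3.0, 0.2]), 0.5)
        np.testing.assert_array_equal(idx, [1, 2])

    def test_full_fraction_selects_all(self):
        idx = mf.select_top_fraction(np.array([1.0, 2.0, 3.0]), 1.0)
        np.testing.assert_array_equal(idx, [0, 1, 2])

    def test_tie_broken_by_lower_index(self):
        idx = mf.select_top_fraction(np.array([2.0, -2.0, 1.0]), 1 / 3)
        np.testing.assert_array_equal(idx, [0])

    @pytest.mark.parametrize("fraction", [0.0, -0.2, 1.5])
    def test_invalid_fraction(self, fraction):
        with pytest.raises(InvalidParameterError):
            mf.select_top_fraction(np.ones(4), fraction)

    def test_count_is_ceiling(self):
        values = np.arange(10, dtype=float)
        assert len(mf.select_top_fraction(values, 0.25)) == 3  # ceil(2.5)


class TestSplitHalfReliability:
    def test_identical_halves_give_one(self):
        rng = np.random.default_rng(0)
        m = rng.standard_normal(100)
        assert mf.split_half_reliability(m, m, 0.5) == pytest.approx(1.0)

    def test_independent_halves_near_zero(self):
        rng = np.random.default_rng(1)
        r = mf.split_half_reliability(
            rng.standard_normal(10_000), rng.standard_normal(10_000), 1.0
        )
        assert abs(r) < 0.05

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(200), rng.standard_normal(200)
        assert mf.split_half_reliability(a, b, 0.3) == pytest.approx(
            mf.split_half_reliability(5 * a, 5 * b, 0.3), abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            mf.split_half_reliability(np.ones(10), np.arange(10.0), 1.0)


class TestSubjectToGroupSimilarity:
    def test_shared_map_gives_one(self):
        maps = np.tile(np.random.default_rng(0).standard_normal(50), (6, 1))
        for s in range(6):
            assert mf.subject_to_group_similarity(maps, s, 1.0) == pytest.approx(1.0)

    def test_independent_maps_near_zero(self):
        maps = np.random.default_rng(1).standard_normal((50, 10_000))
        values = [mf.subject_to_group_similarity(maps, s, 1.0) for s in range(50)]
        assert abs(np.mean(values)) < 0.02

    def test_leave_one_out_excludes_self(self):
        # subject 0 has a unique map; others share one -> similarity for a
        # shared-map subject must not be inflated by its own values
        rng = np.random.default_rng(2)
        shared = rng.standard_normal(500)
        maps = np.vstack([rng.standard_normal(500), *([shared] * 4)])
        r0 = mf.subject_to_group_similarity(maps, 0, 1.0)
        assert abs(r0) < 0.2  # uncorrelated with the others' mean


class TestSummarize:
    def test_grid_shape(self, small_dataset):
        summary = mf.summarize(small_dataset, fractions=(0.1, 0.5, 1.0))
        assert len(summary.table) == 3 * 3 * 2  # contrasts x fractions x measures
        assert set(summary.table.measure) == {"reliability", "similarity"}
        assert list(summary.table.fraction.unique()) == [0.1, 0.5, 1.0]

    def test_duplicated_subject_zero_noise_similarity_one(self):
        rng = np.random.default_rng(3)
        T, V = 16, 40
        betas_one = rng.standard_normal((1, T, V))
        betas = np.repeat(betas_one, 6, axis=0)
        rt = np.tile(rng.lognormal(0, 0.3, T), (6, 1))
        conf = np.tile(rng.integers(1, 5, T), (6, 1))
        ds = make_dataset(betas, rt, conf)
        summary = mf.summarize(ds, fractions=(1.0,))
        for contrast in ("task", "rt", "confidence"):
            assert summary.value(contrast, 1.0, "similarity") == pytest.approx(1.0)
            assert summary.table[
                (summary.table.contrast == contrast)
                & (summary.table.measure == "similarity")
            ]["sem"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_targets_vector_order(self, small_dataset):
        summary = mf.summarize(small_dataset, fractions=(1.0,))
        t = summary.targets(1.0)
        assert t.shape == (6,)
        assert t[0] == summary.value("task", 1.0, "reliability")
        assert t[5] == summary.value("confidence", 1.0, "similarity")

    def test_from_targets_round_trip(self):
        values = np.array([0.81, 0.74, 0.55, 0.72, 0.69, 0.52])
        summary = mf.SummaryStatistics.from_targets(values)
        np.testing.assert_allclose(summary.targets(1.0), values)


class TestModelLevelProperties:
    """Map-level oracles built directly from the model's implications.

    A map over V voxels from T trials is (signal) + (noise mean): the task
    map equals w_g*f_g + w_s*f_s + eps with Var(eps) = w_n^2 * (1/#trials).
    Constructing maps at that level gives an independent check of the
    reliability/similarity statistics without running the full simulator.
    """

    def _maps(self, w_g, w_s, w_n, S=50, V=10_000, T=768, seed=0):
        rng = np.random.default_rng(seed)
        f_g = rng.standard_normal(V)
        f_s = rng.standard_normal((S, V))
        signal = w_g * f_g + w_s * f_s
        halves = {
            "odd": signal + w_n * np.sqrt(2 / T) * rng.standard_normal((S, V)),
            "even": signal + w_n * np.sqrt(2 / T) * rng.standard_normal((S, V)),
        }
        halves["all"] = 0.5 * (halves["odd"] + halves["even"])
        return halves

    def test_reliability_monotone_in_noise(self):
        rel = []
        for w_n in (0.5, 1.0, 2.0):
            halves = self._maps(0.15, 0.15, w_n, S=20, V=3000)
            rel.append(
                np.mean(
                    [
                        mf.split_half_reliability(halves["odd"][s], halves["even"][s], 1.0)
                        for s in range(20)
                    ]
                )
            )
        assert rel[0] > rel[1] + 0.02 > rel[2] + 0.02

    def test_top_fraction_increases_reliability(self):
        halves = self._maps(0.15, 0.15, 1.0, S=20, V=3000)
        r10 = np.mean(
            [mf.split_half_reliability(halves["odd"][s], halves["even"][s], 0.1) for s in range(20)]
        )
        r100 = np.mean(
            [mf.split_half_reliability(halves["odd"][s], halves["even"][s], 1.0) for s in range(20)]
        )
        assert r10 >= r100 - 0.02

    def test_similarity_squared_attenuation_bound(self):
        # group + noise only: similarity^2 <= reliability + slack
        halves = self._maps(0.2, 0.0, 1.0, S=50, V=10_000)
        rel = np.mean(
            [mf.split_half_reliability(halves["odd"][s], halves["even"][s], 1.0) for s in range(50)]
        )
        sim = np.mean(
            [mf.subject_to_group_similarity(halves["all"], s, 1.0) for s in range(50)]
        )
        assert sim**2 <= rel + 0.03


def test_default_fractions_are_protocol():
    assert DEFAULT_FRACTIONS == (0.10, 0.25, 0.50, 0.75, 1.00)
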