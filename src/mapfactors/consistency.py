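"""Sign-consistency and top-fraction-overlap analyses with maximal-statistic nulls.

Sign consistency of voxel i across subjects is C_i = 100 * (#subjects with
activation >= 0) / n_subjects, folded about 50 (C_folded = max(C, 100 - C)) so
that 100 means perfect agreement in either sign.  The top-fraction overlap is
the percent of subjects for which a voxel lands in their top-X% most strongly
activated voxels (by absolute value).

Because a whole-brain map contains many voxels, even unrelated maps produce
some high values by chance.  The null reference is therefore the *maximum* of
the statistic over voxels, computed on independent random maps and averaged
over iterations; exact binomial order-statistic expectations are provided as
analytic cross-checks (both statistics are distribution-free under
independence, so the choice of a standard-normal null is immaterial).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EmptyInputError, InvalidParameterError
from .reliability import select_top_fraction


@dataclass
class ConsistencyMap:
    """Per-voxel sign consistency: raw percent positive, folded, dominant sign."""

    c_raw: np.ndarray  # percent of subjects with activation >= 0, in [0, 100]
    c_folded: np.ndarray  # max(c_raw, 100 - c_raw), in [50, 100]
    sign_label: np.ndarray  # 'positive-consistent' | 'negative-consistent'


@dataclass
class NullResult:
    """Maximal-statistic null: per-iteration maxima and their mean."""

    maxima: np.ndarray
    mean: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"iteration": np.arange(len(self.maxima)), "max_statistic": self.maxima}
        )


def _check_counts(**kwargs) -> None:
    for name, value in kwargs.items():
        if int(value) != value or value < 1:
            raise InvalidParameterError(f"{name} must be a positive integer, got {value!r}")


def sign_consistency(maps) -> ConsistencyMap:
    """Percent of subjects with non-negative activation per voxel, folded.

    Exactly-zero values are treated as missing (the convention for voxels
    outside the brain) and excluded from that voxel's denominator; voxels
    with no valid value in any subject are NaN in the output.  Raises
    :class:`EmptyInputError` when no voxel has any valid value.
    """
    if not isinstance(maps, np.ndarray):
        maps = np.stack([m.values for m in maps])
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 1:
        maps = maps[None, :]
    valid = maps != 0
    n_valid = valid.sum(axis=0)
    if not np.any(n_valid):
        raise EmptyInputError("no voxel has a nonzero value in any subject")
    positive = ((maps >= 0) & valid).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_raw = 100.0 * positive / n_valid
    c_raw[n_valid == 0] = np.nan
    c_folded = np.fmax(c_raw, 100.0 - c_raw)
    sign = np.where(c_raw >= 50, "positive-consistent", "negative-consistent")
    return ConsistencyMap(c_raw=c_raw, c_folded=c_folded, sign_label=sign)


def top_fraction_overlap(maps, fraction: float = 0.1) -> np.ndarray:
    """Percent of subjects selecting each voxel in their top-fraction set.

    Each subject selects their ceil(fraction * V) voxels with largest
    absolute activation; the mean of the returned frequencies over voxels is
    exactly 100 * ceil(fraction * V) / V.
    """
    if not isinstance(maps, np.ndarray):
        maps = np.stack([m.values for m in maps])
    n_subjects, n_voxels = maps.shape
    counts = np.zeros(n_voxels, dtype=np.int64)
    for s in range(n_subjects):
        counts[select_top_fraction(maps[s], fraction)] += 1
    return 100.0 * counts / n_subjects


def _max_overlap_one(x: np.ndarray, k: int) -> float:
    """Max selection frequency for one random cohort (ties ignored: continuous draws)."""
    n_subjects, n_voxels = x.shape
    idx = np.argpartition(-np.abs(x), k - 1, axis=1)[:, :k]
    counts = np.bincount(idx.ravel(), minlength=n_voxels)
    return 100.0 * counts.max() / n_subjects


def random_null_consistency(
    n_subjects: int, n_voxels: int, n_iterations: int = 1000, seed: int = 0
) -> NullResult:
    """Null of the maximal folded sign consistency under independent maps.

    Each iteration draws i.i.d. standard-normal maps for all subjects,
    computes the folded consistency of every voxel, and records the maximum
    over voxels; the mean over iterations is the reported null level.
    """
    _check_counts(n_subjects=n_subjects, n_voxels=n_voxels, n_iterations=n_iterations)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_iterations)
    for i in range(n_iterations):
        x = rng.standard_normal((n_subjects, n_voxels), dtype=np.float32)
        positive = (x >= 0).sum(axis=0)
        folded = 100.0 * np.maximum(positive, n_subjects - positive) / n_subjects
        maxima[i] = folded.max()
    return NullResult(maxima=maxima, mean=float(maxima.mean()))


def random_null_overlap(
    n_subjects: int,
    n_voxels: int,
    fraction: float = 0.1,
    n_iterations: int = 1000,
    seed: int = 0,
) -> NullResult:
    """Null of the maximal top-fraction selection frequency under independent maps."""
    _check_counts(n_subjects=n_subjects, n_voxels=n_voxels, n_iterations=n_iterations)
    if not 0 < fraction <= 1:
        raise InvalidParameterError(f"fraction must lie in (0, 1], got {fraction!r}")
    k = math.ceil(fraction * n_voxels)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_iterations)
    for i in range(n_iterations):
        x = rng.standard_normal((n_subjects, n_voxels), dtype=np.float32)
        maxima[i] = _max_overlap_one(x, k)
    return NullResult(maxima=maxima, mean=float(maxima.mean()))


def _expected_max_from_cdf(values: np.ndarray, cdf: np.ndarray, n_voxels: int) -> float:
    cdf_max = cdf**n_voxels
    pmf_max = np.diff(np.concatenate([[0.0], cdf_max]))
    return float((values * pmf_max).sum())


def expected_max_folded_consistency(n_subjects: int, n_voxels: int) -> float:
    """Exact E[max over voxels of folded consistency] for independent maps.

    Per voxel the positive count is Binomial(n_subjects, 1/2); voxels are
    independent, so the maximum's distribution follows from the per-voxel CDF
    raised to the number of voxels.
    """
    _check_counts(n_subjects=n_subjects, n_voxels=n_voxels)
    k = np.arange(n_subjects + 1)
    pmf = stats.binom.pmf(k, n_subjects, 0.5)
    folded = 100.0 * np.maximum(k, n_subjects - k) / n_subjects
    values = np.unique(folded)
    p = np.array([pmf[folded == v].sum() for v in values])
    return _expected_max_from_cdf(values, np.cumsum(p), n_voxels)


def expected_max_overlap(n_subjects: int, n_voxels: int, fraction: float = 0.1) -> float:
    """Binomial order-statistic expectation of the maximal selection frequency.

    Treats each voxel's selection count as Binomial(n_subjects, k/V) with
    k = ceil(fraction * V), independent across voxels.  The fixed per-subject
    total introduces a weak negative dependence, so this is an (excellent,
    slightly conservative) approximation for large V rather than an identity.
    """
    _check_counts(n_subjects=n_subjects, n_voxels=n_voxels)
    if not 0 < fraction <= 1:
        raise InvalidParameterError(f"fraction must lie in (0, 1], got {fraction!r}")
    k_sel = math.ceil(fraction * n_voxels)
    counts = np.arange(n_subjects + 1)
    cdf = stats.binom.cdf(counts, n_subjects, k_sel / n_voxels)
    return _expected_max_from_cdf(100.0 * counts / n_subjects, cdf, n_voxels)
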