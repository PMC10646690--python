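"""Per-subject activation maps and the standard group-level t-map.

Three contrasts are supported:

* ``task``       — mean beta across the selected trials (activation vs. baseline);
* ``rt``         — two-sample pooled-variance t comparing betas on trials with
  above- vs. below-or-at-median RT;
* ``confidence`` — same median-split t for the confidence rating.

Maps can be computed on all trials or on the odd/even halves (chronological
1-based positions) used by the split-half reliability analysis, and trials can
be aggregated to block-level pseudo-trials first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import median_split_labels, zscore_behavior
from .exceptions import (
    EmptySubsetError,
    InsufficientDataError,
    InvalidParameterError,
    MissingMetadataError,
)
from .generative import StudyDesign, TrialDataset

CONTRASTS = ("task", "rt", "confidence")
SUBSETS = ("all", "odd", "even")


@dataclass
class ActivationMap:
    """One subject's voxelwise statistic for one contrast and trial subset."""

    subject_id: int
    contrast: str  # 'task' | 'rt' | 'confidence'
    statistic: str  # 'mean_beta' | 't_value'
    trial_subset: str  # 'all' | 'odd' | 'even'
    values: np.ndarray

    def __post_init__(self):
        if self.contrast not in CONTRASTS:
            raise InvalidParameterError(f"unknown contrast {self.contrast!r}")
        expected = "mean_beta" if self.contrast == "task" else "t_value"
        if self.statistic != expected:
            raise InvalidParameterError(
                f"contrast {self.contrast!r} requires statistic {expected!r}"
            )


def split_odd_even(n_trials: int) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive odd/even trial indices (odd = 1st, 3rd, ... trials)."""
    if n_trials < 2:
        raise InsufficientDataError("odd/even split requires >= 2 trials")
    trials = np.arange(n_trials)
    return trials[::2], trials[1::2]


def _subset_indices(n_trials: int, subset) -> np.ndarray:
    if isinstance(subset, str):
        if subset == "all":
            return np.arange(n_trials)
        odd, even = split_odd_even(n_trials)
        if subset == "odd":
            return odd
        if subset == "even":
            return even
        raise InvalidParameterError(f"unknown trial subset {subset!r}")
    idx = np.asarray(subset, dtype=int)
    if idx.size == 0:
        raise EmptySubsetError("trial subset selects no trials")
    return idx


def task_map(dataset: TrialDataset, subject: int, subset="all") -> ActivationMap:
    """Mean beta over the selected trials, per voxel."""
    idx = _subset_indices(dataset.n_trials, subset)
    values = dataset.betas[subject, idx].mean(axis=0)
    name = subset if isinstance(subset, str) else "custom"
    return ActivationMap(subject, "task", "mean_beta", name, values)


def pooled_t(high: np.ndarray, low: np.ndarray) -> np.ndarray:
    """Student (pooled-variance) two-sample t per voxel, high minus low.

    ``high``/``low`` are [trials x voxels].  Voxels with zero pooled variance
    yield +/-inf (or nan when the mean difference is also zero).
    """
    n_h, n_l = high.shape[0], low.shape[0]
    if n_h < 1 or n_l < 1 or n_h + n_l < 3:
        raise InsufficientDataError("pooled t requires both groups non-empty and n_h+n_l >= 3")
    diff = high.mean(axis=0) - low.mean(axis=0)
    ss_h = ((high - high.mean(axis=0)) ** 2).sum(axis=0)
    ss_l = ((low - low.mean(axis=0)) ** 2).sum(axis=0)
    sp2 = (ss_h + ss_l) / (n_h + n_l - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return diff / np.sqrt(sp2 * (1.0 / n_h + 1.0 / n_l))


def contrast_map(dataset: TrialDataset, subject: int, variable: str, subset="all") -> ActivationMap:
    """Median-split t-map for RT or confidence within the chosen trial subset.

    The median is recomputed within the subset, so odd/even half-maps are
    self-contained.  Ties at the median go to the low group.
    """
    if variable not in ("rt", "confidence"):
        raise InvalidParameterError(f"variable must be 'rt' or 'confidence', got {variable!r}")
    idx = _subset_indices(dataset.n_trials, subset)
    x = dataset.arrays()[variable][subject, idx]
    labels = median_split_labels(x)  # raises DegenerateSplitError when constant
    betas = dataset.betas[subject, idx]
    values = pooled_t(betas[labels == "high"], betas[labels == "low"])
    name = subset if isinstance(subset, str) else "custom"
    return ActivationMap(subject, variable, "t_value", name, values)


def block_aggregate(dataset: TrialDataset) -> TrialDataset:
    """Aggregate trials to one pseudo-trial per block.

    Betas and behavior are averaged within each (run, block); z-scores are
    recomputed on the block means.  The aggregated confidence is a mean, so it
    is generally non-integer — downstream median splits and z-scoring are
    unaffected.
    """
    for col in ("run", "block"):
        if col not in dataset.behavior.columns:
            raise MissingMetadataError(f"behavior table lacks the {col!r} column")
    arrays = dataset.arrays()
    run, block = arrays["run"], arrays["block"]
    key = run * (block.max() + 1) + block
    uniq, inverse = np.unique(key, return_inverse=True)
    counts = np.bincount(inverse)
    if counts.min() != counts.max():
        raise InvalidParameterError("block aggregation requires equal trials per block")
    n_blocks = uniq.size
    # mean within block along the trial axis
    agg = np.zeros((dataset.n_subjects, n_blocks, dataset.n_voxels))
    np.add.at(agg, (slice(None), inverse), dataset.betas)
    agg /= counts[None, :, None]

    # np.unique sorts keys, so block order is chronological (run-major)
    run_blk = (np.bincount(inverse, weights=run) / counts).astype(int)
    blk_blk = (np.bincount(inverse, weights=block) / counts).astype(int)
    rows = []
    for s in range(dataset.n_subjects):
        rows.append(
            pd.DataFrame(
                {
                    "subject": s,
                    "run": run_blk,
                    "block": blk_blk,
                    "trial": np.arange(n_blocks),
                    "rt": np.bincount(inverse, weights=arrays["rt"][s]) / counts,
                    "confidence": np.bincount(inverse, weights=arrays["confidence"][s]) / counts,
                }
            )
        )
    behavior = pd.concat(rows, ignore_index=True)
    design = StudyDesign(
        n_subjects=dataset.n_subjects,
        n_runs=dataset.design.n_runs,
        blocks_per_run=dataset.design.blocks_per_run,
        trials_per_block=1,
        n_voxels=dataset.n_voxels,
    )
    return TrialDataset(
        betas=agg,
        behavior=zscore_behavior(behavior),
        design=design,
        provenance={**dataset.provenance, "aggregated": "block"},
    )


def compute_all_maps(dataset: TrialDataset) -> dict[str, dict[str, np.ndarray]]:
    """All-subject map stacks for every contrast x subset.

    Returns ``maps[contrast][subset]`` as [subjects x voxels] arrays; the
    input to the reliability/similarity summaries.
    """
    out: dict[str, dict[str, np.ndarray]] = {c: {} for c in CONTRASTS}
    for subset in SUBSETS:
        idx = _subset_indices(dataset.n_trials, subset)
        out["task"][subset] = dataset.betas[:, idx].mean(axis=1)
        for variable in ("rt", "confidence"):
            out[variable][subset] = np.stack(
                [
                    contrast_map(dataset, s, variable, subset).values
                    for s in range(dataset.n_subjects)
                ]
            )
    return out


def group_tmap(maps, alpha: float = 0.05):
    """One-sample t across subjects per voxel, with Benjamini-Hochberg FDR.

    Parameters
    ----------
    maps
        [subjects x voxels] array or a list of per-subject ActivationMaps.
    alpha
        FDR level for the significance mask.

    Returns
    -------
    (t, q, mask): t values (inf sentinel where across-subject variance is
    zero with nonzero mean), BH q-values, and the boolean mask ``q < alpha``.
    """
    if not isinstance(maps, np.ndarray):
        maps = np.stack([m.values for m in maps])
    n = maps.shape[0]
    if n < 2:
        raise InsufficientDataError("group t-map requires >= 2 subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    zero_var = sd == 0
    if np.any(zero_var):
        warnings.warn(
            "zero across-subject variance at some voxels; reporting +/-inf t there",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[zero_var & (mean != 0)] = np.sign(mean[zero_var & (mean != 0)]) * np.inf
    t[zero_var & (mean == 0)] = 0.0
    p = 2 * stats.t.sf(np.abs(np.where(np.isinf(t), np.finfo(float).max, t)), df=n - 1)
    p[np.isinf(t)] = 0.0
    q = stats.false_discovery_control(p)
    return t, q, q < alpha
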