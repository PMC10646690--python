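"""Split-half reliability and subject-to-group similarity of activation maps.

Within-subject reliability is the average of the odd-to-even and even-to-odd
Pearson correlations between maps built from disjoint trial halves, each
direction selecting the top-X% most strongly activated voxels (largest
absolute statistic) of the *selecting* half.  Subject-to-group similarity
correlates a subject's all-trials map, on that subject's own top-X% voxels,
with the unweighted mean map of the remaining subjects.  Summaries report the
across-subject mean +/- SEM for each contrast x voxel fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    DimensionError,
    InsufficientDataError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from .generative import TrialDataset
from .maps import ActivationMap, CONTRASTS, compute_all_maps

#: Voxel fractions of the reporting protocol (top 10/25/50/75/100%).
DEFAULT_FRACTIONS = (0.10, 0.25, 0.50, 0.75, 1.00)
MEASURES = ("reliability", "similarity")


def _values(map_or_array) -> np.ndarray:
    if isinstance(map_or_array, ActivationMap):
        return np.asarray(map_or_array.values, dtype=float)
    return np.asarray(map_or_array, dtype=float)


def select_top_fraction(map_or_array, fraction: float) -> np.ndarray:
    """Indices of the ceil(fraction * V) voxels with largest absolute value.

    Both strong activations and strong deactivations are selected.  Ties are
    broken toward the lower voxel index; the result is sorted ascending.
    """
    values = _values(map_or_array)
    if values.size == 0:
        raise InvalidParameterError("cannot select voxels from an empty map")
    if not 0 < fraction <= 1:
        raise InvalidParameterError(f"fraction must lie in (0, 1], got {fraction!r}")
    k = math.ceil(fraction * values.size)
    order = np.argsort(-np.abs(values), kind="stable")
    return np.sort(order[:k])


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; raises UndefinedCorrelationError on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DimensionError(f"shape mismatch {x.shape} vs {y.shape}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise UndefinedCorrelationError("zero variance on the selected voxels")
    return float((xc * yc).sum() / denom)


def split_half_reliability(map_odd, map_even, fraction: float = 1.0) -> float:
    """Mean of the odd-to-even and even-to-odd top-fraction correlations."""
    odd, even = _values(map_odd), _values(map_even)
    if odd.shape != even.shape:
        raise DimensionError("odd and even maps must have equal voxel counts")
    sel_odd = select_top_fraction(odd, fraction)
    sel_even = select_top_fraction(even, fraction)
    return 0.5 * (pearson(odd[sel_odd], even[sel_odd]) + pearson(even[sel_even], odd[sel_even]))


def subject_to_group_similarity(maps, subject: int, fraction: float = 1.0) -> float:
    """Correlate one subject's map with the mean map of the remaining subjects.

    Voxels are the subject's own top-fraction selection from their all-trials
    map; ``maps`` is a [subjects x voxels] stack or list of ActivationMaps.
    """
    if not isinstance(maps, np.ndarray):
        maps = np.stack([_values(m) for m in maps])
    if maps.shape[0] < 2:
        raise InsufficientDataError("similarity requires >= 2 subjects")
    own = maps[subject]
    sel = select_top_fraction(own, fraction)
    others = (maps.sum(axis=0) - own) / (maps.shape[0] - 1)
    return pearson(own[sel], others[sel])


@dataclass
class SummaryStatistics:
    """Reliability/similarity summaries per contrast x fraction.

    ``table`` is tidy: columns contrast, fraction, measure, mean, sem, n.
    ``per_subject[(contrast, fraction, measure)]`` retains the individual
    values the means were taken over.
    """

    table: pd.DataFrame
    per_subject: dict[tuple[str, float, str], np.ndarray]

    def value(self, contrast: str, fraction: float, measure: str) -> float:
        rows = self.table[
            (self.table.contrast == contrast)
            & (np.isclose(self.table.fraction, fraction))
            & (self.table.measure == measure)
        ]
        if rows.empty:
            raise KeyError((contrast, fraction, measure))
        return float(rows["mean"].iloc[0])

    def targets(self, fraction: float = 1.0) -> np.ndarray:
        """The six fit targets at one fraction: reliability then similarity,
        each ordered task, rt, confidence."""
        return np.array(
            [self.value(c, fraction, m) for m in MEASURES for c in CONTRASTS]
        )

    @classmethod
    def from_targets(cls, targets, fraction: float = 1.0) -> "SummaryStatistics":
        """Wrap a bare six-value target vector (e.g. published values) as a summary."""
        targets = np.asarray(targets, dtype=float)
        if targets.shape != (6,):
            raise InvalidParameterError("expected 6 values: reliability then similarity x (task, rt, confidence)")
        rows = [
            {"contrast": c, "fraction": fraction, "measure": m, "mean": targets[i * 3 + j], "sem": np.nan, "n": 0}
            for i, m in enumerate(MEASURES)
            for j, c in enumerate(CONTRASTS)
        ]
        return cls(table=pd.DataFrame(rows), per_subject={})

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SummaryStatistics":
        return cls(table=pd.read_csv(path, sep="\t"), per_subject={})


def summarize_maps(maps: dict[str, dict[str, np.ndarray]], fractions=DEFAULT_FRACTIONS) -> SummaryStatistics:
    """Summarise reliability and similarity from precomputed map stacks.

    ``maps[contrast][subset]`` are [subjects x voxels] arrays with subsets
    'all', 'odd', 'even' (as returned by
    :func:`mapfactors.maps.compute_all_maps`).
    """
    fractions = sorted(float(f) for f in fractions)
    rows = []
    per_subject = {}
    for contrast in CONTRASTS:
        stack_all = maps[contrast]["all"]
        stack_odd = maps[contrast]["odd"]
        stack_even = maps[contrast]["even"]
        n_subjects = stack_all.shape[0]
        for fraction in fractions:
            rel = np.array(
                [
                    split_half_reliability(stack_odd[s], stack_even[s], fraction)
                    for s in range(n_subjects)
                ]
            )
            sim = np.array(
                [
                    subject_to_group_similarity(stack_all, s, fraction)
                    for s in range(n_subjects)
                ]
            )
            for measure, values in (("reliability", rel), ("similarity", sim)):
                per_subject[(contrast, fraction, measure)] = values
                rows.append(
                    {
                        "contrast": contrast,
                        "fraction": fraction,
                        "measure": measure,
                        "mean": values.mean(),
                        "sem": values.std(ddof=1) / np.sqrt(n_subjects) if n_subjects > 1 else 0.0,
                        "n": n_subjects,
                    }
                )
    return SummaryStatistics(table=pd.DataFrame(rows), per_subject=per_subject)


def summarize(dataset: TrialDataset, fractions=DEFAULT_FRACTIONS) -> SummaryStatistics:
    """Full summary of a trial dataset at the given voxel fractions."""
    if dataset.n_subjects < 2:
        raise InsufficientDataError("summaries require >= 2 subjects")
    return summarize_maps(compute_all_maps(dataset), fractions)
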