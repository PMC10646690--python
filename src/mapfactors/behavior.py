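"""Trial-wise behavioral variables: generation, z-scoring, median splits.

The generative model consumes two behavioral regressors per trial — reaction
time (RT, seconds) and a 1-4 confidence rating — z-scored within subject.
This module generates synthetic behavior with the study's block design
(runs x blocks x trials), normalizes it, and provides the median-split
labelling used by the RT/confidence contrasts.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateSplitError,
    FormatError,
    InsufficientDataError,
    InvalidParameterError,
)

#: Canonical column order of a behavior (events) table.
BEHAVIOR_COLUMNS = ["subject", "run", "block", "trial", "rt", "confidence"]

#: Default log-normal RT parameters: median 1.0 s, moderate skew.
DEFAULT_RT_PARAMS = (0.0, 0.4)

#: Default latent thresholds mapping a standard-normal draw to ratings 1-4
#: (symmetric; rating probabilities ~ 0.16/0.34/0.34/0.16).
DEFAULT_CONF_THRESHOLDS = (-1.0, 0.0, 1.0)


def generate_behavior(
    n_subjects: int,
    n_runs: int = 6,
    blocks_per_run: int = 16,
    trials_per_block: int = 8,
    rt_params: tuple[float, float] = DEFAULT_RT_PARAMS,
    conf_thresholds: Sequence[float] = DEFAULT_CONF_THRESHOLDS,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a cohort's trial-wise behavior table.

    RT is drawn log-normal(mu, sigma); confidence is ``1 + #thresholds`` lying
    below a standard-normal latent draw, so strictly increasing thresholds of
    length 3 yield ratings in {1, 2, 3, 4}.

    Parameters
    ----------
    n_subjects, n_runs, blocks_per_run, trials_per_block
        Design layout; all must be >= 1.  The study default is 50 subjects,
        6 runs x 16 blocks x 8 trials = 768 trials per subject.
    rt_params
        (mu, sigma) of log RT; sigma > 0.
    conf_thresholds
        Strictly increasing latent thresholds.
    seed
        Integer seed; output is bit-identical across calls with the same seed.

    Returns
    -------
    pandas.DataFrame with columns ``subject, run, block, trial, rt,
    confidence``; ``trial`` is 0-based and consecutive within subject,
    ``run`` is 1-based, ``block`` is 1-based within run.
    """
    for name, value in (
        ("n_subjects", n_subjects),
        ("n_runs", n_runs),
        ("blocks_per_run", blocks_per_run),
        ("trials_per_block", trials_per_block),
    ):
        if int(value) != value or value < 1:
            raise InvalidParameterError(f"{name} must be a positive integer, got {value!r}")
    mu, sigma = rt_params
    if not sigma > 0:
        raise InvalidParameterError(f"rt sigma must be > 0, got {sigma!r}")
    thresholds = np.asarray(conf_thresholds, dtype=float)
    if thresholds.ndim != 1 or thresholds.size == 0 or np.any(np.diff(thresholds) <= 0):
        raise InvalidParameterError(
            f"conf_thresholds must be strictly increasing, got {conf_thresholds!r}"
        )

    n_trials = n_runs * blocks_per_run * trials_per_block
    rng = np.random.default_rng(seed)
    rt = rng.lognormal(mean=mu, sigma=sigma, size=(n_subjects, n_trials))
    latent = rng.standard_normal((n_subjects, n_trials))
    confidence = 1 + (latent[..., None] > thresholds).sum(axis=-1)

    trial = np.arange(n_trials)
    run = 1 + trial // (blocks_per_run * trials_per_block)
    block = 1 + (trial % (blocks_per_run * trials_per_block)) // trials_per_block
    return pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subjects), n_trials),
            "run": np.tile(run, n_subjects),
            "block": np.tile(block, n_subjects),
            "trial": np.tile(trial, n_subjects),
            "rt": rt.ravel(),
            "confidence": confidence.ravel().astype(np.int64),
        }
    )


def validate_behavior(table: pd.DataFrame) -> pd.DataFrame:
    """Check the behavior-table contract; return the table sorted by (subject, trial)."""
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"behavior table missing column(s): {', '.join(missing)}")
    if np.any(table["rt"].to_numpy() <= 0):
        raise FormatError("behavior table contains non-positive rt values")
    table = table.sort_values(["subject", "trial"], kind="stable").reset_index(drop=True)
    if table.duplicated(["subject", "trial"]).any():
        raise FormatError("duplicate (subject, trial) pairs in behavior table")
    counts = table.groupby("subject", sort=True).size()
    if counts.nunique() != 1:
        raise FormatError("trials per subject are not constant across the dataset")
    return table


def zscore_behavior(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score rt and confidence within subject (sample SD, n-1 denominator).

    Returns a copy of the table with ``z_rt`` and ``z_conf`` columns appended.
    A behaviorally constant column for a subject maps to all zeros.  Raises
    :class:`InsufficientDataError` if any subject has fewer than 2 trials.
    """
    table = validate_behavior(table)
    if table.groupby("subject").size().min() < 2:
        raise InsufficientDataError("z-scoring requires at least 2 trials per subject")
    out = table.copy()
    for col, zcol in (("rt", "z_rt"), ("confidence", "z_conf")):
        grouped = out.groupby("subject")[col]
        mean = grouped.transform("mean")
        sd = grouped.transform("std")  # pandas std uses ddof=1
        z = (out[col] - mean) / sd
        out[zcol] = z.where(sd > 0, 0.0)
    return out


def median_split_labels(values) -> np.ndarray:
    """Label each value 'high' (> median) or 'low' (<= median, ties to low).

    Raises :class:`DegenerateSplitError` when all values are identical, since
    no two-group contrast is then possible; raises
    :class:`InsufficientDataError` for fewer than 2 values.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise InsufficientDataError("median split requires a 1-D vector of length >= 2")
    if np.all(values == values[0]):
        raise DegenerateSplitError("all values identical; median split is degenerate")
    high = values > np.median(values)
    if not high.any():
        # possible with heavy ties (e.g. the median equals the maximum)
        raise DegenerateSplitError("no value exceeds the median; split is degenerate")
    return np.where(high, "high", "low")


def behavior_arrays(ztable: pd.DataFrame) -> dict[str, np.ndarray]:
    """Pivot a z-scored behavior table into [subjects x trials] arrays.

    Returns a dict with keys ``rt``, ``confidence``, ``z_rt``, ``z_conf``
    (each [S, T]) and ``run``, ``block`` (each [T]; layout shared by all
    subjects).
    """
    ztable = validate_behavior(ztable)
    if "z_rt" not in ztable.columns:
        ztable = zscore_behavior(ztable)
    n_subjects = ztable["subject"].nunique()
    n_trials = len(ztable) // n_subjects
    first = ztable.iloc[:n_trials]
    out = {
        "run": first["run"].to_numpy(),
        "block": first["block"].to_numpy(),
    }
    for col in ("rt", "confidence", "z_rt", "z_conf"):
        out[col] = ztable[col].to_numpy(dtype=float).reshape(n_subjects, n_trials)
    return out
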