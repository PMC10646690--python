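"""Seven-factor generative model of trial-wise voxel activations.

The activation (beta) of voxel v on trial t of subject s is modelled as a
weighted sum of three group-level factors (shared by all subjects), three
subject-level factors (unique per subject), and trial-unique Gaussian noise:

    beta[s,t,v] = w_task_group * f_task_group[v]
                + w_rt_group   * f_rt_group[v]   * RT[s,t]
                + w_conf_group * f_conf_group[v] * conf[s,t]
                + w_task_subj  * f_task_subj[s,v]
                + w_rt_subj    * f_rt_subj[s,v]  * RT[s,t]
                + w_conf_subj  * f_conf_subj[s,v]* conf[s,t]
                + w_noise      * eps[s,t,v]

where RT and conf are the subject's z-scored reaction times and confidence
ratings, every latent factor f and the noise eps are i.i.d. standard normal,
and the w's scale each factor's contribution (w_noise is fixed to 1 in the
fitting protocol).  No spatial or temporal autocorrelation is simulated: the
model quantifies variance contributions, not anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .behavior import behavior_arrays, zscore_behavior
from .exceptions import DimensionError, InvalidParameterError

_GROUP_FIELDS = ("w_task_group", "w_rt_group", "w_conf_group")
_SUBJECT_FIELDS = ("w_task_subj", "w_rt_subj", "w_conf_subj")
#: Order of the six free weights wherever they appear as a flat vector.
FREE_WEIGHT_FIELDS = _GROUP_FIELDS + _SUBJECT_FIELDS


@dataclass(frozen=True)
class FactorWeights:
    """The seven factor weights; ``w_noise`` defaults to the protocol's fixed 1."""

    w_task_group: float = 0.0
    w_rt_group: float = 0.0
    w_conf_group: float = 0.0
    w_task_subj: float = 0.0
    w_rt_subj: float = 0.0
    w_conf_subj: float = 0.0
    w_noise: float = 1.0

    def __post_init__(self):
        for name in FREE_WEIGHT_FIELDS + ("w_noise",):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {value!r}")

    @property
    def group(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _GROUP_FIELDS])

    @property
    def subject(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _SUBJECT_FIELDS])

    def free_vector(self) -> np.ndarray:
        """The six free weights as a flat array (group task/rt/conf, then subject)."""
        return np.array([getattr(self, f) for f in FREE_WEIGHT_FIELDS])

    @classmethod
    def from_free_vector(cls, x, w_noise: float = 1.0) -> "FactorWeights":
        x = np.asarray(x, dtype=float)
        if x.shape != (6,):
            raise InvalidParameterError(f"expected 6 free weights, got shape {x.shape}")
        return cls(**{f: float(v) for f, v in zip(FREE_WEIGHT_FIELDS, x)}, w_noise=float(w_noise))

    def zeroed(self, which: str) -> "FactorWeights":
        """Copy with the 'group' or 'subject' weights set to zero (nested models)."""
        if which == "group":
            return replace(self, **{f: 0.0 for f in _GROUP_FIELDS})
        if which == "subject":
            return replace(self, **{f: 0.0 for f in _SUBJECT_FIELDS})
        raise InvalidParameterError(f"which must be 'group' or 'subject', got {which!r}")

    def as_dict(self) -> dict[str, float]:
        return {f: float(getattr(self, f)) for f in FREE_WEIGHT_FIELDS + ("w_noise",)}


@dataclass(frozen=True)
class StudyDesign:
    """Design constants of a cohort: layout and voxel count."""

    n_subjects: int = 50
    n_runs: int = 6
    blocks_per_run: int = 16
    trials_per_block: int = 8
    n_voxels: int = 10_000

    def __post_init__(self):
        for name in ("n_subjects", "n_runs", "blocks_per_run", "trials_per_block", "n_voxels"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.blocks_per_run * self.trials_per_block


def default_design() -> StudyDesign:
    """The study-scale design: 50 subjects, 768 trials (6x16x8), 10,000 voxels."""
    return StudyDesign()


@dataclass
class FactorMaps:
    """Latent factor values: group factors [V], subject factors [S, V]."""

    f_task_group: np.ndarray
    f_rt_group: np.ndarray
    f_conf_group: np.ndarray
    f_task_subj: np.ndarray
    f_rt_subj: np.ndarray
    f_conf_subj: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.f_task_subj.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.f_task_group.shape[0]


def sample_factor_maps(n_subjects: int, n_voxels: int, seed: int) -> FactorMaps:
    """Draw all six latent factor maps i.i.d. standard normal, reproducibly."""
    if n_subjects < 1 or n_voxels < 1:
        raise InvalidParameterError("n_subjects and n_voxels must be >= 1")
    rng = np.random.default_rng(seed)
    return FactorMaps(
        f_task_group=rng.standard_normal(n_voxels),
        f_rt_group=rng.standard_normal(n_voxels),
        f_conf_group=rng.standard_normal(n_voxels),
        f_task_subj=rng.standard_normal((n_subjects, n_voxels)),
        f_rt_subj=rng.standard_normal((n_subjects, n_voxels)),
        f_conf_subj=rng.standard_normal((n_subjects, n_voxels)),
    )


def noise_rng(seed: int, subject: int) -> np.random.Generator:
    """Per-subject noise stream.

    Noise is generated per subject (stream keyed by ``(seed, subject)``) so
    that large cohorts can be simulated or summarised one subject at a time
    while remaining bit-identical to the all-at-once path.
    """
    return np.random.default_rng([seed, subject])


@dataclass
class TrialDataset:
    """A cohort of trial-wise voxel betas plus behavior and design labels.

    ``betas`` is [subjects x trials x voxels]; ``behavior`` is the z-scored
    behavior table (one row per subject x trial, sorted).  ``provenance``
    records weights and seeds when the dataset was simulated.
    """

    betas: np.ndarray
    behavior: pd.DataFrame
    design: StudyDesign
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.betas.ndim != 3:
            raise DimensionError(f"betas must be 3-D [S,T,V], got shape {self.betas.shape}")
        s, t, _ = self.betas.shape
        if len(self.behavior) != s * t:
            raise DimensionError(
                f"behavior has {len(self.behavior)} rows, expected {s * t} ({s} subjects x {t} trials)"
            )
        self._arrays = None

    @property
    def n_subjects(self) -> int:
        return self.betas.shape[0]

    @property
    def n_trials(self) -> int:
        return self.betas.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[2]

    def arrays(self) -> Mapping[str, np.ndarray]:
        """Behavior pivoted to [S, T] arrays (cached)."""
        if self._arrays is None:
            self._arrays = behavior_arrays(self.behavior)
        return self._arrays


def simulate_dataset(
    weights: FactorWeights,
    maps: FactorMaps,
    zbehavior: pd.DataFrame,
    seed: int,
) -> TrialDataset:
    """Simulate trial-wise betas from the seven-factor equation.

    ``zbehavior`` must carry z_rt/z_conf columns (see
    :func:`mapfactors.behavior.zscore_behavior`); its subject count must match
    ``maps``.  Noise is drawn per subject from :func:`noise_rng`, so the
    result is reproducible from ``seed`` and independent of chunking.
    """
    if "z_rt" not in zbehavior.columns:
        zbehavior = zscore_behavior(zbehavior)
    arrays = behavior_arrays(zbehavior)
    z_rt, z_conf = arrays["z_rt"], arrays["z_conf"]
    n_subjects, n_trials = z_rt.shape
    if n_subjects != maps.n_subjects:
        raise DimensionError(
            f"behavior has {n_subjects} subjects but factor maps have {maps.n_subjects}"
        )
    n_voxels = maps.n_voxels
    betas = np.empty((n_subjects, n_trials, n_voxels))
    for s in range(n_subjects):
        task = weights.w_task_group * maps.f_task_group + weights.w_task_subj * maps.f_task_subj[s]
        rt_coef = weights.w_rt_group * maps.f_rt_group + weights.w_rt_subj * maps.f_rt_subj[s]
        conf_coef = (
            weights.w_conf_group * maps.f_conf_group + weights.w_conf_subj * maps.f_conf_subj[s]
        )
        betas[s] = (
            task[None, :]
            + np.outer(z_rt[s], rt_coef)
            + np.outer(z_conf[s], conf_coef)
            + weights.w_noise * noise_rng(seed, s).standard_normal((n_trials, n_voxels))
        )
    n_runs = int(arrays["run"].max())
    blocks_per_run = int(arrays["block"].max())
    design = StudyDesign(
        n_subjects=n_subjects,
        n_runs=n_runs,
        blocks_per_run=blocks_per_run,
        trials_per_block=max(1, n_trials // (n_runs * blocks_per_run)),
        n_voxels=n_voxels,
    )
    return TrialDataset(
        betas=betas,
        behavior=zbehavior,
        design=design,
        provenance={"weights": weights.as_dict(), "noise_seed": int(seed)},
    )
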