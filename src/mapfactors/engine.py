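"""Fast re-evaluation of simulated summary statistics across factor weights.

The generative equation is linear in the weights once the latent factors,
the noise, and the behavior are fixed.  Every map statistic the reliability
and similarity summaries need — per-subset trial means and median-split
pooled-t values — depends on the noise only through a handful of per-voxel
sufficient statistics (group noise means, noise sums of squares, and noise
cross-products with the centered behavioral regressors).  This engine draws
the factors and noise once, caches those statistics, and then evaluates the
maps for any weight vector in milliseconds without rematerializing the
[subjects x trials x voxels] beta array.

This is what makes common-random-numbers fitting practical: the optimizer
sees a deterministic, smooth objective surface, and the maps produced here
are numerically identical (to floating-point reassociation) to running
:func:`mapfactors.generative.simulate_dataset` followed by
:func:`mapfactors.maps.compute_all_maps`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import behavior_arrays, generate_behavior, median_split_labels, zscore_behavior
from .generative import (
    FactorMaps,
    FactorWeights,
    StudyDesign,
    noise_rng,
    sample_factor_maps,
)
from .maps import CONTRASTS, SUBSETS, _subset_indices
from .reliability import (
    DEFAULT_FRACTIONS,
    SummaryStatistics,
    summarize_maps,
)

_VARIABLES = ("rt", "confidence")


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one base seed."""
    state = np.random.SeedSequence(base_seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching rows of two [S, V] arrays."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    return (ac * bc).sum(axis=1) / np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))


class SimulationEngine:
    """Cache of factor maps, behavior, and noise sufficient statistics.

    Parameters
    ----------
    zbehavior
        Behavior table (z-scored or raw; z-scores are added if missing).
    n_voxels
        Number of simulated voxels.
    maps_seed, noise_seed
        Seeds of the latent factor maps and of the per-subject noise streams.
    """

    def __init__(self, zbehavior: pd.DataFrame, n_voxels: int, maps_seed: int, noise_seed: int):
        if "z_rt" not in zbehavior.columns:
            zbehavior = zscore_behavior(zbehavior)
        self.behavior = zbehavior
        arrays = behavior_arrays(zbehavior)
        self.z_rt, self.z_conf = arrays["z_rt"], arrays["z_conf"]
        self.n_subjects, self.n_trials = self.z_rt.shape
        self.n_voxels = int(n_voxels)
        self.maps_seed, self.noise_seed = int(maps_seed), int(noise_seed)
        self.factor_maps: FactorMaps = sample_factor_maps(
            self.n_subjects, self.n_voxels, maps_seed
        )
        self._precompute(arrays)

    # -- precomputation -------------------------------------------------

    def _precompute(self, arrays) -> None:
        S, T, V = self.n_subjects, self.n_trials, self.n_voxels
        subsets = {name: _subset_indices(T, name) for name in SUBSETS}

        # group membership per (variable, subset, subject): median split on raw behavior
        splits = {}
        for var in _VARIABLES:
            raw = arrays[var]
            for name, idx in subsets.items():
                labels = np.stack([median_split_labels(raw[s, idx]) for s in range(S)])
                splits[(var, name)] = labels == "high"

        # behavioral scalars and noise sufficient statistics
        self._task = {
            name: {
                "mr": self.z_rt[:, idx].mean(axis=1),
                "mc": self.z_conf[:, idx].mean(axis=1),
                "nbar": np.empty((S, V)),
            }
            for name, idx in subsets.items()
        }
        self._cells = {}
        for var in _VARIABLES:
            for name, idx in subsets.items():
                for grp in ("high", "low"):
                    self._cells[(var, name, grp)] = {
                        "n": np.empty(S, dtype=np.int64),
                        "mr": np.empty(S),
                        "mc": np.empty(S),
                        "Srr": np.empty(S),
                        "Scc": np.empty(S),
                        "Src": np.empty(S),
                        "nbar": np.empty((S, V)),
                        "Sre": np.empty((S, V)),
                        "Sce": np.empty((S, V)),
                        "See": np.empty((S, V)),
                    }

        for s in range(S):
            eps = noise_rng(self.noise_seed, s).standard_normal((T, V))
            for name, idx in subsets.items():
                self._task[name]["nbar"][s] = eps[idx].mean(axis=0)
                for var in _VARIABLES:
                    high = splits[(var, name)][s]
                    for grp, mask in (("high", high), ("low", ~high)):
                        g_idx = idx[mask]
                        cell = self._cells[(var, name, grp)]
                        r = self.z_rt[s, g_idx]
                        c = self.z_conf[s, g_idx]
                        E = eps[g_idx]
                        n = g_idx.size
                        mr, mc = r.mean(), c.mean()
                        dr, dc = r - mr, c - mc
                        nbar = E.mean(axis=0)
                        cell["n"][s] = n
                        cell["mr"][s], cell["mc"][s] = mr, mc
                        cell["Srr"][s] = dr @ dr
                        cell["Scc"][s] = dc @ dc
                        cell["Src"][s] = dr @ dc
                        cell["nbar"][s] = nbar
                        cell["Sre"][s] = dr @ E
                        cell["Sce"][s] = dc @ E
                        cell["See"][s] = np.einsum("tv,tv->v", E, E) - n * nbar**2

    # -- evaluation ------------------------------------------------------

    def _coefficients(self, weights: FactorWeights):
        fm = self.factor_maps
        a0 = weights.w_task_group * fm.f_task_group + weights.w_task_subj * fm.f_task_subj
        ar = weights.w_rt_group * fm.f_rt_group + weights.w_rt_subj * fm.f_rt_subj
        ac = weights.w_conf_group * fm.f_conf_group + weights.w_conf_subj * fm.f_conf_subj
        return a0, ar, ac

    def maps(self, weights: FactorWeights) -> dict[str, dict[str, np.ndarray]]:
        """Map stacks maps[contrast][subset] -> [S, V] for the given weights."""
        a0, ar, ac = self._coefficients(weights)
        wn = weights.w_noise
        out: dict[str, dict[str, np.ndarray]] = {c: {} for c in CONTRASTS}
        for name in SUBSETS:
            t = self._task[name]
            out["task"][name] = (
                a0 + ar * t["mr"][:, None] + ac * t["mc"][:, None] + wn * t["nbar"]
            )
        for var in _VARIABLES:
            for name in SUBSETS:
                stats_g = {}
                for grp in ("high", "low"):
                    cell = self._cells[(var, name, grp)]
                    mean = (
                        a0
                        + ar * cell["mr"][:, None]
                        + ac * cell["mc"][:, None]
                        + wn * cell["nbar"]
                    )
                    ss = (
                        ar**2 * cell["Srr"][:, None]
                        + ac**2 * cell["Scc"][:, None]
                        + 2 * ar * ac * cell["Src"][:, None]
                        + 2 * wn * (ar * cell["Sre"] + ac * cell["Sce"])
                        + wn**2 * cell["See"]
                    )
                    stats_g[grp] = (cell["n"][:, None], mean, ss)
                n_h, m_h, ss_h = stats_g["high"]
                n_l, m_l, ss_l = stats_g["low"]
                sp2 = (ss_h + ss_l) / (n_h + n_l - 2)
                out[var][name] = (m_h - m_l) / np.sqrt(sp2 * (1.0 / n_h + 1.0 / n_l))
        return out

    def summary(self, weights: FactorWeights, fractions=DEFAULT_FRACTIONS) -> SummaryStatistics:
        """Reliability/similarity summary at the given fractions (with selection)."""
        return summarize_maps(self.maps(weights), fractions)

    def targets(self, weights: FactorWeights) -> np.ndarray:
        """The six 100%-fraction fit targets, vectorized (no voxel selection).

        Order matches :meth:`SummaryStatistics.targets`: reliability then
        similarity, each for task, rt, confidence.
        """
        maps = self.maps(weights)
        rel = []
        sim = []
        for contrast in CONTRASTS:
            rel.append(
                _rowwise_pearson(maps[contrast]["odd"], maps[contrast]["even"]).mean()
            )
            stack = maps[contrast]["all"]
            others = (stack.sum(axis=0) - stack) / (self.n_subjects - 1)
            sim.append(_rowwise_pearson(stack, others).mean())
        return np.array(rel + sim)


def make_engine(
    design: StudyDesign,
    base_seed: int,
    behavior: pd.DataFrame | None = None,
) -> SimulationEngine:
    """Build an engine from design constants and one base seed.

    When no behavior table is supplied, synthetic behavior with the design's
    layout is generated from a child seed, mirroring the protocol in which
    simulations reuse the cohort's empirical RT/confidence values.
    """
    behavior_seed, maps_seed, noise_seed = derive_seeds(base_seed, 3)
    if behavior is None:
        behavior = generate_behavior(
            n_subjects=design.n_subjects,
            n_runs=design.n_runs,
            blocks_per_run=design.blocks_per_run,
            trials_per_block=design.trials_per_block,
            seed=behavior_seed,
        )
    return SimulationEngine(behavior, design.n_voxels, maps_seed, noise_seed)
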