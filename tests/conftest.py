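import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import mapfactors as mf
from mapfactors.behavior import zscore_behavior

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

SMALL_DESIGN = mf.StudyDesign(
    n_subjects=6, n_runs=2, blocks_per_run=4, trials_per_block=8, n_voxels=300
)

MIXED_WEIGHTS = mf.FactorWeights(
    w_task_group=0.17,
    w_rt_group=0.091,
    w_conf_group=0.061,
    w_task_subj=0.15,
    w_rt_subj=0.123,
    w_conf_subj=0.101,
)


@pytest.fixture(scope="session")
def small_design():
    return SMALL_DESIGN


@pytest.fixture(scope="session")
def small_behavior():
    d = SMALL_DESIGN
    return mf.generate_behavior(
        d.n_subjects, d.n_runs, d.blocks_per_run, d.trials_per_block, seed=1
    )


@pytest.fixture(scope="session")
def small_zbehavior(small_behavior):
    return zscore_behavior(small_behavior)


@pytest.fixture(scope="session")
def small_factor_maps():
    d = SMALL_DESIGN
    return mf.sample_factor_maps(d.n_subjects, d.n_voxels, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_factor_maps, small_zbehavior):
    """Mixed group+subject signal in unit noise at toy scale (6 x 64 x 300)."""
    return mf.simulate_dataset(MIXED_WEIGHTS, small_factor_maps, small_zbehavior, seed=7)


@pytest.fixture(scope="session")
def noise_dataset(small_factor_maps, small_zbehavior):
    return mf.simulate_dataset(
        mf.FactorWeights(), small_factor_maps, small_zbehavior, seed=8
    )


def make_dataset(betas, rt, confidence, trials_per_block=None):
    """Build a TrialDataset from explicit arrays (betas [S,T,V]; rt/conf [S,T])."""
    betas = np.asarray(betas, dtype=float)
    rt = np.asarray(rt, dtype=float)
    confidence = np.asarray(confidence)
    n_subjects, n_trials = rt.shape
    tpb = trials_per_block or n_trials
    behavior = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subjects), n_trials),
            "run": 1,
            "block": np.tile(1 + np.arange(n_trials) // tpb, n_subjects),
            "trial": np.tile(np.arange(n_trials), n_subjects),
            "rt": rt.ravel(),
            "confidence": confidence.ravel(),
        }
    )
    design = mf.StudyDesign(
        n_subjects=n_subjects,
        n_runs=1,
        blocks_per_run=max(1, n_trials // tpb),
        trials_per_block=tpb,
        n_voxels=betas.shape[2],
    )
    return mf.TrialDataset(betas=betas, behavior=zscore_behavior(behavior), design=design)
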