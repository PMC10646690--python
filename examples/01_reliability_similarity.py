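"""Split-half reliability and subject-to-group similarity of simulated maps.

Simulates a small cohort from the seven-factor generative model (group +
subject task/RT/confidence factors in unit Gaussian noise), builds the
per-subject activation maps, and prints the reliability/similarity summary.
"""

import mapfactors as mf

design = mf.StudyDesign(n_subjects=20, n_runs=2, blocks_per_run=16,
                        trials_per_block=8, n_voxels=2000)
behavior = mf.generate_behavior(design.n_subjects, design.n_runs,
                                design.blocks_per_run, design.trials_per_block, seed=1)
weights = mf.FactorWeights(w_task_group=0.17, w_rt_group=0.09, w_conf_group=0.06,
                           w_task_subj=0.15, w_rt_subj=0.12, w_conf_subj=0.10)
factor_maps = mf.sample_factor_maps(design.n_subjects, design.n_voxels, seed=2)
dataset = mf.simulate_dataset(weights, factor_maps, behavior, seed=3)

summary = mf.summarize(dataset, fractions=(0.1, 0.5, 1.0))
print(summary.table.to_string(index=False, float_format="%.3f"))
print()
print("Each row: across-subject mean +/- SEM of a Pearson correlation.")
print("'reliability' correlates a subject's odd-trial and even-trial maps on")
print("the top-fraction most activated voxels; 'similarity' correlates each")
print("subject's map with the mean map of the remaining subjects.  More noise")
print("or fewer trials pulls both toward 0; shared (group) structure pushes")
print("similarity up toward reliability.")
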