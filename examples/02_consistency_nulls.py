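"""Sign-consistency and top-10% overlap, calibrated against maximal-statistic nulls.

High sign consistency at single voxels arises by chance in whole-brain maps;
the relevant reference is the *maximum* over voxels under independent random
maps.  This example computes both statistics on simulated data with group
structure and compares against simulated and exact analytic nulls at a
reduced voxel count.
"""

import mapfactors as mf

n_subjects, n_voxels = 50, 5000
behavior = mf.generate_behavior(n_subjects, n_runs=2, blocks_per_run=16,
                                trials_per_block=8, seed=1)
weights = mf.FactorWeights(w_task_group=0.2, w_task_subj=0.1)
factor_maps = mf.sample_factor_maps(n_subjects, n_voxels, seed=2)
dataset = mf.simulate_dataset(weights, factor_maps, behavior, seed=3)
task_maps = mf.compute_all_maps(dataset)["task"]["all"]

consistency = mf.sign_consistency(task_maps)
overlap = mf.top_fraction_overlap(task_maps, fraction=0.1)
print(f"max folded sign consistency (group signal present): {consistency.c_folded.max():.0f}%")
print(f"max top-10% overlap (group signal present):         {overlap.max():.0f}%")

null = mf.random_null_consistency(n_subjects, n_voxels, n_iterations=200, seed=4)
exact = mf.expected_max_folded_consistency(n_subjects, n_voxels)
print(f"consistency null at V={n_voxels}: simulated {null.mean:.1f}%, exact binomial {exact:.1f}%")

null_ov = mf.random_null_overlap(n_subjects, n_voxels, 0.1, n_iterations=200, seed=5)
exact_ov = mf.expected_max_overlap(n_subjects, n_voxels, 0.1)
print(f"overlap null at V={n_voxels}:     simulated {null_ov.mean:.1f}%, order-statistic {exact_ov:.1f}%")
print()
print("Observed maxima far above the null means (which grow with voxel count)")
print("indicate genuinely shared activation structure across subjects.")
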