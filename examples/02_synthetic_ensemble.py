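"""Generate a two-state synthetic ensemble and inspect its features.

An "extended" state (reference torsions) and a "kinked" state (Linkage2
psi shifted) are mixed 70/30; per-frame observables are computed and
summarized per generator state to show that the descriptors separate the
two regimes.
"""
from gagflex import (build_topology, compute_feature_table, sample_ensemble,
                     two_state_spec)

top = build_topology("HA", 5)
traj = sample_ensemble(two_state_spec(top, n_frames=500, seed=42))
feats = compute_feature_table(traj, top)
feats["true_state"] = traj.state_labels

print(f"{traj.n_frames} frames, {traj.n_atoms} atoms")
print("\nmean features per generator state "
      "(0 = extended, 1 = kinked):")
print(feats.groupby("true_state")[["D_L1", "D_L2", "R_ee", "N_HB", "RMSD"]]
      .mean().round(3).to_string())
print("\nstate fractions:", feats["true_state"].value_counts(normalize=True)
      .sort_index().round(3).to_dict())
# D_L2 (the Linkage2 dihedral offset, 2 = fully extended) and R_ee drop
# sharply in the kinked state, while D_L1 stays near 2: only the
# inter-disaccharide linkages were perturbed.
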