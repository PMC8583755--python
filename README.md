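# gagflex

Conformational-ensemble analysis of short glycosaminoglycan (GAG) chains.

GAGs — hyaluronic acid (HA), heparan-6-sulphate (H6S), chondroitin-4- and
chondroitin-6-sulphate (C4S, C6S) — are unbranched polysaccharides of
repeating disaccharide units whose biological activity hinges on subtle
conformational preferences.  Their dominant degrees of freedom are the
glycosidic torsions φ and ψ on either side of each inter-residue oxygen
(φ = O5–C1–O4′–C4′, ψ = C1–O4′–C4′–C3′ for a (1→4) bond, with the O3
bridge substituted for (1→3) bonds).  `gagflex` is a library for people
who analyse molecular-dynamics-style ensembles of such chains: it computes
the standard structural observables, clusters conformations, and builds a
free-energy picture of the sampled states.

## What it computes

Per frame of a trajectory (coordinates in nm):

* **Dihedral offset** for each linkage class (N linkages):

  D<sub>offset</sub> = (1/2N) Σᵢ [(1 + cos(φᵢ − φ_ref)) + (1 + cos(ψᵢ − ψ_ref))]

  normalized so the fully extended reference conformation scores exactly 2
  (range [0, 2]; smaller = more kinked).
* **R_ee** — end-to-end distance, C1 of the starting (reducing-end)
  residue to C4 of the terminal residue.
* **Contacts** — residue–residue contact probability (any-atom minimum
  distance ≤ 0.4 nm), **hydrogen bonds** (D–A < 0.35 nm, deviation from
  D–H linearity < 30°), **fitted RMSD**, **cation–anion radial
  distribution functions** g(r) averaged over the carboxylate/sulphate
  groups, and **proximal-ion counts** (within 0.5 nm, minimum image).

On the ensemble:

* **Neighbour-count RMSD clustering** (the Daura algorithm): repeatedly
  extract the frame with the most neighbours within a cutoff (0.3/0.4/0.5
  nm) together with those neighbours; the cluster-count-vs-time curve is a
  sampling-convergence diagnostic.
* **Free-energy landscape**: PCA of the per-frame state vector
  (D_L1, D_L2, R_ee, N_HB), then ΔG(PC) = −k_B T ln[P(PC)/P_max] over a 2-D
  histogram of the first two PC scores, and k-means segregation of the
  states with elbow selection of k, including a per-state centroid report.

Because real microsecond GAG trajectories are rarely distributable, the
package includes a first-class synthetic-ensemble generator: frames are
drawn from a mixture of conformational states with von Mises torsion
noise and rebuilt into Cartesian coordinates over an idealized rigid-ring
geometry, so every downstream stage can be validated against known ground
truth.  Idealized topologies and fully extended reference structures for
all four GAGs (5 disaccharides: 10 residues, 5 Linkage1 + 4 Linkage2
bonds, net charge −5 for HA and −10 for the sulphated chains) are built
in; trajectories read/write through MDAnalysis (PDB, GRO, XTC, DCD,
multi-model PDB).

## Worked example

```python
import numpy as np
from gagflex import (build_topology, sample_ensemble, two_state_spec,
                     compute_feature_table, assemble_state_matrix,
                     principal_components, free_energy_surface,
                     kmeans_with_elbow, representative_frames)

top = build_topology("HA", n_disaccharides=5)
traj = sample_ensemble(two_state_spec(top, n_frames=2000, seed=11))
feats = compute_feature_table(traj, top)
proj = principal_components(assemble_state_matrix(feats), k_pc=2)
fes = free_energy_surface(proj, bins=50, temperature=300.0)
states = kmeans_with_elbow(proj, k_range=range(1, 9), seed=0, fixed_k=2)
print(representative_frames(states, proj, traj, top, feats)
      [["state", "population_pct", "R_ee", "Linkage2_psi"]].round(2))
```

prints

```
 state  population_pct  R_ee  Linkage2_psi
     1           71.55  4.82        176.37
     0           28.45  2.65         46.41
```

i.e. the pipeline recovers the generator's 70/30 mixture of an extended
state (R_ee ≈ 4.8 nm, Linkage2 ψ at the extended reference) and a kinked
state (R_ee ≈ 2.7 nm, ψ shifted by 130°); label agreement with the
generator's ground truth is 100% here.  The scripts in `examples/` walk
through each capability (topology building, synthetic ensembles,
clustering, the free-energy landscape, ion fields and RDFs), and a thin
CLI mirrors the pipeline: `gagflex run --n-frames 1000 --outdir out`.

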