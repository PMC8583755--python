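# Methods

## Chains and linkage chemistry

Four glycosaminoglycans are modelled as linear chains of `n` repeating
disaccharide units (default 5, i.e. 10 residues):

| kind | Linkage1 (intra-disaccharide)   | Linkage2 (inter-disaccharide)  |
|------|----------------------------------|--------------------------------|
| HA   | GlcNAc–β(1→4)–GlcUA             | GlcUA–β(1→3)–GlcNAc            |
| H6S  | GlcNAc(6S)–α(1→4)–GlcUA         | GlcUA–β(1→4)–GlcNAc(6S)        |
| C4S  | GalNAc(4S)–β(1→4)–GlcUA         | GlcUA–β(1→3)–GalNAc(4S)        |
| C6S  | GalNAc(6S)–β(1→4)–GlcUA         | GlcUA–β(1→3)–GalNAc(6S)        |

The starting residue for the end-to-end distance is the reducing-end
GlcUA; residue indices increase toward the non-reducing terminus, so an
`n`-disaccharide chain has `n` Linkage1 and `n−1` Linkage2 bonds.  Each
disaccharide carries one carboxylate (on GlcUA) and, for the sulphated
chains, one sulphate, giving formal charges of −n (HA) and −2n
(H6S/C4S/C6S) — the numbers of neutralizing monovalent cations.

Torsions follow the heavy-atom convention φ = O5–C1–O4′–C4′,
ψ = C1–O4′–C4′–C3′ for (1→4) bonds.  For (1→3) bonds no printed
convention exists in the sources this package follows; we substitute the
O3 bridge throughout, preserving the pattern
(ring-O, anomeric C, bridge O, acceptor C) for φ and
(anomeric C, bridge O, acceptor C, preceding C) for ψ:
φ = O5–C1–O3′–C3′, ψ = C1–O3′–C3′–C2′.  Dihedral signs follow the
standard convention (validated against MDAnalysis) and live in
(−180°, 180°].

## Idealized geometry and the chain builder

Residues are rigid templates: an ideal pyranose ring in the ⁴C₁ chair
(uniform ring bond 0.1505 nm, internal angle 111°) with substituents on
ideal axial/equatorial directions encoding the correct β-D stereochemistry
(verified against an independently embedded β-D-glucopyranose model);
glycosidic bonds use C1–O 0.142 nm and a C–O–C angle of 117°.  Heavy
atoms plus polar (hydroxyl/amide) hydrogens are modelled; aliphatic
hydrogens are omitted — RMSD and contacts therefore run over this reduced
all-heavy-atom set.  Ring puckering is out of scope by design: rings are
rigid and only the glycosidic torsions move.

A chain is built residue by residue: the next residue's anomeric anchors
(C1, O5) are placed from the acceptor's bridge geometry by
internal-coordinate construction at the requested (φ, ψ), and the rigid
template is least-squares-fitted onto the anchors.  Because the anchor
triple is congruent to the template's by construction, the fit is exact
and measured torsions reproduce the requested ones to < 10⁻⁶ degrees.
Building is fully deterministic (bit-identical on identical inputs).

### Reference torsions

The dihedral-offset descriptor needs per-class reference angles
(φ_ref, ψ_ref), defined as the torsions of the fully extended starting
structure.  Under the idealized rigid-ring geometry the fully extended
chain is found by deterministically maximizing the 5-disaccharide
end-to-end distance over class-shared torsions; the resulting values are
frozen as shipped defaults (recomputable via
`topology.find_extended_torsions`).  The extended chains span
R_ee = 4.88 nm (HA, C4S, C6S) and 4.77 nm (H6S, whose α(1→4) Linkage1
extends slightly less), matching the ≈4.8 nm expected for five
disaccharide repeats at ≈0.97 nm each.  Torsion references measured on
force-field-built starting structures of the same chains are provided as
`FORCE_FIELD_STARTING_TORSIONS`; they differ because real CHARMM-type
rings and exocyclic angles deviate from rigid ideal templates (building
the idealized chain at those values yields R_ee ≈ 3.4 nm, which would
break the defining property "reference = fully extended").  Users
analysing real trajectories against their own starting structure should
pass its measured torsions via
`build_topology(..., reference_torsions=...)`.

## Observables

* **Dihedral offset.**  For the N linkages of one class,
  `D = (1/2N) Σ [(1+cos Δφ) + (1+cos Δψ)]`.  The ½ normalization makes
  the reference score exactly 2 and bounds the range to [0, 2]; the
  un-normalized two-term sum would score 4 at the reference, which is
  inconsistent with the conventional [0, 2] reading of the descriptor, so
  the normalized form is used throughout.
* **Contacts.**  Two residues are in contact when any inter-atom distance
  is ≤ 0.4 nm (boundary inclusive).  The diagonal and first off-diagonal
  are reported but flagged masked-for-display (trivial covalent
  neighbours).
* **Hydrogen bonds.**  Counted when the donor–acceptor distance is
  strictly < 0.35 nm and the angle between the D→H and D→A directions
  (deviation from linearity) is strictly < 30°.  A literal
  donor–H–acceptor interior angle below 30° would describe a folded-back,
  non-bonding geometry, so the deviation convention — the one used by
  standard trajectory-analysis tools — is adopted; both cutoffs are
  configurable.  With no explicit solvent, the pipeline's N_HB feature
  counts intramolecular hydroxyl/amide→oxygen bonds, which is
  conformation dependent; deterministic pseudo-water probes
  (`place_hbond_probes`) exist to exercise the criterion itself.
* **RDF.**  g(r) per anionic group (its equivalent oxygens as reference
  points) with minimum-image distances, shell-volume normalization and
  bulk density ρ = n_ions/V_box; per-group time-averaged profiles are
  computed first and then averaged over groups.  Bin ranges beyond half
  the box edge are rejected.
* **Proximal ions.**  Ions whose minimum-image distance to any chain atom
  is ≤ 0.5 nm.
* **RMSD.**  Non-mass-weighted, after least-squares rigid superposition
  over all chain atoms (selection configurable).

Distances are nm, angles degrees, energies k_BT and kJ/mol everywhere.

## Clustering

Greedy neighbour-count clustering on the pairwise fitted-RMSD matrix:
count each remaining frame's neighbours within the cutoff (a frame is its
own neighbour, so the minimum cluster size is 1), extract the frame with
the most neighbours as centre together with its neighbours, repeat.  Ties
on the neighbour count go to the lowest frame index — a deterministic
choice matching common reference implementations; the sources define
neither the tie-break nor self-neighbouring, so both are package
decisions.  Standard cutoffs are 0.3/0.4/0.5 nm.  The evolution curve
re-clusters the leading t×t submatrix at growing checkpoints.  Pairwise
matrices above 4000 frames require an explicit opt-in (`allow_large`);
the pipeline strides long trajectories down to ≤ 400 frames for this
stage by default.

## Free-energy landscape

The state vector per frame is (D_L1, D_L2, R_ee, N_HB).  The four
features carry incommensurate units, so columns are z-scored before PCA
by default (without scaling, whichever feature has the largest variance
dominates); `standardize=False` restores raw-covariance PCA, and the
(mean, scale) pairs are recorded for exact de-standardization.  PCA is an
exact SVD (scikit-learn, full solver); scores on the first two components
are binned on a 50×50 grid spanning the data padded by 5%.  Free energy:
ΔG = −k_B T ln(P/P_max) with k_B = 0.008314 kJ/(mol·K), default
T = 300 K; the most probable bin sits at ΔG = 0 and empty bins are
undefined (written as missing, never infinite).

k-means (k-means++, 10 restarts, fixed seed — which makes the inertia
curve deterministic and non-increasing in k) runs over candidate
k = 1…8.  k is selected by the knee of the inertia curve: the interior
candidate farthest below the chord joining the curve's endpoints, ties to
the smaller k.  (The simpler largest-second-difference rule was rejected:
on well-separated clusters the raw inertia curve is convex and that rule
collapses to k = 2.)  The full curve is always exported so users can
override k.  Each state's representative structure is the member frame
closest to the k-means centre in PC space; the state report lists
population %, means and standard errors of R_ee and N_HB, and circular
means of (φ, ψ) per linkage class.  State populations are k-means label
counts, not basin integrals.

## Synthetic ensembles

Frames are i.i.d.: a latent state is drawn from the mixture weights, then
each linkage's (φ, ψ) independently from a von Mises distribution around
the state's means (concentration κ; κ = 0 is uniform, κ = 40 ≈ 9° spread).
The canonical two-regime generator mixes an extended state at the
reference torsions with a kinked state whose Linkage2 ψ is shifted by
−130° (far beyond the ≥ 90° separation needed for downstream
identifiability), at weights 0.7/0.3 — emulating the
extended-versus-compact dichotomy seen in real GAG ensembles.  Ion fields
are either uniform in the cubic box (default edge 6.8 nm; an ideal gas,
so g(r) = 1 analytically) or placed on thin shells around target atoms
(producing a contact-ion-pair-like g(r) peak at the shell radius).

What the generator does **not** emulate: temporal correlation (frames are
independent, so convergence diagnostics level off unrealistically fast),
excluded volume (ions and chain may overlap; torsion draws may produce
sterically clashing chains), coupling between linkages, ring-pucker
dynamics, explicit water, and ion–chain energetics (shell placement is
geometric, not Boltzmann-weighted).  Passing tests therefore demonstrate
the correctness of the *analysis machinery* against controlled ground
truth — not that the generator reproduces the physics of solvated GAGs.

## Numerical choices and problem sizes

Determinism: every stochastic component takes an integer seed
(numpy `default_rng`); identical seeds give bit-identical trajectories,
labels, and CSV outputs.  Degenerate inputs: colinear torsion quadruples
yield NaN (flagged, not raised); rank-deficient feature matrices yield
zero-variance components; empty k-means clusters are omitted from the
state report.  Test and validation sizes were chosen to finish in minutes
on one CPU: clustering oracle checks on ≤ 50-frame matrices (200 random
instances), ideal-gas RDF at 1000 ions × 100 frames (3-standard-error
bands per bin), and end-to-end state recovery on 5000-frame two-state
ensembles (label agreement ≥ 95%, populations within ±0.03).

## Known limitations

* The idealized rigid-ring geometry reproduces chain topology and
  connectivity-level geometry, not force-field detail; absolute torsion
  values differ from CHARMM-type structures (see "Reference torsions").
* N_HB without solvent is intramolecular and numerically small (0–3)
  rather than the ~80–110 of solvated chains.
* The Daura clustering is O(n²) in frames; long trajectories must be
  strided.
* Multi-model PDB is the only trajectory format whose mid-frame
  truncation is detectable; XTC/DCD readers index complete frames only,
  so a truncated tail reads as a shorter trajectory.
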