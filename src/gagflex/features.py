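"""Per-frame structural and interaction observables.

Implements the analysis layer applied to every trajectory frame:

* fitted RMSD to a reference structure (rigid least-squares superposition,
  non-mass-weighted, all chain atoms by default);
* end-to-end distance R_ee (C1 of the reducing-end residue to C4 of the
  terminal residue; the chain is treated as whole, no periodic wrapping);
* residue-residue contact probability maps (any-atom minimum distance
  <= 0.4 nm, boundary inclusive);
* glycosidic dihedral series and the collective dihedral-offset descriptor

      D_offset = (1/2N) * sum_i [ (1 + cos(phi_i - phi_ref))
                                 + (1 + cos(psi_i - psi_ref)) ]

  averaged over the N linkages of one class and normalized so the
  reference conformation scores exactly 2 (range [0, 2]; smaller values
  mean larger deviation from the extended reference);
* geometric hydrogen-bond counts (donor-acceptor distance < 0.35 nm,
  strict, and deviation of the D->A direction from the D-H direction
  < 30 degrees);
* cation-anion radial distribution functions averaged over anionic
  groups, with minimum-image distances and bulk-density normalization;
* proximal-ion counts (ions within 0.5 nm of any chain atom).

Distances in nm, angles in degrees throughout.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import dihedral, minimum_image_dists, rmsd_fitted
from .topology import GagTopology, ReferenceTorsions

CONTACT_CUTOFF = 0.4  # nm, inclusive
HBOND_DIST_CUTOFF = 0.35  # nm, strict
HBOND_ANGLE_CUTOFF = 30.0  # deg, deviation from linearity
ION_PROXIMITY_CUTOFF = 0.5  # nm


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DihedralSeries:
    """(phi, psi) per frame per linkage, degrees in (-180, 180]."""

    phi_psi: np.ndarray  # (n_frames, n_linkages, 2)
    linkage_classes: tuple

    @property
    def n_frames(self):
        return self.phi_psi.shape[0]


@dataclass(frozen=True)
class ContactMap:
    """Residue-residue contact probabilities in [0, 1], symmetric.

    ``masked`` flags the diagonal and first off-diagonal, which are
    trivially near 1 (covalently linked neighbours) and are conventionally
    hidden in displays; the values themselves are reported unmasked.
    """

    probability: np.ndarray  # (n_res, n_res)
    cutoff: float
    masked: np.ndarray  # bool, same shape


@dataclass(frozen=True)
class RdfProfile:
    """Radial distribution function averaged over anionic groups."""

    bin_centers: np.ndarray  # nm
    g: np.ndarray
    bin_width: float
    n_groups: int


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def fit_and_rmsd(traj, reference: np.ndarray, selection=None) -> np.ndarray:
    """Per-frame RMSD (nm) to ``reference`` after least-squares rigid
    superposition over ``selection`` (default: all chain atoms)."""
    ref = np.asarray(reference, float)
    if selection is None:
        selection = np.arange(traj.n_atoms)
    selection = np.asarray(selection, int)
    if selection.size == 0:
        raise ValueError("selection must be nonempty")
    if ref.shape[0] != traj.n_atoms:
        raise ValueError(
            f"atom-count mismatch: reference has {ref.shape[0]} atoms, "
            f"trajectory {traj.n_atoms}"
        )
    refsel = ref[selection]
    return np.array([rmsd_fitted(f[selection], refsel) for f in traj.coords])


def end_to_end_distance(traj, topology: GagTopology) -> np.ndarray:
    """Per-frame R_ee (nm): C1 of the starting (reducing-end) residue to
    C4 of the terminal residue, plain Euclidean distance (chain whole)."""
    try:
        i = topology.atom_index(*topology.ree_endpoints[0])
        j = topology.atom_index(*topology.ree_endpoints[1])
    except KeyError as e:
        raise ValueError(f"endpoint atom missing from topology: {e}") from None
    d = traj.coords[:, i, :] - traj.coords[:, j, :]
    return np.linalg.norm(d, axis=-1)


def contact_probability_map(traj, topology: GagTopology,
                            cutoff: float = CONTACT_CUTOFF) -> ContactMap:
    """Fraction of frames in which any-atom minimum distance between two
    residues is <= cutoff (boundary inclusive)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    groups = topology.residue_atom_indices
    n_res = len(groups)
    counts = np.zeros((n_res, n_res))
    for f in traj.coords:
        for a in range(n_res):
            for b in range(a + 1, n_res):
                dmin = cdist(f[groups[a]], f[groups[b]]).min()
                if dmin <= cutoff:
                    counts[a, b] += 1
    prob = counts / traj.n_frames
    prob = prob + prob.T
    np.fill_diagonal(prob, 1.0)  # a residue trivially contacts itself
    masked = np.zeros_like(prob, dtype=bool)
    ii = np.arange(n_res)
    masked[ii, ii] = True
    masked[ii[:-1], ii[:-1] + 1] = True
    masked[ii[:-1] + 1, ii[:-1]] = True
    return ContactMap(probability=prob, cutoff=cutoff, masked=masked)


def glycosidic_dihedrals(traj, topology: GagTopology) -> DihedralSeries:
    """Measure (phi, psi) for every linkage in every frame.

    Degenerate (colinear) geometries yield NaN for that frame/linkage.
    """
    n = traj.n_frames
    out = np.empty((n, topology.n_linkages, 2))
    for lk in topology.linkages:
        pa = traj.coords[:, topology.atom_indices(lk.phi_atoms), :]
        sa = traj.coords[:, topology.atom_indices(lk.psi_atoms), :]
        out[:, lk.index, 0] = dihedral(pa[:, 0], pa[:, 1], pa[:, 2], pa[:, 3])
        out[:, lk.index, 1] = dihedral(sa[:, 0], sa[:, 1], sa[:, 2], sa[:, 3])
    return DihedralSeries(
        phi_psi=out,
        linkage_classes=tuple(lk.linkage_class for lk in topology.linkages),
    )


def dihedral_offset(dihedrals: DihedralSeries, refs: ReferenceTorsions,
                    linkage_class: str) -> np.ndarray:
    """Collective dihedral-offset descriptor per frame for one linkage
    class: the (1 + cos) deviations of phi and psi from the reference,
    averaged over the class's N linkages and over the two angles, so the
    reference conformation scores exactly 2 and the range is [0, 2].
    """
    mask = np.array([c == linkage_class for c in dihedrals.linkage_classes])
    if not mask.any():
        raise ValueError(f"no linkages of class {linkage_class!r}")
    ref = refs.phi_psi[mask]  # (N, 2)
    dev = np.radians(dihedrals.phi_psi[:, mask, :] - ref[None, :, :])
    per_linkage = np.sum(1.0 + np.cos(dev), axis=2) / 2.0  # (n_frames, N)
    return per_linkage.mean(axis=1)


def count_hbonds(frame_coords: np.ndarray, donors, hydrogens, acceptors,
                 dist_cutoff: float = HBOND_DIST_CUTOFF,
                 angle_cutoff: float = HBOND_ANGLE_CUTOFF,
                 acceptor_coords: np.ndarray | None = None) -> int:
    """Count hydrogen bonds in one frame by the geometric criterion.

    A donor-acceptor pair is counted when the D-A distance is strictly
    below ``dist_cutoff`` and the angle between the D->H and D->A
    directions (deviation from linearity) is strictly below
    ``angle_cutoff``.  ``donors`` and ``hydrogens`` are parallel index
    arrays (each donor with its bound hydrogen); ``acceptors`` indexes
    ``acceptor_coords`` if given, else ``frame_coords``.  A donor's own
    hydrogen/self is never counted.
    """
    frame_coords = np.asarray(frame_coords, float)
    donors = np.asarray(donors, int)
    hydrogens = np.asarray(hydrogens, int)
    if donors.shape != hydrogens.shape:
        raise ValueError("donors and hydrogens must be parallel arrays")
    if donors.size and (hydrogens < 0).any():
        bad = donors[hydrogens < 0][0]
        raise ValueError(f"donor atom {int(bad)} has no attached hydrogen")
    acc_xyz = (np.asarray(acceptor_coords, float)[np.asarray(acceptors, int)]
               if acceptor_coords is not None
               else frame_coords[np.asarray(acceptors, int)])
    count = 0
    for d, h in zip(donors, hydrogens):
        pd, ph = frame_coords[d], frame_coords[h]
        da = acc_xyz - pd
        dist = np.linalg.norm(da, axis=1)
        u = ph - pd
        u /= np.linalg.norm(u)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosdev = (da @ u) / dist
        dev = np.degrees(np.arccos(np.clip(cosdev, -1.0, 1.0)))
        ok = (dist > 1e-9) & (dist < dist_cutoff) & (dev < angle_cutoff)
        if acceptor_coords is None:
            # exclude the donor itself and its own hydrogen as acceptors
            acc_idx = np.asarray(acceptors, int)
            ok &= (acc_idx != d) & (acc_idx != h)
        count += int(ok.sum())
    return count


def gag_donors_acceptors(topology: GagTopology):
    """Intra-chain donor/H pairs and acceptor oxygens of the GAG itself.

    Donors are hydroxyl and amide groups (O/N with a bound polar H);
    acceptors are all chain oxygens.  Used for the conformation-dependent
    intramolecular N_HB feature when no solvent is present.
    """
    donors, hydros = [], []
    names = topology.atom_names
    for r, atom_names in enumerate(topology.residue_atoms):
        present = set(atom_names)
        for h in present:
            if h.startswith("HO") or h == "HN2":
                heavy = h[1:]  # HO2 -> O2, HN2 -> N2
                if heavy in present:
                    donors.append(topology.atom_index(r, heavy))
                    hydros.append(topology.atom_index(r, h))
    acceptors = [i for i, n in enumerate(names) if n.startswith("O")]
    return (np.array(donors, int), np.array(hydros, int),
            np.array(acceptors, int))


def hbond_series(traj, topology: GagTopology,
                 dist_cutoff: float = HBOND_DIST_CUTOFF,
                 angle_cutoff: float = HBOND_ANGLE_CUTOFF) -> np.ndarray:
    """Per-frame intramolecular hydrogen-bond count N_HB for the chain."""
    donors, hydros, acceptors = gag_donors_acceptors(topology)
    return np.array([
        count_hbonds(f, donors, hydros, acceptors, dist_cutoff, angle_cutoff)
        for f in traj.coords
    ])


def radial_distribution(traj, group_oxygens, bins: np.ndarray,
                        box_edge: float | None = None,
                        ion_coords: np.ndarray | None = None) -> RdfProfile:
    """Cation-anion g(r) averaged over anionic groups and frames.

    For each group (a set of equivalent oxygen atoms) a g(r) profile is
    accumulated over the group's oxygens and all frames with
    minimum-image distances, shell-volume normalization and bulk ion
    density rho = n_ions / box volume; the per-group profiles are then
    averaged.  ``bins`` are edges (nm), strictly increasing, with range at
    most half the box edge.
    """
    box = box_edge if box_edge is not None else traj.box_edge
    ions = ion_coords if ion_coords is not None else traj.ion_coords
    if ions is None or ions.shape[1] == 0:
        raise ValueError("trajectory has no ions")
    bins = np.asarray(bins, float)
    if bins[-1] > box / 2:
        raise ValueError("bin range exceeds half the box edge")
    n_ions = ions.shape[1]
    rho = n_ions / box**3
    shell_vol = 4.0 / 3.0 * np.pi * (bins[1:] ** 3 - bins[:-1] ** 3)
    profiles = []
    for group in group_oxygens:
        idx = np.asarray(group, int)
        counts = np.zeros(len(bins) - 1)
        for f in range(traj.n_frames):
            d = minimum_image_dists(traj.coords[f][idx], ions[f], box)
            counts += np.histogram(d.ravel(), bins=bins)[0]
        n_ref = idx.size * traj.n_frames
        profiles.append(counts / (n_ref * rho * shell_vol))
    g = np.mean(profiles, axis=0)
    centers = 0.5 * (bins[:-1] + bins[1:])
    return RdfProfile(bin_centers=centers, g=g,
                      bin_width=float(np.mean(np.diff(bins))),
                      n_groups=len(group_oxygens))


def proximal_ion_count(traj, cutoff: float = ION_PROXIMITY_CUTOFF,
                       ion_coords: np.ndarray | None = None,
                       box_edge: float | None = None) -> np.ndarray:
    """Per-frame number of ions within ``cutoff`` (minimum image) of any
    chain atom."""
    ions = ion_coords if ion_coords is not None else traj.ion_coords
    box = box_edge if box_edge is not None else traj.box_edge
    if ions is None:
        return np.zeros(traj.n_frames, dtype=int)
    out = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        if ions[f].shape[0] == 0:
            out[f] = 0
            continue
        d = minimum_image_dists(ions[f], traj.coords[f], box)
        out[f] = int(np.sum(d.min(axis=1) <= cutoff))
    return out


def compute_feature_table(traj, topology: GagTopology,
                          reference: np.ndarray | None = None):
    """All per-frame features as a pandas DataFrame.

    Columns: D_L1, D_L2, R_ee, N_HB, plus auxiliary RMSD (to ``reference``
    or the extended chain) and ion_count when ions are present.
    """
    import pandas as pd

    from .topology import build_extended_chain

    refs = topology.reference_torsions
    dih = glycosidic_dihedrals(traj, topology)
    data = {
        "D_L1": dihedral_offset(dih, refs, "Linkage1"),
        "D_L2": dihedral_offset(dih, refs, "Linkage2"),
        "R_ee": end_to_end_distance(traj, topology),
        "N_HB": hbond_series(traj, topology),
    }
    ref_coords = reference if reference is not None else build_extended_chain(topology)
    data["RMSD"] = fit_and_rmsd(traj, ref_coords)
    if traj.ion_coords is not None:
        data["ion_count"] = proximal_ion_count(traj)
    return pd.DataFrame(data)
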