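"""Reading and writing standard structure/trajectory formats.

MDAnalysis does the format work (PDB and GRO topologies; XTC, DCD and
multi-model PDB trajectories).  Internally everything is in nm and
0-based indices; at the format boundary coordinates are converted to the
format's native unit (Angstrom for PDB/DCD, nm for GRO/XTC — MDAnalysis
normalizes to Angstrom in memory) and PDB serials/residue numbers are
1-based.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .ensemble import Trajectory
from .topology import PDB_RESNAMES, GagTopology

NM_PER_ANGSTROM = 0.1

_ION_NAME = "NA"  # monovalent cation placeholder in exported files


def _mda():
    import MDAnalysis as mda
    warnings.filterwarnings("ignore", module="MDAnalysis")
    return mda


def _universe_from(topology: GagTopology, n_ions: int = 0,
                   resname_map: dict | None = None):
    mda = _mda()
    names = list(topology.atom_names)
    resindex = list(topology.atom_residues)
    rmap = dict(PDB_RESNAMES)
    if resname_map:
        rmap.update(resname_map)
    resnames = [rmap[c] for c in topology.residue_codes]
    n_res = topology.n_residues
    for k in range(n_ions):
        names.append(_ION_NAME)
        resindex.append(n_res + k)
        resnames.append(_ION_NAME)
    n_atoms = len(names)
    u = mda.Universe.empty(n_atoms, n_residues=n_res + n_ions,
                           atom_resindex=np.array(resindex),
                           residue_segindex=np.zeros(n_res + n_ions, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, n_res + n_ions + 1))
    elements = list(topology.atom_elements) + ["Na"] * n_ions
    u.add_TopologyAttr("elements", elements)
    return u


def write_topology_pdb(topology: GagTopology, coords: np.ndarray, path,
                       resname_map: dict | None = None) -> None:
    """Write a single-MODEL PDB of one frame (input coords in nm)."""
    u = _universe_from(topology, resname_map=resname_map)
    u.atoms.positions = np.asarray(coords) / NM_PER_ANGSTROM
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_topology_sidecar(topology: GagTopology, path) -> None:
    """JSON sidecar: linkage torsion quadruples and anionic-group atom
    indices, all 0-based (PDB serials in the companion file are 1-based)."""
    doc = {
        "gag_kind": topology.gag_kind,
        "n_disaccharides": topology.n_disaccharides,
        "formal_charge": topology.formal_charge,
        "residue_codes": list(topology.residue_codes),
        "linkages": [
            {
                "index": lk.index,
                "class": lk.linkage_class,
                "geometry": lk.geometry,
                "anomeric": lk.anomeric,
                "phi_atoms": [int(i) for i in topology.atom_indices(lk.phi_atoms)],
                "psi_atoms": [int(i) for i in topology.atom_indices(lk.psi_atoms)],
            }
            for lk in topology.linkages
        ],
        "carboxylate_oxygens": [
            [int(i) for i in topology.atom_indices(g)]
            for g in topology.carboxylate_oxygens
        ],
        "sulphate_oxygens": [
            [int(i) for i in topology.atom_indices(g)]
            for g in topology.sulphate_oxygens
        ],
        "ree_endpoints": [int(topology.atom_index(*e)) for e in topology.ree_endpoints],
        "reference_torsions": topology.reference_torsions.phi_psi.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def write_trajectory(traj: Trajectory, topology_path, trajectory_path) -> None:
    """Write topology PDB plus a trajectory file; the trajectory format is
    inferred from the extension (.xtc, .dcd, or .pdb for multi-model)."""
    if traj.topology is None:
        raise ValueError("trajectory has no attached GagTopology")
    n_ions = 0 if traj.ion_coords is None else traj.ion_coords.shape[1]
    u = _universe_from(traj.topology, n_ions=n_ions)

    def frame_xyz(i):
        xyz = traj.coords[i]
        if n_ions:
            xyz = np.vstack([xyz, traj.ion_coords[i]])
        return xyz / NM_PER_ANGSTROM

    u.atoms.positions = frame_xyz(0)
    if traj.box_edge is not None:
        u.dimensions = [traj.box_edge / NM_PER_ANGSTROM] * 3 + [90, 90, 90]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(topology_path))
        mda = _mda()
        with mda.Writer(str(trajectory_path), u.atoms.n_atoms) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = frame_xyz(i)
                if traj.box_edge is not None:
                    u.dimensions = [traj.box_edge / NM_PER_ANGSTROM] * 3 + [90, 90, 90]
                w.write(u.atoms)


def read_trajectory(topology_path, trajectory_path=None,
                    topology: GagTopology | None = None) -> Trajectory:
    """Load a trajectory through MDAnalysis, coordinates in nm.

    ``topology_path`` is a PDB or GRO file; ``trajectory_path`` (XTC, DCD
    or multi-model PDB) defaults to reading frames from the topology file
    itself.  Ion atoms (resname NA/K/NA+) are split from the chain.  An
    unreadable or truncated trajectory raises with the index of the last
    complete frame.
    """
    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if trajectory_path is None:
                u = mda.Universe(str(topology_path))
            else:
                u = mda.Universe(str(topology_path), str(trajectory_path))
        except Exception as e:
            raise IOError(
                f"could not open {trajectory_path or topology_path}: {e}"
            ) from e
        ion_sel = u.select_atoms("resname NA K NA+ K+ SOD POT")
        chain_sel = u.atoms - ion_sel
        frames, ion_frames = [], []
        n_read = 0
        try:
            for _ in u.trajectory:
                frames.append(chain_sel.positions * NM_PER_ANGSTROM)
                if len(ion_sel):
                    ion_frames.append(ion_sel.positions * NM_PER_ANGSTROM)
                n_read += 1
        except Exception as e:
            raise IOError(
                f"trajectory {trajectory_path or topology_path} unreadable "
                f"after frame {n_read - 1} (last complete frame): {e}"
            ) from e
        box = None
        if u.dimensions is not None and u.dimensions[0] > 0:
            box = float(u.dimensions[0]) * NM_PER_ANGSTROM
    coords = np.array(frames)
    if topology is not None and coords.shape[1] != topology.n_atoms:
        raise ValueError(
            f"atom-count mismatch: file has {coords.shape[1]} chain atoms, "
            f"topology expects {topology.n_atoms}"
        )
    resindex = chain_sel.resindices
    return Trajectory(
        atom_names=list(chain_sel.names),
        atom_residues=resindex - resindex.min() if len(resindex) else resindex,
        residue_codes=[r.resname for r in chain_sel.residues],
        atom_elements=[n[0] for n in chain_sel.names],
        coords=coords,
        box_edge=box,
        ion_coords=np.array(ion_frames) if ion_frames else None,
        topology=topology,
    )
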