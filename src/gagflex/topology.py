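"""GAG chain topologies and idealized 3-D structure building.

Encodes the chemistry of four short glycosaminoglycans built from repeating
disaccharide units of an uronic acid (GlcUA) and an N-acetylated amino sugar:

====  =========================================  =========================================
kind  Linkage1 (intra-disaccharide)              Linkage2 (inter-disaccharide)
====  =========================================  =========================================
HA    GlcNAc-beta(1->4)-GlcUA                    GlcUA-beta(1->3)-GlcNAc
H6S   GlcNAc(6S)-alpha(1->4)-GlcUA               GlcUA-beta(1->4)-GlcNAc(6S)
C4S   GalNAc(4S)-beta(1->4)-GlcUA                GlcUA-beta(1->3)-GalNAc(4S)
C6S   GalNAc(6S)-beta(1->4)-GlcUA                GlcUA-beta(1->3)-GalNAc(6S)
====  =========================================  =========================================

The "starting residue" is the reducing-end GlcUA; residue indices increase
toward the non-reducing terminus.  An ``n``-disaccharide chain therefore has
``2n`` residues, ``n`` Linkage1 and ``n - 1`` Linkage2 glycosidic bonds.

Glycosidic torsions follow the IUPAC-style heavy-atom convention: for a
(1->4) bond phi = O5-C1-O4'-C4' and psi = C1-O4'-C4'-C3'; for a (1->3) bond
the acceptor-side atoms shift to the O3 bridge, phi = O5-C1-O3'-C3' and
psi = C1-O3'-C3'-C2'.

Residues are modelled as rigid ideal pyranose rings in the 4C1 chair with
heavy atoms plus polar hydrogens (hydroxyl and amide); aliphatic hydrogens
are omitted.  Chains are assembled residue-by-residue from internal
coordinates, so any set of per-linkage (phi, psi) maps deterministically to
Cartesian coordinates — the same machinery builds the fully extended
reference structure and re-builds synthetic ensemble frames from sampled
torsions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .geometry import angle_between, nerf_place, superpose

GAG_KINDS = ("HA", "H6S", "C4S", "C6S")

# Idealized bond lengths (nm) and angles (deg)
RING_BOND = 0.1505
RING_ANGLE = 111.0
GLYCOSIDIC_BOND = 0.142   # anomeric C1 - bridge O
GLYCOSIDIC_ANGLE = 117.0  # C1 - O - C at the bridge
TETRAHEDRAL = 109.47

# Reference (phi, psi) per linkage class, degrees: the torsions of the
# fully extended chain under this package's idealized rigid-ring geometry,
# obtained by maximizing the end-to-end distance of the 5-disaccharide
# chain over class-shared torsions (deterministic; reproducible with
# ``find_extended_torsions``).  The reference conformation therefore is,
# by construction, the maximally extended chain (R_ee ~ 4.8-4.9 nm).
# Overridable via ``build_topology(..., reference_torsions=...)``.
DEFAULT_REFERENCE_TORSIONS: dict[str, dict[str, tuple[float, float]]] = {
    "HA": {"Linkage1": (-67.91, 119.66), "Linkage2": (-119.16, 176.46)},
    "H6S": {"Linkage1": (139.94, -154.28), "Linkage2": (-118.97, 118.94)},
    "C4S": {"Linkage1": (-67.91, 119.66), "Linkage2": (-119.16, 176.46)},
    "C6S": {"Linkage1": (-67.91, 119.66), "Linkage2": (-119.16, 176.46)},
}

# Torsion references measured on the force-field-built extended starting
# models of the same chains (all-atom CHARMM-type geometry).  They differ
# from the idealized-geometry references above because real pyranose rings
# and exocyclic angles deviate from rigid ideal templates.  Provided as an
# alternative reference convention for users analysing force-field
# trajectories against their own starting structures.
FORCE_FIELD_STARTING_TORSIONS: dict[str, dict[str, tuple[float, float]]] = {
    "HA": {"Linkage1": (-132.1, -146.1), "Linkage2": (-93.4, 76.1)},
    "H6S": {"Linkage1": (-111.6, 87.2), "Linkage2": (45.6, 64.3)},
    "C4S": {"Linkage1": (-139.4, -146.9), "Linkage2": (-102.8, 91.1)},
    "C6S": {"Linkage1": (-120.8, -156.3), "Linkage2": (-106.6, 87.4)},
}

# residue codes per kind: (uronic acid, amino sugar)
_RESIDUE_CODES = {
    "HA": ("GU", "GlN"),
    "H6S": ("GU", "aGlN"),
    "C4S": ("GU", "GaN4"),
    "C6S": ("GU", "GaN6"),
}

# PDB residue-name dialect (3-char); override via the io layer if a reader
# expects different codes.
PDB_RESNAMES = {"GU": "GCU", "GlN": "NAG", "aGlN": "NDG", "GaN4": "ASG", "GaN6": "NGS"}

# acceptor bridge per kind for Linkage2 (Linkage1 always enters GlcUA at O4)
_LINKAGE2_BRIDGE = {"HA": "O3", "H6S": "O4", "C4S": "O3", "C6S": "O3"}
_LINKAGE1_ANOMERIC = {"HA": "beta", "H6S": "alpha", "C4S": "beta", "C6S": "beta"}


# ---------------------------------------------------------------------------
# residue templates
# ---------------------------------------------------------------------------

_RING_NAMES = ("C1", "C2", "C3", "C4", "C5", "O5")


def _chair_ring(bond: float = RING_BOND, ring_angle: float = RING_ANGLE):
    """Ideal 6-membered chair: returns name -> xyz (nm) for the ring atoms.

    Atoms sit at 60-degree steps on a circle with alternating +/-q pucker;
    q is solved so every internal ring angle equals ``ring_angle``.  The
    parity is chosen so C1 lies below and C4 above the mean plane (4C1).
    """

    def positions(q):
        r = np.sqrt(bond**2 - 4 * q**2)
        pts = []
        for i in range(6):
            th = np.radians(-60.0 * i)
            pts.append([r * np.cos(th), r * np.sin(th), ((-1) ** (i + 1)) * q])
        return np.array(pts)

    def angle_err(q):
        p = positions(q)
        return angle_between(p[5], p[0], p[1]) - ring_angle

    q = brentq(angle_err, 1e-6, bond / 2 - 1e-6)
    pts = positions(q)
    return {name: pts[i] for i, name in enumerate(_RING_NAMES)}


def _exocyclic_dirs(ring: dict, name: str):
    """(axial, equatorial) unit vectors at a ring atom of the chair."""
    i = _RING_NAMES.index(name)
    p = ring[name]
    u1 = ring[_RING_NAMES[(i - 1) % 6]] - p
    u2 = ring[_RING_NAMES[(i + 1) % 6]] - p
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    s = -(u1 + u2)
    s /= np.linalg.norm(s)
    n = np.cross(u1, u2)
    n /= np.linalg.norm(n)
    cosg = np.cos(np.radians(TETRAHEDRAL)) / np.dot(s, u1)
    cosg = float(np.clip(cosg, -1.0, 1.0))
    sing = np.sqrt(1.0 - cosg**2)
    d1 = cosg * s + sing * n
    d2 = cosg * s - sing * n
    # the chair's axis is z; axial is the direction more parallel to it
    if abs(d1[2]) >= abs(d2[2]):
        return d1, d2
    return d2, d1


@dataclass(frozen=True)
class ResidueTemplate:
    """Rigid ideal-geometry coordinates for one monosaccharide type."""

    code: str
    atoms: dict  # name -> xyz (nm), local frame
    anomeric: str  # "alpha" | "beta"
    c1_o5_bond: float
    o5_c1_o1_angle: float  # deg; used to reattach the ring across a linkage

    @property
    def atom_names(self):
        return list(self.atoms)


def _place(atoms, a, b, c, name, bond, angle, torsion):
    atoms[name] = nerf_place(atoms[a], atoms[b], atoms[c], bond, angle, torsion)


def _build_template(code: str, anomeric: str, galacto: bool, c2_group: str,
                    c6_group: str, o4_group: str) -> ResidueTemplate:
    ring = _chair_ring()
    atoms = {n: ring[n].copy() for n in _RING_NAMES}

    def sub(carbon, name, bond, kind):
        ax, eq = _exocyclic_dirs(ring, carbon)
        d = ax if kind == "ax" else eq
        atoms[name] = atoms[carbon] + bond * d

    # anomeric oxygen: equatorial for beta-D, axial for alpha-D in 4C1
    sub("C1", "O1", GLYCOSIDIC_BOND, "eq" if anomeric == "beta" else "ax")
    _place(atoms, "C2", "C1", "O1", "HO1", 0.096, 107.0, 180.0)

    if c2_group == "OH":
        sub("C2", "O2", 0.143, "eq")
        _place(atoms, "C1", "C2", "O2", "HO2", 0.096, 107.0, 180.0)
    else:  # N-acetyl
        sub("C2", "N2", 0.149, "eq")
        _place(atoms, "C1", "C2", "N2", "C7", 0.133, 123.0, 150.0)
        _place(atoms, "C1", "C2", "N2", "HN2", 0.101, 118.0, -30.0)
        _place(atoms, "C2", "N2", "C7", "O7", 0.123, 123.0, 0.0)
        _place(atoms, "C2", "N2", "C7", "C8", 0.150, 116.0, 180.0)

    sub("C3", "O3", 0.143, "eq")
    _place(atoms, "C2", "C3", "O3", "HO3", 0.096, 107.0, 180.0)

    sub("C4", "O4", 0.143, "ax" if galacto else "eq")
    if o4_group == "OH":
        _place(atoms, "C3", "C4", "O4", "HO4", 0.096, 107.0, 180.0)
    else:  # 4-O-sulphate
        _place(atoms, "C3", "C4", "O4", "S", 0.157, 118.0, 180.0)
        for i, tor in enumerate((60.0, 180.0, -60.0), start=1):
            _place(atoms, "C4", "O4", "S", f"O{i}S", 0.146, 105.0, tor)

    sub("C5", "C6", 0.152, "eq")
    if c6_group == "carboxylate":
        _place(atoms, "C4", "C5", "C6", "O6A", 0.125, 117.0, 30.0)
        _place(atoms, "C4", "C5", "C6", "O6B", 0.125, 117.0, -150.0)
    else:
        _place(atoms, "C4", "C5", "C6", "O6", 0.143, 111.0, 180.0)
        if c6_group == "OH":
            _place(atoms, "C5", "C6", "O6", "HO6", 0.096, 107.0, 180.0)
        else:  # 6-O-sulphate
            _place(atoms, "C5", "C6", "O6", "S", 0.157, 118.0, 180.0)
            for i, tor in enumerate((60.0, 180.0, -60.0), start=1):
                _place(atoms, "C6", "O6", "S", f"O{i}S", 0.146, 105.0, tor)

    return ResidueTemplate(
        code=code,
        atoms=atoms,
        anomeric=anomeric,
        c1_o5_bond=float(np.linalg.norm(atoms["C1"] - atoms["O5"])),
        o5_c1_o1_angle=float(angle_between(atoms["O5"], atoms["C1"], atoms["O1"])),
    )


def residue_template(code: str) -> ResidueTemplate:
    """Ideal-geometry template for a residue code (cached)."""
    try:
        return _TEMPLATES[code]
    except KeyError:
        raise ValueError(
            f"unknown residue code {code!r}; valid codes: {sorted(_TEMPLATES)}"
        ) from None


_TEMPLATES = {
    "GU": _build_template("GU", "beta", galacto=False, c2_group="OH",
                          c6_group="carboxylate", o4_group="OH"),
    "GlN": _build_template("GlN", "beta", galacto=False, c2_group="NAc",
                           c6_group="OH", o4_group="OH"),
    "aGlN": _build_template("aGlN", "alpha", galacto=False, c2_group="NAc",
                            c6_group="sulphate", o4_group="OH"),
    "GaN4": _build_template("GaN4", "beta", galacto=True, c2_group="NAc",
                            c6_group="OH", o4_group="sulphate"),
    "GaN6": _build_template("GaN6", "beta", galacto=True, c2_group="NAc",
                            c6_group="sulphate", o4_group="OH"),
}


# ---------------------------------------------------------------------------
# topology data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Linkage:
    """One glycosidic bond.  The donor contributes the anomeric C1, the
    acceptor the bridge oxygen; atom references are (residue_index, name)."""

    index: int
    linkage_class: str  # "Linkage1" | "Linkage2"
    geometry: str  # "1-4" | "1-3"
    anomeric: str  # "alpha" | "beta"
    donor: int
    acceptor: int
    bridge: str  # acceptor-side bridge oxygen name ("O4" or "O3")
    phi_atoms: tuple  # 4 x (residue_index, atom_name)
    psi_atoms: tuple


@dataclass(frozen=True)
class ReferenceTorsions:
    """Per-linkage reference (phi, psi) of the fully extended structure."""

    phi_psi: np.ndarray  # (n_linkages, 2) degrees
    linkage_classes: tuple

    def for_class(self, linkage_class: str) -> np.ndarray:
        mask = [c == linkage_class for c in self.linkage_classes]
        return self.phi_psi[mask]


@dataclass(frozen=True)
class GagTopology:
    """Chemistry and geometry conventions of one GAG chain."""

    gag_kind: str
    n_disaccharides: int
    residue_codes: tuple  # per residue, reducing end first
    residue_atoms: tuple  # per residue, tuple of atom names actually present
    linkages: tuple  # of Linkage
    carboxylate_oxygens: tuple  # per GlcUA: ((res, "O6A"), (res, "O6B"))
    sulphate_oxygens: tuple  # per sulphated residue: 3 x (res, name)
    ree_endpoints: tuple  # ((0, "C1"), (last, "C4"))
    reference_torsions: ReferenceTorsions
    _index: dict = field(repr=False, hash=False, compare=False, default=None)

    # -- atom bookkeeping ---------------------------------------------------
    def __post_init__(self):
        idx = {}
        for r, names in enumerate(self.residue_atoms):
            for n in names:
                idx[(r, n)] = len(idx)
        object.__setattr__(self, "_index", idx)

    @property
    def n_residues(self) -> int:
        return len(self.residue_codes)

    @property
    def n_atoms(self) -> int:
        return len(self._index)

    def atom_index(self, residue: int, name: str) -> int:
        return self._index[(residue, name)]

    def atom_indices(self, refs) -> np.ndarray:
        return np.array([self.atom_index(r, n) for r, n in refs], dtype=int)

    @property
    def atom_names(self):
        return [n for names in self.residue_atoms for n in names]

    @property
    def atom_residues(self) -> np.ndarray:
        return np.array(
            [r for r, names in enumerate(self.residue_atoms) for _ in names], dtype=int
        )

    @property
    def atom_elements(self):
        out = []
        for n in self.atom_names:
            out.append("H" if n.startswith(("H",)) else n[0])
        return out

    @property
    def residue_atom_indices(self):
        """List of global atom-index arrays, one per residue."""
        res = self.atom_residues
        return [np.flatnonzero(res == r) for r in range(self.n_residues)]

    # -- chemistry ----------------------------------------------------------
    @property
    def formal_charge(self) -> int:
        return -(len(self.carboxylate_oxygens) + len(self.sulphate_oxygens))

    @property
    def n_linkages(self) -> int:
        return len(self.linkages)

    def linkages_of_class(self, linkage_class: str):
        return [lk for lk in self.linkages if lk.linkage_class == linkage_class]


def build_topology(gag_kind: str, n_disaccharides: int = 5,
                   reference_torsions: dict | None = None) -> GagTopology:
    """Construct the chain topology for one GAG kind.

    Parameters
    ----------
    gag_kind : {"HA", "H6S", "C4S", "C6S"}
    n_disaccharides : int
        Number of repeating disaccharide units (the studies modelled 5).
    reference_torsions : dict, optional
        ``{"Linkage1": (phi, psi), "Linkage2": (phi, psi)}`` in degrees,
        overriding the shipped extended-structure defaults.
    """
    if gag_kind not in GAG_KINDS:
        raise ValueError(
            f"unknown gag_kind {gag_kind!r}; valid codes: {', '.join(GAG_KINDS)}"
        )
    if n_disaccharides < 1:
        raise ValueError("n_disaccharides must be >= 1")

    uronic, amino = _RESIDUE_CODES[gag_kind]
    codes = []
    for _ in range(n_disaccharides):
        codes.extend([uronic, amino])
    n_res = len(codes)

    l2_bridge = _LINKAGE2_BRIDGE[gag_kind]
    linkages = []
    for d in range(1, n_res):
        a = d - 1
        if d % 2 == 1:  # amino sugar -> GlcUA: Linkage1, always 1->4 at O4
            cls, bridge, anom = "Linkage1", "O4", _LINKAGE1_ANOMERIC[gag_kind]
        else:  # GlcUA -> amino sugar: Linkage2
            cls, bridge, anom = "Linkage2", l2_bridge, "beta"
        geometry = "1-4" if bridge == "O4" else "1-3"
        cx = "C4" if bridge == "O4" else "C3"
        cprev = "C3" if bridge == "O4" else "C2"
        phi = ((d, "O5"), (d, "C1"), (a, bridge), (a, cx))
        psi = ((d, "C1"), (a, bridge), (a, cx), (a, cprev))
        linkages.append(
            Linkage(index=len(linkages), linkage_class=cls, geometry=geometry,
                    anomeric=anom, donor=d, acceptor=a, bridge=bridge,
                    phi_atoms=phi, psi_atoms=psi)
        )

    # per-residue atom lists: start from the template, strip atoms consumed
    # by linkage roles (donor loses its anomeric O1/HO1; an acceptor loses
    # the bridge hydroxyl hydrogen)
    removed = [set() for _ in range(n_res)]
    for lk in linkages:
        removed[lk.donor].update({"O1", "HO1"})
        removed[lk.acceptor].add("H" + lk.bridge)
    residue_atoms = tuple(
        tuple(n for n in residue_template(c).atom_names if n not in removed[r])
        for r, c in enumerate(codes)
    )

    carbox = tuple(
        ((r, "O6A"), (r, "O6B")) for r, c in enumerate(codes) if c == "GU"
    )
    sulph = tuple(
        tuple((r, f"O{i}S") for i in (1, 2, 3))
        for r, c in enumerate(codes)
        if "S" in residue_template(c).atom_names
    )

    ref_map = dict(DEFAULT_REFERENCE_TORSIONS[gag_kind])
    if reference_torsions:
        ref_map.update(reference_torsions)
    phi_psi = np.array([ref_map[lk.linkage_class] for lk in linkages], dtype=float)
    refs = ReferenceTorsions(
        phi_psi=phi_psi, linkage_classes=tuple(lk.linkage_class for lk in linkages)
    )

    return GagTopology(
        gag_kind=gag_kind,
        n_disaccharides=n_disaccharides,
        residue_codes=tuple(codes),
        residue_atoms=residue_atoms,
        linkages=tuple(linkages),
        carboxylate_oxygens=carbox,
        sulphate_oxygens=sulph,
        ree_endpoints=((0, "C1"), (n_res - 1, "C4")),
        reference_torsions=refs,
    )


# ---------------------------------------------------------------------------
# chain building from internal coordinates
# ---------------------------------------------------------------------------

def build_chain_coords(topology: GagTopology, torsions: np.ndarray) -> np.ndarray:
    """Cartesian coordinates (n_atoms, 3) for given per-linkage torsions.

    ``torsions`` has shape (n_linkages, 2) with columns (phi, psi) in
    degrees.  Residues are rigid ideal templates; each donor residue is
    placed by constructing its anomeric anchor atoms (C1, O5) from the
    acceptor's bridge geometry at the requested torsions and rigid-fitting
    the template onto them, which reproduces the requested torsions exactly.
    Deterministic: identical inputs give bit-identical output.
    """
    torsions = np.asarray(torsions, dtype=float)
    if torsions.shape != (topology.n_linkages, 2):
        raise ValueError(
            f"torsions must have shape ({topology.n_linkages}, 2), "
            f"got {torsions.shape}"
        )
    coords = np.empty((topology.n_atoms, 3))
    placed = [None] * topology.n_residues  # per residue: dict name -> xyz

    tpl0 = residue_template(topology.residue_codes[0])
    placed[0] = {n: tpl0.atoms[n] for n in topology.residue_atoms[0]}

    for lk in topology.linkages:
        phi, psi = torsions[lk.index]
        acc = placed[lk.acceptor]
        tpl = residue_template(topology.residue_codes[lk.donor])
        cx, cprev = lk.psi_atoms[2][1], lk.psi_atoms[3][1]
        obr = acc[lk.bridge]
        c1 = nerf_place(acc[cprev], acc[cx], obr,
                        GLYCOSIDIC_BOND, GLYCOSIDIC_ANGLE, psi)
        o5 = nerf_place(acc[cx], obr, c1,
                        tpl.c1_o5_bond, tpl.o5_c1_o1_angle, phi)
        mob = np.array([tpl.atoms["C1"], tpl.atoms["O1"], tpl.atoms["O5"]])
        tgt = np.array([c1, obr, o5])
        R, t = superpose(mob, tgt)
        placed[lk.donor] = {
            n: tpl.atoms[n] @ R.T + t for n in topology.residue_atoms[lk.donor]
        }

    for r, names in enumerate(topology.residue_atoms):
        for n in names:
            coords[topology.atom_index(r, n)] = placed[r][n]
    return coords


def build_extended_chain(topology: GagTopology) -> np.ndarray:
    """Single-frame coordinates of the fully extended chain, i.e. the chain
    built with every linkage at its reference (phi, psi)."""
    return build_chain_coords(topology, topology.reference_torsions.phi_psi)


def end_to_end(topology: GagTopology, coords: np.ndarray) -> float:
    """End-to-end distance (nm) of one frame: C1 of the reducing-end
    residue to C4 of the non-reducing terminal residue."""
    i = topology.atom_index(*topology.ree_endpoints[0])
    j = topology.atom_index(*topology.ree_endpoints[1])
    return float(np.linalg.norm(coords[i] - coords[j]))


def find_extended_torsions(gag_kind: str, n_disaccharides: int = 5, seed: int = 7):
    """Recompute the maximally extended class-shared (phi, psi) for a GAG
    kind by maximizing the chain's end-to-end distance (the procedure that
    produced ``DEFAULT_REFERENCE_TORSIONS``).  Deterministic for a given
    seed.  Returns ``{"Linkage1": (phi, psi), "Linkage2": (phi, psi)}``.
    """
    from scipy.optimize import differential_evolution, minimize

    top = build_topology(gag_kind, n_disaccharides)
    classes = [lk.linkage_class for lk in top.linkages]

    def neg_ree(x):
        tors = np.array([x[:2] if c == "Linkage1" else x[2:] for c in classes])
        return -end_to_end(top, build_chain_coords(top, tors))

    res = differential_evolution(
        neg_ree, [(-180.0, 180.0)] * 4, seed=seed, tol=1e-10, maxiter=400
    )
    res2 = minimize(neg_ree, res.x, method="Nelder-Mead",
                    options=dict(xatol=1e-9, fatol=1e-11, maxiter=10000))
    x = res2.x if res2.fun <= res.fun else res.x
    return {"Linkage1": (x[0], x[1]), "Linkage2": (x[2], x[3])}
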