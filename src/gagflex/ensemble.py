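"""Synthetic conformational ensembles with known ground truth.

Real microsecond trajectories of solvated GAG chains are not distributable,
so this module generates stand-in ensembles whose statistical structure is
fully controlled: each frame belongs to a latent conformational state drawn
from a categorical mixture, and every glycosidic (phi, psi) is drawn
independently from a von Mises distribution centred on that state's
per-linkage means.  Coordinates are rebuilt from the sampled torsions over
the idealized rigid-ring geometry, so the generating torsions are recovered
exactly by dihedral measurement — every downstream stage can be tested
against the generator's ground truth.

Optionally a field of monovalent cations is placed in a cubic periodic box,
either uniformly (an ideal gas, for which the radial distribution function
is analytically 1) or on a thin shell around chosen target atoms (producing
a g(r) peak at the shell radius, mimicking contact ion pairing).

No explicit water is generated.  For testing the geometric hydrogen-bond
criterion, :func:`place_hbond_probes` deterministically positions acceptor
probes at prescribed distance and angular deviation from chain donors.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import nerf_place
from .topology import GagTopology, build_chain_coords

DEFAULT_BOX_EDGE = 6.8  # nm, cubic solvation box of the reference setup
BOX_MARGIN = 1.2  # nm, minimum chain-to-wall distance the box must allow


@dataclass(frozen=True)
class ConformationalState:
    """One mixture component: per-linkage mean torsions and spread."""

    name: str
    mean_torsions: np.ndarray  # (n_linkages, 2) degrees
    concentration: float  # von Mises kappa, >= 0 (0 = uniform)
    weight: float

    def __post_init__(self):
        object.__setattr__(
            self, "mean_torsions", np.asarray(self.mean_torsions, dtype=float)
        )
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not self.weight > 0:
            raise ValueError("state weights must be positive")


@dataclass(frozen=True)
class IonModel:
    """Monovalent-cation placement model for a cubic periodic box."""

    mode: str  # "uniform_bulk" | "shell"
    n_ions: int
    box_edge: float = DEFAULT_BOX_EDGE
    target_atoms: np.ndarray | None = None  # indices into the chain, shell mode
    shell_radius: float = 0.25
    shell_width: float = 0.02

    def __post_init__(self):
        if self.mode not in ("uniform_bulk", "shell"):
            raise ValueError("mode must be 'uniform_bulk' or 'shell'")
        if self.n_ions < 0:
            raise ValueError("n_ions must be >= 0")
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")
        if self.mode == "shell":
            if self.target_atoms is None or len(self.target_atoms) == 0:
                raise ValueError("shell mode needs target_atoms")
            object.__setattr__(
                self, "target_atoms", np.asarray(self.target_atoms, dtype=int)
            )
            if self.shell_radius + self.shell_width / 2 > self.box_edge / 2:
                raise ValueError(
                    "shell radius exceeds half the box edge; periodic images ambiguous"
                )


@dataclass(frozen=True)
class EnsembleSpec:
    """Full recipe for a synthetic ensemble."""

    topology: GagTopology
    states: tuple  # of ConformationalState
    n_frames: int
    seed: int
    ion_model: IonModel | None = None

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.states:
            raise ValueError("at least one state is required")
        for st in self.states:
            if st.mean_torsions.shape != (self.topology.n_linkages, 2):
                raise ValueError(
                    f"state {st.name!r}: mean_torsions must be "
                    f"({self.topology.n_linkages}, 2)"
                )
        w = np.array([st.weight for st in self.states], dtype=float)
        object.__setattr__(self, "_weights", w / w.sum())

    @property
    def weights(self) -> np.ndarray:
        return self._weights


@dataclass
class Trajectory:
    """In-memory ensemble: per-frame chain coordinates plus metadata.

    Coordinates are in nm.  ``state_labels`` carries the generator's latent
    state per frame (synthetic data only; None for file-read trajectories).
    """

    atom_names: list
    atom_residues: np.ndarray  # (n_atoms,) residue index per atom
    residue_codes: list  # per residue
    atom_elements: list
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    box_edge: float | None = None
    ion_coords: np.ndarray | None = None  # (n_frames, n_ions, 3)
    state_labels: np.ndarray | None = None  # (n_frames,)
    torsions: np.ndarray | None = None  # (n_frames, n_linkages, 2), synthetic only
    topology: GagTopology | None = field(default=None, repr=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")
        if self.box_edge is not None and self.box_edge <= 0:
            raise ValueError("box edge must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def two_state_spec(topology: GagTopology, n_frames: int, seed: int,
                   weights: tuple = (0.7, 0.3), concentration: float = 40.0,
                   kink_shift: float = -130.0,
                   ion_model: IonModel | None = None) -> EnsembleSpec:
    """Canonical two-regime ensemble: an "extended" state at the reference
    torsions and a "kinked" state whose Linkage2 psi is shifted by
    ``kink_shift`` degrees (default -130, well beyond the 90-degree
    separation needed for the states to be distinguishable downstream).
    """
    ref = topology.reference_torsions.phi_psi
    kinked = ref.copy()
    for lk in topology.linkages:
        if lk.linkage_class == "Linkage2":
            kinked[lk.index, 1] += kink_shift
    kinked[:, 1] = (kinked[:, 1] + 180.0) % 360.0 - 180.0
    states = (
        ConformationalState("extended", ref, concentration, weights[0]),
        ConformationalState("kinked", kinked, concentration, weights[1]),
    )
    return EnsembleSpec(topology=topology, states=states, n_frames=n_frames,
                        seed=seed, ion_model=ion_model)


def sample_ensemble(spec: EnsembleSpec) -> Trajectory:
    """Draw a synthetic trajectory from the mixture model.

    Frame i's latent state is drawn from the mixture weights; each
    linkage's (phi, psi) is drawn independently from a von Mises around the
    state's means with the state's concentration; coordinates are rebuilt
    from the torsions over the idealized geometry.  Identical specs give
    bit-identical trajectories.
    """
    top = spec.topology
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    labels = rng.choice(len(spec.states), size=n, p=spec.weights)

    torsions = np.empty((n, top.n_linkages, 2))
    for s, st in enumerate(spec.states):
        idx = np.flatnonzero(labels == s)
        if idx.size == 0:
            continue
        mu = np.radians(st.mean_torsions)[None, :, :]
        if st.concentration == 0:
            draw = rng.uniform(-np.pi, np.pi, size=(idx.size,) + mu.shape[1:])
        else:
            draw = rng.vonmises(mu, st.concentration,
                                size=(idx.size,) + mu.shape[1:])
        torsions[idx] = np.degrees(draw)
    # wrap into (-180, 180]
    torsions = -((-torsions + 180.0) % 360.0 - 180.0)

    coords = np.empty((n, top.n_atoms, 3))
    for i in range(n):
        coords[i] = build_chain_coords(top, torsions[i])

    box = spec.ion_model.box_edge if spec.ion_model else DEFAULT_BOX_EDGE
    # centre the chain in the box so minimum-image arithmetic is benign
    coords += box / 2 - coords.mean(axis=(0, 1))

    ion_coords = None
    if spec.ion_model is not None and spec.ion_model.n_ions > 0:
        ion_coords = np.empty((n, spec.ion_model.n_ions, 3))
        for i in range(n):
            ion_coords[i] = place_ions(coords[i], spec.ion_model,
                                       seed=rng.integers(2**31))

    return Trajectory(
        atom_names=top.atom_names,
        atom_residues=top.atom_residues,
        residue_codes=list(top.residue_codes),
        atom_elements=top.atom_elements,
        coords=coords,
        box_edge=box,
        ion_coords=ion_coords,
        state_labels=labels,
        torsions=torsions,
        topology=top,
    )


def place_ions(frame: np.ndarray, model: IonModel, seed: int) -> np.ndarray:
    """Ion coordinates (n_ions, 3) for one chain frame.

    uniform_bulk: i.i.d. uniform in the box.  shell: each ion sits on a
    thin spherical shell (radius +- width/2, isotropic direction) around a
    uniformly chosen target atom, wrapped into the box.
    """
    rng = np.random.default_rng(seed)
    n = model.n_ions
    if n == 0:
        return np.empty((0, 3))
    if model.mode == "uniform_bulk":
        return rng.uniform(0.0, model.box_edge, size=(n, 3))
    centers = np.asarray(frame, float)[rng.choice(model.target_atoms, size=n)]
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.uniform(model.shell_radius - model.shell_width / 2,
                    model.shell_radius + model.shell_width / 2, size=(n, 1))
    return (centers + r * v) % model.box_edge


def place_hbond_probes(frame: np.ndarray, donors: np.ndarray,
                       hydrogens: np.ndarray, distance: float,
                       angular_deviation: float) -> np.ndarray:
    """Deterministic pseudo-water acceptor probes for H-bond testing.

    For each donor D with bound hydrogen H, place one acceptor probe at
    ``distance`` (nm) from D such that the angle between D->H and D->probe
    equals ``angular_deviation`` (degrees).  With deviation 0 the probe is
    exactly along the D-H direction (an ideal linear hydrogen bond).
    """
    frame = np.asarray(frame, float)
    out = np.empty((len(donors), 3))
    for k, (d, h) in enumerate(zip(donors, hydrogens)):
        pd, ph = frame[d], frame[h]
        u = ph - pd
        u /= np.linalg.norm(u)
        # any perpendicular direction; deterministic choice
        ref = np.array([1.0, 0.0, 0.0])
        if abs(u @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        perp = np.cross(u, ref)
        perp /= np.linalg.norm(perp)
        a = np.radians(angular_deviation)
        out[k] = pd + distance * (np.cos(a) * u + np.sin(a) * perp)
    return out
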