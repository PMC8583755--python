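"""Free-energy landscape of collective structural fluctuations.

The per-frame state vector concatenates four observables — the dihedral
offsets of the two linkage classes, the end-to-end distance and the
hydrogen-bond count — into a frames x 4 matrix.  Principal component
analysis reduces it to two collective coordinates; a two-dimensional
histogram of the scores gives a probability surface P(PC), converted into
a free-energy surface by the Boltzmann inversion

    dG(PC) = -kB T ln [ P(PC) / P_max ]

so the most probable bin sits at dG = 0.  Conformational states are then
segregated by k-means clustering of the PC scores, with k chosen by the
elbow of the inertia curve, and a representative frame per state is the
member closest to the k-means centre in PC space.

Features have incommensurate units (dimensionless offsets, nm, counts),
so columns are z-scored before PCA by default; raw-covariance PCA is a
flag away.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

BOLTZMANN_KJ_PER_MOL_K = 0.008314462618  # kB in kJ/(mol K)
DEFAULT_TEMPERATURE = 300.0  # K
FEATURE_COLUMNS = ("D_L1", "D_L2", "R_ee", "N_HB")


@dataclass(frozen=True)
class FeatureMatrix:
    """frames x 4 state-vector matrix with the standardization record."""

    values: np.ndarray  # standardized (or raw) data actually used downstream
    columns: tuple
    means: np.ndarray
    scales: np.ndarray
    standardized: bool

    def destandardize(self) -> np.ndarray:
        return self.values * self.scales + self.means


@dataclass(frozen=True)
class PcProjection:
    """PCA scores and model of the feature matrix."""

    scores: np.ndarray  # (n_frames, k_pc)
    loadings: np.ndarray  # (k_pc, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray


@dataclass(frozen=True)
class FesGrid:
    """Binned probability and free energy over (PC1, PC2)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray  # sums to 1 over occupied bins
    dg_kt: np.ndarray  # NaN on empty bins
    dg_kjmol: np.ndarray
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return self.probability > 0


@dataclass(frozen=True)
class StateClustering:
    """k-means segregation of PC space with the elbow-selection trace."""

    labels: np.ndarray  # (n_frames,)
    k: int
    centers: np.ndarray  # (k, k_pc)
    k_candidates: np.ndarray
    inertias: np.ndarray
    populations: np.ndarray  # fraction per state, sums to 1
    centroid_frames: np.ndarray  # representative frame index per state


def assemble_state_matrix(features: pd.DataFrame,
                          standardize: bool = True) -> FeatureMatrix:
    """Column-bind the four state-vector features in fixed order.

    ``features`` must contain the columns D_L1, D_L2, R_ee, N_HB with a
    common length.  With ``standardize`` each column is z-scored and the
    (mean, scale) pair recorded; zero-variance columns get scale 1.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in features]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    X = features.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite entries")
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales = np.where(scales > 0, scales, 1.0)
    if standardize:
        values = (X - means) / scales
    else:
        values, means, scales = X, np.zeros(X.shape[1]), np.ones(X.shape[1])
    return FeatureMatrix(values=values, columns=FEATURE_COLUMNS, means=means,
                         scales=scales, standardized=standardize)


def principal_components(matrix: FeatureMatrix, k_pc: int = 2) -> PcProjection:
    """Project the (already centred/standardized) state matrix onto its
    top ``k_pc`` principal components."""
    X = matrix.values
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more frames than features for PCA")
    pca = PCA(n_components=k_pc, svd_solver="full")
    scores = pca.fit_transform(X)
    return PcProjection(scores=scores, loadings=pca.components_,
                        explained_variance_ratio=pca.explained_variance_ratio_)


def free_energy_surface(projection: PcProjection, bins: int = 50,
                        temperature: float = DEFAULT_TEMPERATURE,
                        pad_fraction: float = 0.05) -> FesGrid:
    """Boltzmann-invert the 2-D histogram of (PC1, PC2) scores.

    The grid spans the scores' extent padded by ``pad_fraction``; empty
    bins are left undefined (NaN), never infinite.  The most probable bin
    has dG = 0 exactly; dG >= 0 everywhere occupied.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    s = projection.scores[:, :2]
    lo, hi = s.min(axis=0), s.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    lo = lo - pad_fraction * span
    hi = hi + pad_fraction * span
    H, xe, ye = np.histogram2d(s[:, 0], s[:, 1], bins=bins,
                               range=[(lo[0], hi[0]), (lo[1], hi[1])])
    P = H / H.sum()
    pmax = P.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        dg_kt = np.where(P > 0, -np.log(P / pmax), np.nan)
    kt = BOLTZMANN_KJ_PER_MOL_K * temperature
    return FesGrid(x_edges=xe, y_edges=ye, probability=P, dg_kt=dg_kt,
                   dg_kjmol=dg_kt * kt, temperature=temperature)


def select_elbow(k_candidates: np.ndarray, inertias: np.ndarray) -> int:
    """Elbow rule: the interior candidate whose inertia lies farthest below
    the chord joining the curve's endpoints (maximum-deviation "knee"
    detection; ties go to the smaller k).  With fewer than three candidates
    the smallest k is returned."""
    k_candidates = np.asarray(k_candidates, int)
    if len(k_candidates) < 3:
        return int(k_candidates[0])
    k0, k1 = k_candidates[0], k_candidates[-1]
    i0, i1 = inertias[0], inertias[-1]
    chord = i0 + (i1 - i0) * (k_candidates - k0) / (k1 - k0)
    gap = chord - inertias
    return int(k_candidates[int(np.argmax(gap))])


def kmeans_with_elbow(projection: PcProjection, k_range=range(1, 9),
                      seed: int = 0, fixed_k: int | None = None) -> StateClustering:
    """k-means over PC scores with inertia-curve elbow selection.

    Every candidate k is fitted with k-means++ and 10 restarts from a
    fixed seed, so the inertia curve is deterministic and non-increasing.
    ``fixed_k`` overrides the elbow rule (the curve is still reported).
    """
    ks = np.asarray(sorted(k_range), int)
    if ks.size == 0:
        raise ValueError("k_range must be nonempty")
    X = projection.scores
    if ks.max() > X.shape[0]:
        raise ValueError("k exceeds the number of frames")
    fits, inertias = {}, []
    for k in ks:
        km = KMeans(n_clusters=int(k), n_init=10, random_state=seed).fit(X)
        fits[int(k)] = km
        inertias.append(km.inertia_)
    inertias = np.array(inertias)
    k_sel = int(fixed_k) if fixed_k is not None else select_elbow(ks, inertias)
    if k_sel not in fits:
        fits[k_sel] = KMeans(n_clusters=k_sel, n_init=10, random_state=seed).fit(X)
    km = fits[k_sel]
    labels = km.labels_
    populations = np.bincount(labels, minlength=k_sel) / labels.size
    centroid_frames = _nearest_members(X, km.cluster_centers_, labels)
    return StateClustering(labels=labels, k=k_sel, centers=km.cluster_centers_,
                           k_candidates=ks, inertias=inertias,
                           populations=populations,
                           centroid_frames=centroid_frames)


def _nearest_members(X, centers, labels):
    out = np.full(centers.shape[0], -1, dtype=int)
    for c in range(centers.shape[0]):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            continue  # empty cluster: no representative
        d = np.linalg.norm(X[members] - centers[c], axis=1)
        out[c] = members[int(np.argmin(d))]
    return out


def representative_frames(clustering: StateClustering,
                          projection: PcProjection, traj, topology,
                          features: pd.DataFrame) -> pd.DataFrame:
    """Per-state centroid report: population, R_ee, N_HB and class-mean
    (phi, psi) with standard errors, plus the centroid frame index.

    States are reported in decreasing population order.  Empty clusters
    (possible when k-means drops a centre) are omitted.
    """
    from .features import glycosidic_dihedrals

    dih = glycosidic_dihedrals(traj, topology)
    rows = []
    order = np.argsort(clustering.populations)[::-1]
    for state in order:
        members = np.flatnonzero(clustering.labels == state)
        if members.size == 0:
            continue
        row = {
            "state": int(state),
            "population_pct": 100.0 * clustering.populations[state],
            "centroid_frame": int(clustering.centroid_frames[state]),
            "R_ee": features["R_ee"].to_numpy()[members].mean(),
            "R_ee_se": _sem(features["R_ee"].to_numpy()[members]),
            "N_HB": features["N_HB"].to_numpy()[members].mean(),
            "N_HB_se": _sem(features["N_HB"].to_numpy()[members]),
        }
        for cls in ("Linkage1", "Linkage2"):
            mask = np.array([c == cls for c in dih.linkage_classes])
            if not mask.any():
                continue
            ang = dih.phi_psi[members][:, mask, :]  # (m, N, 2)
            phi_m, phi_se = _circular_mean_se(ang[:, :, 0])
            psi_m, psi_se = _circular_mean_se(ang[:, :, 1])
            row[f"{cls}_phi"], row[f"{cls}_phi_se"] = phi_m, phi_se
            row[f"{cls}_psi"], row[f"{cls}_psi_se"] = psi_m, psi_se
        rows.append(row)
    return pd.DataFrame(rows)


def _sem(x):
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def _circular_mean_se(ang_deg: np.ndarray):
    """Circular mean (deg) over all values and the SEM of per-frame
    circular means, for a (frames, linkages) angle block."""
    rad = np.radians(ang_deg)
    mean = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
    per_frame = np.degrees(
        np.arctan2(np.sin(rad).mean(axis=1), np.cos(rad).mean(axis=1))
    )
    # centre per-frame means on the overall mean before a linear SEM
    dev = (per_frame - mean + 180.0) % 360.0 - 180.0
    return float(mean), _sem(dev)
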