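"""End-to-end orchestration: ensemble -> features -> clustering -> FES.

Every stage writes its artifacts as CSV/JSON into the output directory and
registers them in a provenance manifest (config, seeds, package versions,
file list).  Reruns with an identical config produce byte-identical CSVs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import cluster_count_evolution, daura_cluster, pairwise_rmsd_matrix
from .config import PipelineConfig
from .ensemble import IonModel, Trajectory, sample_ensemble, two_state_spec
from .features import compute_feature_table, contact_probability_map, radial_distribution
from .fes import (assemble_state_matrix, free_energy_surface, kmeans_with_elbow,
                  principal_components, representative_frames)
from .io import read_trajectory
from .topology import build_extended_chain, build_topology

log = logging.getLogger("gagflex")


def _float_fmt(df: pd.DataFrame) -> str:
    return df.to_csv(index=False, float_format="%.8g", lineterminator="\n")


class PipelineRun:
    """Tracks the output directory and the provenance manifest."""

    def __init__(self, config: PipelineConfig, outdir=None):
        self.config = config.validate()
        self.outdir = Path(outdir if outdir is not None else config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.files: list[str] = []

    def write_csv(self, name: str, df: pd.DataFrame) -> Path:
        p = self.outdir / name
        p.write_text(_float_fmt(df))
        self.files.append(name)
        return p

    def write_json(self, name: str, obj) -> Path:
        p = self.outdir / name
        p.write_text(json.dumps(obj, indent=1, sort_keys=True))
        self.files.append(name)
        return p

    def finish(self) -> Path:
        cfg = self.config.to_dict()
        manifest = {
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "gagflex_version": __version__,
            "numpy_version": np.__version__,
            "files": sorted(self.files),
        }
        p = self.outdir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return p


def build_ensemble(config: PipelineConfig) -> Trajectory:
    """Synthesize (or load) the trajectory named by the config."""
    top = build_topology(config.gag_kind, config.n_disaccharides)
    if config.topology_path is not None:
        return read_trajectory(config.topology_path, config.trajectory_path,
                               topology=top)
    ion_model = None
    if config.n_ions > 0:
        ion_model = IonModel(mode="uniform_bulk", n_ions=config.n_ions,
                             box_edge=config.box_edge)
    spec = two_state_spec(top, n_frames=config.n_frames, seed=config.seed,
                          weights=config.state_weights,
                          concentration=config.concentration,
                          kink_shift=config.kink_shift, ion_model=ion_model)
    return sample_ensemble(spec)


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run all stages and write every artifact; returns a result bundle."""
    t0 = time.time()
    run = PipelineRun(config, outdir)
    log.info("conventions: contact<=%.2f nm, hbond<%.2f nm/%g deg, "
             "ion proximity<=%.2f nm, RMSD cutoff %.2f nm",
             config.contact_cutoff, config.hbond_dist_cutoff,
             config.hbond_angle_cutoff, config.ion_proximity_cutoff,
             config.rmsd_cutoff)
    top = build_topology(config.gag_kind, config.n_disaccharides)

    stage = "ensemble"
    try:
        traj = build_ensemble(config)
        log.info("stage %s: %d frames, %d atoms (%.1fs)", stage, traj.n_frames,
                 traj.n_atoms, time.time() - t0)

        stage = "features"
        feats = compute_feature_table(traj, top)
        if traj.state_labels is not None:
            feats["true_state"] = traj.state_labels
        run.write_csv("features.csv", feats.assign(frame=np.arange(len(feats)))
                      [["frame"] + list(feats.columns)])
        cmap = contact_probability_map(traj, top, config.contact_cutoff)
        run.write_csv("contact_map.csv", pd.DataFrame(cmap.probability))
        if traj.ion_coords is not None and traj.ion_coords.shape[1] > 0:
            bins = np.arange(0.0, min(1.2, traj.box_edge / 2), 0.02)
            rdf = radial_distribution(
                traj, [top.atom_indices(g) for g in top.carboxylate_oxygens], bins)
            run.write_csv("rdf_carboxylate.csv",
                          pd.DataFrame({"r": rdf.bin_centers, "g": rdf.g}))
        log.info("stage features done (%.1fs)", time.time() - t0)

        stage = "clustering"
        stride = max(1, traj.n_frames // config.cluster_max_frames)
        sub = Trajectory(atom_names=traj.atom_names,
                         atom_residues=traj.atom_residues,
                         residue_codes=traj.residue_codes,
                         atom_elements=traj.atom_elements,
                         coords=traj.coords[::stride],
                         box_edge=traj.box_edge, topology=traj.topology)
        M = pairwise_rmsd_matrix(sub)
        cres = daura_cluster(M, config.rmsd_cutoff)
        run.write_csv("clusters.csv", pd.DataFrame({
            "frame": np.arange(sub.n_frames) * stride,
            "cluster_id": cres.labels,
            "is_center": np.isin(np.arange(sub.n_frames), cres.centers),
        }))
        ncp = min(config.evolution_checkpoints, sub.n_frames)
        cps = np.unique(np.linspace(1, sub.n_frames, ncp).astype(int))
        evo = cluster_count_evolution(M, config.rmsd_cutoff, cps)
        run.write_csv("cluster_evolution.csv", pd.DataFrame({
            "checkpoint_frame": evo.checkpoints * stride,
            "n_clusters": evo.n_clusters,
        }))
        log.info("stage clustering: %d clusters at %.2f nm (%.1fs)",
                 cres.n_clusters, config.rmsd_cutoff, time.time() - t0)

        stage = "fes"
        fm = assemble_state_matrix(feats, standardize=config.standardize)
        proj = principal_components(fm, k_pc=2)
        fes = free_energy_surface(proj, bins=config.fes_bins,
                                  temperature=config.temperature)
        xc = 0.5 * (fes.x_edges[:-1] + fes.x_edges[1:])
        yc = 0.5 * (fes.y_edges[:-1] + fes.y_edges[1:])
        ii, jj = np.meshgrid(np.arange(len(xc)), np.arange(len(yc)), indexing="ij")
        run.write_csv("fes.csv", pd.DataFrame({
            "PC1_bin": xc[ii.ravel()], "PC2_bin": yc[jj.ravel()],
            "P": fes.probability.ravel(),
            "dG_kBT": fes.dg_kt.ravel(), "dG_kJmol": fes.dg_kjmol.ravel(),
        }))
        states = kmeans_with_elbow(proj, k_range=range(config.k_min,
                                                       config.k_max + 1),
                                   seed=config.seed, fixed_k=config.fixed_k)
        report = representative_frames(states, proj, traj, top, feats)
        run.write_csv("state_report.csv", report)
        run.write_csv("inertia.csv", pd.DataFrame({
            "k": states.k_candidates, "inertia": states.inertias}))
        run.write_json("pca.json", {
            "loadings": proj.loadings.tolist(),
            "explained_variance_ratio": proj.explained_variance_ratio.tolist(),
            "feature_columns": list(fm.columns),
            "standardized": fm.standardized,
            "selected_k": states.k,
        })
        log.info("stage fes: selected k=%d (%.1fs)", states.k, time.time() - t0)
    except Exception:
        log.error("pipeline failed in stage %r; completed outputs kept in %s",
                  stage, run.outdir)
        raise

    manifest = run.finish()
    return {
        "outdir": run.outdir,
        "manifest": manifest,
        "trajectory": traj,
        "features": feats,
        "clusters": cres,
        "projection": proj,
        "fes": fes,
        "states": states,
        "report": report,
    }
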