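"""End-to-end orchestration of the validation stages.

Each ``run_*`` function consumes a :class:`~g4validate.config.RunConfig`,
writes TSV/JSON reports into the configured output directory, and
returns the machine-readable summary it also writes to disk.  Errors
are re-raised with the stage name attached so a failing pipeline names
the stage, and no partial summary is written.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from pathlib import Path

import numpy as np

from . import clustering as clu
from . import io as gio
from . import ions as ion_mod
from . import observables as obs
from . import synthetic as synth
from .config import RunConfig
from .core import EnsembleBundle
from .topology import (StructuralAnnotation, detect_tetrads,
                       enumerate_backbone_dihedrals, enumerate_hbond_definitions,
                       parse_sequence)

log = logging.getLogger("g4validate")


class StageError(RuntimeError):
    pass


@contextmanager
def _stage(name: str):
    log.info("[%s] start", name)
    try:
        yield
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"[{name}] {exc}") from exc
    log.info("[%s] done", name)


def _outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _load_inputs(config: RunConfig):
    """Resolve (bundle, trajectory, noe_table, annotation, sequence)."""
    thr = config.thresholds
    if config.synthetic is not None:
        spec = config.synthetic
        model, ann = synth.build_system(spec)
        sigma_map = {
            f"resid 1-{4 * spec.n_tetrads}": spec.sigma_g4,
            f"resid {4 * spec.n_tetrads + 1}-{4 * spec.n_tetrads + 2 * spec.duplex_pairs}":
                spec.sigma_duplex,
            "element K": spec.sigma_ions,
        }
        traj = synth.generate_fluctuating_trajectory(
            model, sigma_map, spec.n_frames, seed=config.seed + spec.seed,
            dt=spec.dt, box_edge=spec.box_edge)
        if spec.ion_schedule:
            ion_resid = int(model.resids[model.indices("element K")[0]])
            traj = synth.inject_ion_entry(traj, ion_resid, spec.ion_schedule, ann.tetrads)
        bundle = EnsembleBundle([model])
        # restraints describe the ensemble they were measured on: derive
        # them from the trajectory frames (r^-6 averaged), as an NMR table
        # derives from the conformations present in solution
        frame_bundle = EnsembleBundle([traj.frame(f) for f in range(traj.n_frames)])
        table = synth.derive_noe_table(frame_bundle, cutoff=thr["noe_cutoff"],
                                       padding=thr["noe_padding"])
        sequence = None
        return bundle, traj, table, ann, sequence
    paths = config.inputs
    bundle = gio.read_structure_bundle(paths["bundle"])
    traj = gio.read_trajectory(bundle.topology, paths["trajectory"],
                               fmt=paths.get("trajectory_format"))
    table = gio.read_noe_table(paths["restraints"], paths["restraint_dialect"],
                               topology=bundle.topology)
    sequence, ann = (None, StructuralAnnotation())
    if paths.get("annotation"):
        from .topology import load_annotation
        sequence, ann = load_annotation(paths["annotation"])
    if not ann.tetrads:
        ann.tetrads = detect_tetrads(bundle.topology)
    return bundle, traj, table, ann, sequence


def _default_masks(config: RunConfig, ann: StructuralAnnotation) -> dict:
    masks = dict(config.masks)
    g4_res = sorted({r for q in ann.tetrads for r in q})
    if g4_res and "g4_bases" not in masks:
        lo, hi = min(g4_res), max(g4_res)
        masks["g4_bases"] = f"resid {lo}-{hi} and heavy and not name P OP1 OP2 O5' C5' C4' C3' O3' C1'"
    duplex_res = sorted({r for p in ann.duplex_pairs for r in p})
    if duplex_res and "duplex" not in masks:
        masks["duplex"] = f"resid {min(duplex_res)}-{max(duplex_res)} and heavy"
    masks.setdefault("align", "heavy and not element K")
    masks.setdefault("backbone", "name P O5' C5' C4' C3' O3'")
    return masks


def run_validation(config: RunConfig) -> dict:
    """NOE comparison and violations, H-bond statistics, dihedral
    occupancies, RMSD and RMSF reports plus a machine-readable summary."""
    out = _outdir(config)
    thr = config.thresholds
    with _stage("inputs"):
        bundle, traj, table, ann, sequence = _load_inputs(config)
        masks = _default_masks(config, ann)
    with _stage("noe"):
        comparison = obs.noe_backcalculate(traj, table, equilibration=thr["equilibration"])
        per_restraint, per_residue = obs.noe_violations(comparison, thr["noe_tolerance"])
        gio.write_report(per_restraint, out / "noe_comparison.tsv")
        gio.write_report(per_residue, out / "noe_violations_per_residue.tsv")
    with _stage("hbonds"):
        defs = enumerate_hbond_definitions(ann, sequence, include_bifurcated=False)
        hb = None
        if defs:
            hb = obs.hbond_series(traj, defs, thr["hbond_distance"], thr["hbond_angle"])
            gio.write_report(hb.to_frame(), out / "hbond_summary.tsv")
    with _stage("dihedrals"):
        n_res = int(traj.topology.resids.max())
        seq = sequence or parse_sequence("G" * n_res)
        dihedral_defs = enumerate_backbone_dihedrals(seq)
        dm = obs.dihedral_matrix(traj, dihedral_defs, bundle, thr["dihedral_bin"])
        rows = []
        for i, resid in enumerate(dm.resids):
            for j, name in enumerate(dm.names):
                if np.isnan(dm.occupancy[i, j]).all():
                    continue
                rows.append({"resid": int(resid), "dihedral": name,
                             **{f"bin_{int(e)}": v for e, v in
                                zip(dm.bin_edges[:-1], dm.occupancy[i, j])}})
        gio.write_report(rows, out / "dihedral_occupancy.tsv")
    with _stage("rmsd"):
        window = min(int(thr["rmsd_window"]), traj.n_frames)
        series = obs.rmsd_series(traj, bundle, align_mask=masks["align"],
                                 measure_mask=masks.get("g4_bases", masks["align"]),
                                 window=window)
        gio.write_report(series.to_frame(), out / "rmsd_g4.tsv")
        rmsf = obs.rmsf_profile(traj, mask=masks["align"])
        gio.write_report(rmsf.per_residue, out / "rmsf_per_residue.tsv")
    with _stage("summary"):
        summary = {
            "config_hash": config.hash(),
            "n_restraints": len(table),
            "n_violations": int(per_restraint.violated.sum()),
            "violation_tolerance": thr["noe_tolerance"],
            "violations_per_residue": {int(r.resid): int(r.violations)
                                       for r in per_residue.itertuples()},
            "n_hbond_definitions": len(defs),
            "hbond_mean_persistence": None if hb is None else float(hb.persistence.mean()),
            "rmsd_g4_final_running_avg": float(series.running[0][-1]),
            "n_frames": traj.n_frames,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return summary


def run_ions(config: RunConfig) -> dict:
    """Channel-state classification, RDF/SDF profiles and the
    occupancy-based binding free energy."""
    out = _outdir(config)
    thr = config.thresholds
    with _stage("inputs"):
        bundle, traj, _table, ann, _seq = _load_inputs(config)
        masks = _default_masks(config, ann)
        if len(ann.tetrads) < 2:
            raise ValueError("ion analysis needs at least two tetrads")
    with _stage("occupancy"):
        occ = ion_mod.classify_channel_states(
            traj, ann.tetrads, cavity_cutoff=thr["cavity_cutoff"],
            plane_halfwidth=thr["plane_halfwidth"],
            approach_cutoff=thr["approach_cutoff"])
        gio.write_report(occ.events, out / "ion_events.tsv")
        free = ion_mod.binding_free_energy(occ, temperature=config.temperature)
    with _stage("rdf"):
        rdf = ion_mod.rdf_com(traj, masks["align"], "element K",
                              bin_width=thr["rdf_bin_width"], r_max=thr["rdf_r_max"],
                              bulk_shell_radius=thr["bulk_shell_radius"])
        gio.write_report(rdf.to_frame(), out / "rdf_k.tsv")
    with _stage("sdf"):
        grid = ion_mod.sdf_grid(traj, "element K", voxel_volume=thr["voxel_volume"],
                                align_mask=masks["align"])
        grid.write_dx(out / "sdf_k.dx")
    with _stage("summary"):
        summary = {
            "config_hash": config.hash(),
            "state_fractions": occ.state_fractions(),
            "bound_fraction": free.bound_fraction,
            "delta_g_kj_mol": free.delta_g_kj_mol,
            "one_sided": free.one_sided,
            "rdf_bulk_density": None if np.isnan(rdf.bulk_density) else rdf.bulk_density,
            "n_events": len(occ.events),
        }
        with open(out / "ions_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return summary


def run_cluster(config: RunConfig) -> dict:
    """Align-on-quadruplex, cluster-on-duplex conformational families."""
    out = _outdir(config)
    thr = config.thresholds
    with _stage("inputs"):
        _bundle, traj, _table, ann, _seq = _load_inputs(config)
        masks = _default_masks(config, ann)
        if "duplex" not in masks:
            raise ValueError("clustering needs a duplex mask or duplex pairs in the annotation")
    with _stage("cluster"):
        stride = int(thr["cluster_stride"]) if traj.n_frames > 10_000 else 1
        matrix = clu.pairwise_rmsd_matrix(traj, masks.get("g4_bases", masks["align"]),
                                          masks["duplex"], stride=stride)
        n_clusters = min(int(thr["n_clusters"]), matrix.shape[0])
        solution = clu.hierarchical_cluster(matrix, n_clusters=n_clusters, stride=stride)
        reps = clu.representative_set(solution, coverage=thr["coverage"])
        gio.write_report(reps, out / "cluster_representatives.tsv")
        labels = [{"frame": int(i * stride), "cluster": int(c)}
                  for i, c in enumerate(solution.labels)]
        gio.write_report(labels, out / "cluster_labels.tsv")
    with _stage("summary"):
        summary = {
            "config_hash": config.hash(),
            "n_clusters": solution.n_clusters,
            "n_representatives_at_coverage": len(reps),
            "coverage": thr["coverage"],
            "populations": solution.populations.tolist(),
            "stride": stride,
        }
        with open(out / "cluster_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return summary


def run_synth(config: RunConfig) -> dict:
    """Write the synthetic fixtures (bundle PDB, trajectory, restraints)."""
    if config.synthetic is None:
        raise StageError("[synth] config has no synthetic section")
    out = _outdir(config)
    with _stage("synth"):
        bundle, traj, table, ann, _seq = _load_inputs(config)
        gio.write_structure_bundle(bundle, out / "reference.pdb")
        gio.write_trajectory(traj, out / "trajectory.dcd")
        gio.write_noe_table(table, out / "restraints.tsv")
        from .topology import save_annotation
        save_annotation(None, ann, out / "annotation.yaml")
    return {"config_hash": config.hash(), "n_atoms": bundle.topology.n_atoms,
            "n_frames": traj.n_frames, "n_restraints": len(table)}


def run_manifest(config: RunConfig) -> dict:
    """Study manifest: systems × replicates × lengths with totals."""
    rows = []
    total = 0.0
    n_runs = 0
    for entry in config.manifest:
        reps = int(entry.get("replicates", 1))
        length = float(entry.get("length_us", 0.0))
        subtotal = reps * length
        total += subtotal
        n_runs += reps
        rows.append({"system": entry["name"], "replicates": reps,
                     "length_us": length, "subtotal_us": subtotal})
    manifest = {
        "config_hash": config.hash(),
        "systems": rows,
        "n_systems": len(rows),
        "n_runs": n_runs,
        "total_us": total,
    }
    out = _outdir(config)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def run_all(config: RunConfig) -> dict:
    results = {"validation": run_validation(config)}
    if config.synthetic is None or config.synthetic.channel_ions >= 1:
        results["ions"] = run_ions(config)
    results["cluster"] = run_cluster(config)
    if config.manifest:
        results["manifest"] = run_manifest(config)
    return results
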