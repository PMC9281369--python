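"""Structural observables: RMSD splits, RMSF, NOE back-calculation,
hydrogen-bond statistics and backbone-torsion occupancy matrices.

Ensemble-averaged interproton distances use the r⁻⁶ convention,
d = ⟨r⁻⁶⟩^(−1/6), pooling all equilibrated frames and all inter-group
proton pairs before the −1/6 power; averaging (not summing) over
equivalent protons keeps the identity d = r for a constant distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from MDAnalysis.lib.distances import calc_angles, calc_dihedrals

from .core import EnsembleBundle, NOETable, StructureModel, TrajectorySet
from .topology import DIHEDRAL_NAMES, DihedralDefinition, HBondDefinition

# ---------------------------------------------------------------------------
# superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimizing
    ||R·mobile + t − reference||; reflections are excluded."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if weights is None:
        weights = np.ones(len(mobile))
    w = weights / weights.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    h = (w[:, None] * (mobile - mc)).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, rc - rot @ mc


def superpose(mobile: np.ndarray, reference: np.ndarray,
              mask=None) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Least-squares superposition; returns ((R, t), RMSD over the mask).

    The mask must select at least three non-collinear atoms.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mask is None:
        sel_m, sel_r = mobile, reference
    else:
        idx = np.asarray(mask)
        idx = np.flatnonzero(idx) if idx.dtype == bool else idx
        sel_m, sel_r = mobile[idx], reference[idx]
    if len(sel_m) < 3:
        raise ValueError("superposition mask selects fewer than 3 atoms")
    centered = sel_m - sel_m.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("superposition mask selects collinear atoms")
    rot, t = kabsch(sel_m, sel_r)
    moved = sel_m @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - sel_r) ** 2, axis=1))))
    return (rot, t), rmsd


def _rmsd_after_fit(frame: np.ndarray, ref: np.ndarray,
                    align_idx: np.ndarray, measure_idx: np.ndarray) -> float:
    (rot, t), _ = superpose(frame, ref, align_idx)
    moved = frame[measure_idx] @ rot.T + t
    return float(np.sqrt(np.mean(np.sum((moved - ref[measure_idx]) ** 2, axis=1))))


def running_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge-shrunk windows (output length
    equals input length)."""
    return (pd.Series(np.asarray(series, float))
            .rolling(window, center=True, min_periods=1).mean().to_numpy())


def _map_reference_indices(traj_top: StructureModel, ref: StructureModel,
                           idx: np.ndarray) -> np.ndarray:
    """Map atom indices of the trajectory topology onto a reference model
    by (residue, atom-name) identity."""
    if ref.atom_signature() == traj_top.atom_signature():
        return idx
    return np.array([ref.atom_index(int(traj_top.resids[i]), str(traj_top.names[i]))
                     for i in idx])


@dataclass
class RMSDSeries:
    values: np.ndarray          # (n_references, n_frames), Å
    labels: list
    times: np.ndarray
    window: int | None = None
    running: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.T, columns=self.labels)
        df.insert(0, "time_ps", self.times)
        return df


def rmsd_series(traj: TrajectorySet, references, align_mask="heavy",
                measure_mask=None, window: int | None = None) -> RMSDSeries:
    """Per-frame RMSD against each reference model after superposition.

    Alignment and measurement masks may differ (e.g. align on all heavy
    atoms, measure on quadruplex bases).  ``window`` adds a centered,
    edge-shrunk running average.
    """
    if isinstance(references, StructureModel):
        references = EnsembleBundle([references])
    top = traj.topology
    align_idx = top.indices(align_mask)
    measure_idx = top.indices(measure_mask) if measure_mask is not None else align_idx
    if len(align_idx) == 0 or len(measure_idx) == 0:
        raise ValueError("empty mask")
    values = np.empty((len(references), traj.n_frames))
    for r, ref in enumerate(references):
        a_idx = _map_reference_indices(top, ref, align_idx)
        m_idx = _map_reference_indices(top, ref, measure_idx)
        ref_xyz = ref.xyz
        for f in range(traj.n_frames):
            frame = traj.coordinates[f]
            (rot, t), _ = superpose(frame[align_idx], ref_xyz[a_idx])
            moved = frame[measure_idx] @ rot.T + t
            values[r, f] = np.sqrt(np.mean(np.sum((moved - ref_xyz[m_idx]) ** 2, axis=1)))
    running = None
    if window is not None:
        running = np.vstack([running_average(v, window) for v in values])
    return RMSDSeries(values, list(references.labels), traj.times.copy(), window, running)


@dataclass
class RMSFProfile:
    atom_indices: np.ndarray
    per_atom: np.ndarray       # Å
    per_residue: pd.DataFrame  # columns: resid, rmsf

    def residue_value(self, resid: int) -> float:
        row = self.per_residue[self.per_residue.resid == resid]
        if row.empty:
            raise KeyError(f"residue {resid} not in profile")
        return float(row.rmsf.iloc[0])


def rmsf_profile(traj: TrajectorySet, mask="heavy") -> RMSFProfile:
    """Atomic fluctuation about the average structure (frames superposed
    to the mean, mean recomputed once), averaged per residue."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    top = traj.topology
    idx = top.indices(mask)
    if len(idx) == 0:
        raise ValueError("empty mask")
    coords = traj.coordinates[:, idx]
    mean = coords.mean(axis=0)
    aligned = np.empty_like(coords)
    for f in range(len(coords)):
        (rot, t), _ = superpose(coords[f], mean)
        aligned[f] = coords[f] @ rot.T + t
    mean = aligned.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    resids = top.resids[idx]
    df = (pd.DataFrame({"resid": resids, "rmsf": per_atom})
          .groupby("resid", as_index=False).mean())
    return RMSFProfile(idx, per_atom, df)


# ---------------------------------------------------------------------------
# equilibration predicates


def equilibrated_frames(traj: TrajectorySet, equilibration=0.1,
                        plateau_tolerance: float = 0.5,
                        window: int = 1000) -> np.ndarray:
    """Boolean mask of equilibrated frames.

    ``equilibration`` may be a fraction to discard from the start
    (default 10%), the string ``"plateau"`` (first frame after which the
    all-atom RMSD running average stays within ``plateau_tolerance`` Å
    of its final value), or a boolean-array-returning callable.
    """
    n = traj.n_frames
    if callable(equilibration):
        mask = np.asarray(equilibration(traj), dtype=bool)
        if mask.shape != (n,):
            raise ValueError("equilibration callable must return one flag per frame")
        return mask
    if equilibration == "plateau":
        series = rmsd_series(traj, traj.topology, align_mask="all",
                             window=min(window, n)).running[0]
        final = series[-1]
        mask = np.zeros(n, dtype=bool)
        ok = np.abs(series - final) <= plateau_tolerance
        start = n - 1
        for f in range(n - 1, -1, -1):
            if not ok[f]:
                break
            start = f
        mask[start:] = True
        return mask
    frac = float(equilibration)
    if not 0 <= frac < 1:
        raise ValueError("equilibration fraction must be in [0, 1)")
    mask = np.zeros(n, dtype=bool)
    mask[int(np.floor(frac * n)):] = True
    return mask


# ---------------------------------------------------------------------------
# NOE back-calculation


@dataclass
class NOEComparison:
    table: NOETable
    frame: pd.DataFrame  # id, resid_a, resid_b, distance, lower, upper, excess

    def __len__(self):
        return len(self.frame)


def noe_backcalculate(traj: TrajectorySet, table: NOETable,
                      equilibration=0.1) -> NOEComparison:
    """Back-calculate every restraint as ⟨r⁻⁶⟩^(−1/6) over equilibrated
    frames and all inter-group proton pairs."""
    top = traj.topology
    missing = []
    for r in table:
        for resid, name in list(r.group_a) + list(r.group_b):
            if not top.has_atom(resid, name):
                missing.append(f"{resid}:{name}")
    if missing:
        raise ValueError("unresolvable restraint atoms: " + ", ".join(sorted(set(missing))))
    mask = equilibrated_frames(traj, equilibration)
    if not mask.any():
        raise ValueError("zero equilibrated frames")
    coords = traj.coordinates[mask]
    rows = []
    for r in table:
        ia = [top.atom_index(*m) for m in r.group_a]
        ib = [top.atom_index(*m) for m in r.group_b]
        diff = coords[:, ia, None, :] - coords[:, None, ib, :]
        rm6 = np.sum(diff ** 2, axis=-1) ** -3.0
        d = float(np.mean(rm6) ** (-1.0 / 6.0))
        excess = max(0.0, r.lower - d, d - r.upper)
        rows.append({"id": r.id, "resid_a": r.residues[0], "resid_b": r.residues[1],
                     "distance": d, "lower": r.lower, "upper": r.upper, "excess": excess})
    return NOEComparison(table, pd.DataFrame(
        rows, columns=["id", "resid_a", "resid_b", "distance", "lower", "upper", "excess"]))


def noe_violations(comparison: NOEComparison, tolerance: float = 1.0):
    """Flag violations (bound exceeded by more than ``tolerance`` Å) and
    attribute each once to both participating residues.

    Returns ``(per_restraint, per_residue)`` DataFrames.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    per = comparison.frame.copy()
    per["violated"] = per["excess"] > tolerance
    viol = per[per.violated]
    counts: dict = {}
    for _, row in viol.iterrows():
        for resid in {int(row.resid_a), int(row.resid_b)}:
            counts[resid] = counts.get(resid, 0) + 1
    per_res = pd.DataFrame(
        sorted(counts.items()), columns=["resid", "violations"], dtype=int)
    return per, per_res


# ---------------------------------------------------------------------------
# hydrogen bonds


@dataclass
class HBondSeries:
    definitions: list
    distances: np.ndarray    # (n_defs, n_frames), donor–acceptor Å
    angles: np.ndarray       # (n_defs, n_frames), donor–H–acceptor deg
    formed: np.ndarray       # bool
    persistence: np.ndarray  # (n_defs,)
    distance_cutoff: float
    angle_cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": [d.label for d in self.definitions],
            "bond_class": [d.bond_class for d in self.definitions],
            "mean_distance": self.distances.mean(axis=1),
            "mean_angle": self.angles.mean(axis=1),
            "persistence": self.persistence,
        })


def hbond_series(traj: TrajectorySet, definitions: list,
                 distance_cutoff: float = 3.0,
                 angle_cutoff: float = 135.0) -> HBondSeries:
    """Donor–acceptor distances and donor–H–acceptor angles per frame.

    A bond is formed when distance ≤ cutoff and angle ≥ cutoff; the
    persistence is the formed fraction of frames.  Amino donors carry
    two candidate protons; the most linear one counts in each frame.
    """
    top = traj.topology
    n_defs, n_frames = len(definitions), traj.n_frames
    distances = np.empty((n_defs, n_frames))
    angles = np.empty((n_defs, n_frames))
    for k, d in enumerate(definitions):
        di = top.atom_index(*d.donor)
        ai = top.atom_index(*d.acceptor)
        hcands = [h for h in d.hydrogen if top.has_atom(d.donor[0], h)]
        if not hcands:
            raise ValueError(f"no hydrogen among {d.hydrogen} on residue {d.donor[0]}")
        dp = traj.coordinates[:, di]
        ap = traj.coordinates[:, ai]
        distances[k] = np.linalg.norm(dp - ap, axis=1)
        best = np.full(n_frames, -np.inf)
        for h in hcands:
            hp = traj.coordinates[:, top.atom_index(d.donor[0], h)]
            ang = np.degrees(calc_angles(dp, hp, ap))
            best = np.maximum(best, ang)
        angles[k] = best
    formed = (distances <= distance_cutoff) & (angles >= angle_cutoff)
    return HBondSeries(list(definitions), distances, angles, formed,
                       formed.mean(axis=1), distance_cutoff, angle_cutoff)


# ---------------------------------------------------------------------------
# backbone torsions


@dataclass
class DihedralMatrix:
    resids: np.ndarray
    names: tuple
    occupancy: np.ndarray    # (n_res, 6, n_bins), normalized; NaN if undefined
    overlay: np.ndarray | None  # (n_res, 6, n_models) torsions of the bundle
    bin_edges: np.ndarray

    def histogram(self, resid: int, name: str) -> np.ndarray:
        i = int(np.flatnonzero(self.resids == resid)[0])
        return self.occupancy[i, self.names.index(name)]


def _torsion_values(coords: np.ndarray, top: StructureModel,
                    definition: DihedralDefinition) -> np.ndarray | None:
    if not definition.defined:
        return None
    try:
        idx = [top.atom_index(*a) for a in definition.atoms]
    except KeyError:
        return None
    p = [coords[:, i] for i in idx]
    return np.degrees(calc_dihedrals(*p))


def dihedral_matrix(traj: TrajectorySet, definitions: list,
                    bundle: EnsembleBundle | None = None,
                    bin_width: float = 15.0) -> DihedralMatrix:
    """Normalized torsion occupancy per (residue, angle) with 15° bins
    over [−180°, 180°), plus per-model reference values as an overlay.

    (Residue, angle) combinations whose atoms are missing are marked
    undefined (NaN), never zero-filled.
    """
    n_bins = int(round(360.0 / bin_width))
    if abs(n_bins * bin_width - 360.0) > 1e-9:
        raise ValueError("bin width must divide 360°")
    edges = -180.0 + bin_width * np.arange(n_bins + 1)
    resids = np.array(sorted({d.resid for d in definitions}))
    occ = np.full((len(resids), len(DIHEDRAL_NAMES), n_bins), np.nan)
    overlay = None
    if bundle is not None:
        overlay = np.full((len(resids), len(DIHEDRAL_NAMES), len(bundle)), np.nan)
    row = {r: i for i, r in enumerate(resids)}
    for d in definitions:
        vals = _torsion_values(traj.coordinates, traj.topology, d)
        if vals is None:
            continue
        i, j = row[d.resid], DIHEDRAL_NAMES.index(d.name)
        # reduce to principal value, left-closed bins
        princ = ((vals + 180.0) % 360.0) - 180.0
        hist, _ = np.histogram(princ, bins=edges)
        occ[i, j] = hist / hist.sum()
        if bundle is not None:
            bvals = _torsion_values(bundle.coordinates(), bundle.topology, d)
            if bvals is not None:
                overlay[i, j] = ((bvals + 180.0) % 360.0) - 180.0
    return DihedralMatrix(resids, DIHEDRAL_NAMES, occ, overlay, edges)
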