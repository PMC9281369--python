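"""Synthetic structures, trajectories and restraint tables with known truth.

The generator emulates the three inputs a quadruplex validation study
consumes — a multi-model reference structure, MD trajectories, and an
NOE restraint table — while keeping the ground truth (tetrad
composition, per-group fluctuation amplitudes, scripted ion states,
restraint padding) available for self-consistency checks.

Bases use the standard planar reference-frame geometry with the minimal
atom set downstream analyses touch (Hoogsteen/Watson–Crick donors and
acceptors, glycosidic C1', a schematic sugar–phosphate chain, and named
protons).  Tetrad and Watson–Crick placements are solved numerically at
import time so that every monitored hydrogen bond of the ideal
structures falls in the 2.8–3.0 Å donor–acceptor band with near-linear
donor–H–acceptor geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .core import NOERestraint, NOETable, StructureModel, TrajectorySet, element_from_name

# planar reference-frame coordinates (Å) of the heavy base atoms
_GUANINE_2D = {
    "C1'": (-2.477, 5.399), "N9": (-1.289, 4.551), "C8": (0.023, 4.962),
    "N7": (0.870, 3.969), "C5": (0.071, 2.833), "C6": (0.424, 1.460),
    "O6": (1.554, 0.955), "N1": (-0.700, 0.641), "C2": (-1.999, 1.087),
    "N2": (-2.949, 0.139), "N3": (-2.342, 2.364), "C4": (-1.265, 3.177),
}
_CYTOSINE_2D = {
    "C1'": (-2.477, 5.402), "N1": (-1.285, 4.542), "C2": (-1.472, 3.158),
    "O2": (-2.628, 2.709), "N3": (-0.391, 2.344), "C4": (0.837, 2.868),
    "N4": (1.875, 2.027), "C5": (1.056, 4.275), "C6": (-0.023, 5.068),
}

# schematic sugar-phosphate chain: (name, offset from the previous atom)
# purely geometric scaffolding so that backbone masks and the six
# torsions are computable on synthetic systems
_BACKBONE_CHAIN = [
    ("C4'", "C1'", (-1.30, 0.70, 0.80)),
    ("C5'", "C4'", (-0.90, -0.60, 1.00)),
    ("O5'", "C5'", (-0.60, -1.00, 0.60)),
    ("P", "O5'", (-0.80, -0.90, 0.80)),
    ("OP1", "P", (-1.20, 0.40, 0.50)),
    ("OP2", "P", (0.30, -1.00, 1.00)),
    ("C3'", "C4'", (0.20, 1.40, 0.70)),
    ("O3'", "C3'", (-0.30, 1.20, -0.30)),
]

_NH_BOND = 1.01
_CH_BOND = 1.09

CHANNEL_STATES = ("bulk", "approach", "in-plane", "cavity")


def _rot2(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def _base_2d(base: str) -> dict:
    """Heavy atoms plus in-plane hydrogens of one base, reference frame."""
    heavy = dict(_GUANINE_2D if base == "G" else _CYTOSINE_2D)
    pts = {k: np.asarray(v, float) for k, v in heavy.items()}

    def lone_h(name, on, neighbors, bond):
        d = pts[on] - np.mean([pts[x] for x in neighbors], axis=0)
        pts[name] = pts[on] + bond * d / np.linalg.norm(d)

    def amino_h(n1, n2, on, stem):
        v = pts[on] - pts[stem]
        v /= np.linalg.norm(v)
        pts[n1] = pts[on] + _NH_BOND * (_rot2(np.deg2rad(60)) @ v)
        pts[n2] = pts[on] + _NH_BOND * (_rot2(np.deg2rad(-60)) @ v)

    if base == "G":
        lone_h("H1", "N1", ["C2", "C6"], _NH_BOND)
        lone_h("H8", "C8", ["N7", "N9"], _CH_BOND)
        amino_h("H21", "H22", "N2", "C2")
    else:
        lone_h("H5", "C5", ["C4", "C6"], _CH_BOND)
        lone_h("H6", "C6", ["C5", "N1"], _CH_BOND)
        amino_h("H41", "H42", "N4", "C4")
    return pts


def _residue_atoms(base: str, planar: np.ndarray | None = None) -> tuple[list, np.ndarray]:
    """3D atom list of one residue in its base frame (plane z=0)."""
    pts2d = _base_2d(base) if planar is None else planar
    names, coords = [], []
    for name, xy in pts2d.items():
        names.append(name)
        coords.append([xy[0], xy[1], 0.0])
    index = {n: i for i, n in enumerate(names)}
    coords = np.array(coords)
    # sugar proton, displaced out of plane
    names.append("H1'")
    coords = np.vstack([coords, coords[index["C1'"]] + [0.0, 0.35, 1.03]])
    for name, parent, off in _BACKBONE_CHAIN:
        names.append(name)
        coords = np.vstack([coords, coords[names.index(parent)] + np.asarray(off)])
    return names, coords


@lru_cache(maxsize=1)
def _tetrad_placement() -> tuple[float, float]:
    """Radius and orientation placing four guanines in cyclic Hoogsteen closure.

    Solved once: both Hoogsteen donor–acceptor distances hit 2.9 Å exactly
    on the sterically open branch (O6 ring facing the channel axis).
    """
    xy = np.array([_GUANINE_2D[n] for n in _GUANINE_2D])
    names = list(_GUANINE_2D)
    i_n1, i_n2, i_o6, i_n7 = (names.index(a) for a in ("N1", "N2", "O6", "N7"))

    def resid(p):
        r, phi = p
        placed = [xy @ _rot2(phi).T + [r, 0.0]]
        placed = [placed[0] @ _rot2(g * np.pi / 2).T for g in range(4)]
        out = []
        for g in range(4):
            a, b = placed[g], placed[(g + 1) % 4]
            out.append(np.linalg.norm(a[i_n1] - b[i_o6]) - 2.9)
            out.append(np.linalg.norm(a[i_n2] - b[i_n7]) - 2.9)
        return out

    sol = least_squares(resid, [2.72, -2.70])
    if sol.cost > 1e-10:
        raise RuntimeError("tetrad placement failed to converge")
    return float(sol.x[0]), float(sol.x[1])


@lru_cache(maxsize=1)
def _wc_placement() -> tuple[float, float, float]:
    """In-plane rigid transform of a (mirrored) cytosine forming a G·C pair.

    Soft-band fit: all three Watson–Crick donor–acceptor distances
    constrained into [2.82, 2.98] Å, starting from the standard-frame flip.
    """
    gxy = {k: np.asarray(v) for k, v in _GUANINE_2D.items()}
    cxy = np.array([_CYTOSINE_2D[n] for n in _CYTOSINE_2D])
    cn = list(_CYTOSINE_2D)

    def dists(p):
        c = (cxy * [1, -1]) @ _rot2(p[2]).T + p[:2]
        at = {n: c[i] for i, n in enumerate(cn)}
        return [np.linalg.norm(gxy["O6"] - at["N4"]),
                np.linalg.norm(gxy["N1"] - at["N3"]),
                np.linalg.norm(gxy["N2"] - at["O2"])]

    def resid(p):
        r = [max(0.0, d - 2.98) + min(0.0, d - 2.82) for d in dists(p)]
        return r + [0.01 * v for v in p]

    sol = least_squares(resid, [0.0, 0.0, 0.0])
    d = dists(sol.x)
    if not all(2.8 < x < 3.0 for x in d):
        raise RuntimeError(f"Watson-Crick placement out of band: {d}")
    return tuple(float(v) for v in sol.x)


def _paired_cytosine_2d() -> dict:
    """Cytosine base-frame coords placed against a standard-frame guanine."""
    tx, ty, th = _wc_placement()
    out = {}
    for name, xy in _base_2d("C").items():
        v = np.asarray(xy) * [1, -1]
        out[name] = _rot2(th) @ v + [tx, ty]
    return out


def _assemble(records: list) -> StructureModel:
    names = [r[0] for r in records]
    resids = [r[1] for r in records]
    resnames = [r[2] for r in records]
    xyz = [r[3] for r in records]
    elements = [element_from_name(n) if r[2] not in ("K",) else "K"
                for n, r in zip(names, records)]
    return StructureModel(np.array(names, dtype=object), np.array(resids),
                          np.array(resnames, dtype=object),
                          np.array(elements, dtype=object), np.array(xyz))


def build_ideal_g4(n_tetrads: int = 3, rise: float = 3.4, twist: float = 30.0,
                   channel_ions: int = 0) -> StructureModel:
    """Idealized parallel G4 stack: ``n_tetrads`` quartets plus channel cations.

    Residues are numbered per tetrad bottom-to-top, in cyclic Hoogsteen
    donor order within each quartet (tetrad k holds residues 4k+1…4k+4).
    Channel ions sit on the axis, exactly midway between adjacent tetrad
    O6-centroid planes, filling slots from the bottom.
    """
    if n_tetrads < 1:
        raise ValueError("need at least one tetrad")
    if channel_ions > n_tetrads - 1:
        raise ValueError(
            f"{channel_ions} channel ions exceed the {n_tetrads - 1} inter-plane slots")
    r0, phi0 = _tetrad_placement()
    names, local = _residue_atoms("G")
    records = []
    o6_z = []
    for k in range(n_tetrads):
        a_stack = _rot2(np.deg2rad(twist * k))
        z0 = rise * k
        o6_z.append(z0)
        for g in range(4):
            resid = 4 * k + g + 1
            # orient the base frame, shift to the tetrad radius, C4-rotate
            for name, xyz in zip(names, local):
                xy = a_stack @ _rot2(g * np.pi / 2) @ (_rot2(phi0) @ xyz[:2] + [r0, 0.0])
                records.append((name, resid, "DG", np.array([xy[0], xy[1], z0 + xyz[2]])))
    next_resid = 4 * n_tetrads + 1
    for slot in range(channel_ions):
        z = 0.5 * (o6_z[slot] + o6_z[slot + 1])
        records.append(("K", next_resid, "K", np.array([0.0, 0.0, z])))
        next_resid += 1
    return _assemble(records)


def build_duplex_stem(n_pairs: int, rise: float = 3.4, twist: float = 36.0) -> StructureModel:
    """B-form-like G·C stem; strand 1 is all G (residues 1…n), strand 2 all C.

    Pair i pairs residue i with residue 2n+1−i, every Watson–Crick
    donor–acceptor distance in the 2.8–3.0 Å band by construction.
    """
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    g_names, g_local = _residue_atoms("G")
    c_names, c_local = _residue_atoms("C", planar=_paired_cytosine_2d())
    records = []
    for i in range(n_pairs):
        a = _rot2(np.deg2rad(twist * i))
        z0 = rise * i
        for name, xyz in zip(g_names, g_local):
            xy = a @ xyz[:2]
            records.append((name, i + 1, "DG", np.array([xy[0], xy[1], z0 + xyz[2]])))
        for name, xyz in zip(c_names, c_local):
            xy = a @ xyz[:2]
            records.append((name, 2 * n_pairs - i, "DC", np.array([xy[0], xy[1], z0 - xyz[2]])))
    records.sort(key=lambda r: r[1])
    return _assemble(records)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic quadruplex–duplex system.

    Defaults emulate the validation study's setting: a rigid three-tetrad
    core with two channel cations, a three-pair duplex stem that
    fluctuates about twice as much as the core, and frames spaced 10 ps.
    """

    n_tetrads: int = 3
    rise: float = 3.4
    twist: float = 30.0
    duplex_pairs: int = 3
    channel_ions: int = 2
    sigma_g4: float = 0.3       # per-coordinate Gaussian amplitude, Å
    sigma_duplex: float = 0.6
    sigma_ions: float = 0.05
    n_frames: int = 500
    dt: float = 10.0            # ps
    box_edge: float = 80.0      # cubic periodic box, Å
    ion_schedule: list = field(default_factory=list)  # [(frame, state), ...]
    seed: int = 0

    def __post_init__(self):
        for sig in (self.sigma_g4, self.sigma_duplex, self.sigma_ions):
            if sig < 0:
                raise ValueError("fluctuation amplitude must be non-negative")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        for f, state in self.ion_schedule:
            if not 0 <= f < self.n_frames:
                raise ValueError(f"schedule frame {f} outside 0..{self.n_frames - 1}")
            if state not in CHANNEL_STATES:
                raise ValueError(f"unknown channel state {state!r}")


def build_system(spec: SyntheticSpec):
    """G4 core + duplex stem + channel ions in one model.

    Returns ``(model, annotation)`` where the annotation records the
    ground-truth tetrads and duplex pairs.
    """
    from .topology import StructuralAnnotation

    g4 = build_ideal_g4(spec.n_tetrads, spec.rise, spec.twist, spec.channel_ions)
    n_g4_res = 4 * spec.n_tetrads
    records = []
    ion_records = []
    for i in range(g4.n_atoms):
        rec = (g4.names[i], int(g4.resids[i]), g4.resnames[i], g4.xyz[i].copy())
        (ion_records if g4.resnames[i] == "K" else records).append(rec)
    duplex = build_duplex_stem(spec.duplex_pairs, spec.rise)
    z_shift = spec.rise * (spec.n_tetrads - 1) + 6.0
    for i in range(duplex.n_atoms):
        xyz = duplex.xyz[i] + [0.0, 0.0, z_shift]
        records.append((duplex.names[i], int(duplex.resids[i]) + n_g4_res,
                        duplex.resnames[i], xyz))
    n_res = n_g4_res + 2 * spec.duplex_pairs
    for j, rec in enumerate(ion_records):
        records.append((rec[0], n_res + j + 1, rec[2], rec[3]))
    model = _assemble(records)
    ann = StructuralAnnotation(
        tetrads=[[4 * k + g + 1 for g in range(4)] for k in range(spec.n_tetrads)],
        duplex_pairs=[(n_g4_res + i + 1, n_g4_res + 2 * spec.duplex_pairs - i)
                      for i in range(spec.duplex_pairs)],
    )
    return model, ann


def generate_fluctuating_trajectory(reference: StructureModel, sigma_map: dict,
                                    n_frames: int, seed: int, dt: float = 10.0,
                                    box_edge: float | None = None) -> TrajectorySet:
    """Frames = reference + isotropic Gaussian noise with per-group amplitude.

    ``sigma_map`` maps selection strings to per-coordinate σ (Å); every
    atom must fall in exactly one group.  Deterministic in ``seed``.
    """
    cover = np.zeros(reference.n_atoms, dtype=int)
    sigma = np.zeros(reference.n_atoms)
    for sel, sig in sigma_map.items():
        if sig < 0:
            raise ValueError(f"negative sigma for group {sel!r}")
        m = reference.mask(sel)
        cover += m
        sigma[m] = sig
    if np.any(cover == 0):
        missing = np.flatnonzero(cover == 0)[:5]
        raise ValueError(f"atoms not assigned to any sigma group (first indices: {missing.tolist()})")
    if np.any(cover > 1):
        raise ValueError("sigma groups overlap")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_frames, reference.n_atoms, 3)) * sigma[None, :, None]
    coords = reference.xyz[None] + noise
    times = dt * np.arange(n_frames, dtype=float)
    box = None
    if box_edge is not None:
        box = np.tile([box_edge, box_edge, box_edge, 90.0, 90.0, 90.0], (n_frames, 1))
    return TrajectorySet(reference, coords, times, box)


def _channel_anchors(frame_xyz: np.ndarray, o6_groups: list) -> dict:
    """Geometric anchors of the four channel states for one frame.

    ``o6_groups`` lists, per tetrad bottom-to-top, the atom indices of
    the four O6 oxygens.
    """
    cents = np.array([frame_xyz[idx].mean(axis=0) for idx in o6_groups])
    axis = cents[-1] - cents[0]
    axis = axis / np.linalg.norm(axis)
    perp = np.array([1.0, 0.0, 0.0])
    perp = perp - (perp @ axis) * axis
    if np.linalg.norm(perp) < 1e-6:
        perp = np.array([0.0, 1.0, 0.0])
        perp = perp - (perp @ axis) * axis
    perp /= np.linalg.norm(perp)
    return {
        "bulk": cents[-1] + 5.0 * axis + 20.0 * perp,
        "approach": cents[-1] + 3.0 * axis,
        "in-plane": cents[-1],
        "cavity": 0.5 * (cents[-1] + cents[-2]),
        "_centroids": cents,
        "_axis": axis,
    }


def schedule_to_states(schedule: list, n_frames: int) -> list:
    """Expand [(frame, state), ...] into one state per frame (None before
    the first scheduled frame)."""
    states = [None] * n_frames
    ordered = sorted(schedule)
    for idx, (f, state) in enumerate(ordered):
        stop = ordered[idx + 1][0] if idx + 1 < len(ordered) else n_frames
        for k in range(f, stop):
            states[k] = state
    return states


def inject_ion_entry(traj: TrajectorySet, ion_resid: int, schedule: list,
                     tetrads: list) -> TrajectorySet:
    """Rewrite one ion's coordinates to follow a scripted channel-state path.

    The schedule is a list of (frame, state) switch points; each state
    holds until the next switch.  Anchors are recomputed per frame from
    that frame's tetrad O6 positions, so a downstream state classifier
    recovers the schedule exactly.
    """
    if len(tetrads) < 2:
        raise ValueError("need at least two tetrads for channel anchors")
    for f, state in schedule:
        if not 0 <= f < traj.n_frames:
            raise ValueError(f"schedule frame {f} outside trajectory (0..{traj.n_frames - 1})")
        if state not in CHANNEL_STATES:
            raise ValueError(f"unknown channel state {state!r}")
    ion_idx = traj.topology.indices(f"resid {ion_resid}")
    if len(ion_idx) != 1:
        raise ValueError(f"residue {ion_resid} does not resolve to a single ion atom")
    ion_idx = int(ion_idx[0])
    o6_groups = [[traj.topology.atom_index(r, "O6") for r in quartet] for quartet in tetrads]
    coords = traj.coordinates.copy()
    states = schedule_to_states(schedule, traj.n_frames)
    for f, state in enumerate(states):
        if state is None:
            continue
        anchors = _channel_anchors(coords[f], o6_groups)
        coords[f, ion_idx] = anchors[state]
    return TrajectorySet(traj.topology, coords, traj.times.copy(),
                         None if traj.box is None else traj.box.copy())


def derive_noe_table(reference, cutoff: float = 5.0, padding: float = 0.5) -> NOETable:
    """Restraints for every proton pair within ``cutoff`` in the reference.

    For a single model the target is the observed distance; for a bundle
    it is the r⁻⁶ average over models, with the pair kept if it is
    within the cutoff in any model.  Bounds are target ∓ padding (lower
    clipped at zero).
    """
    if padding < 0:
        raise ValueError("padding must be non-negative")
    from .core import EnsembleBundle

    if isinstance(reference, EnsembleBundle):
        top = reference.topology
        stacks = reference.coordinates()
    else:
        top = reference
        stacks = reference.xyz[None]
    h_idx = np.flatnonzero(np.char.upper(top.elements.astype(str)) == "H")
    restraints = []
    count = 0
    for ai in range(len(h_idx)):
        for bi in range(ai + 1, len(h_idx)):
            i, j = h_idx[ai], h_idx[bi]
            d = np.linalg.norm(stacks[:, i] - stacks[:, j], axis=1)
            if d.min() > cutoff:
                continue
            target = float(np.mean(d ** -6.0) ** (-1.0 / 6.0))
            count += 1
            restraints.append(NOERestraint(
                id=f"noe-{count:04d}",
                group_a=[(int(top.resids[i]), str(top.names[i]))],
                group_b=[(int(top.resids[j]), str(top.names[j]))],
                lower=max(0.0, target - padding),
                upper=target + padding,
                target=target,
            ))
    return NOETable(restraints)
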