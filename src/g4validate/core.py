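"""Core in-memory containers shared by every analysis stage.

Coordinates are in Å and times in ps throughout; residue indices are
1-based (matching PDB depositions and the G1…G28 naming convention for
quadruplex sequences); frame indices are 0-based with half-open ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .selection import select

# minimal masses (amu) for the elements this pipeline touches
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "K": 39.098, "NA": 22.990, "CL": 35.453, "MG": 24.305,
}


def element_from_name(name: str) -> str:
    """Guess an element symbol from a PDB-style atom name."""
    stripped = name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():  # e.g. 1H5'
        stripped = stripped.lstrip("0123456789")
    if stripped[:2].upper() in ("CL", "NA", "MG", "BR"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


@dataclass
class StructureModel:
    """A single conformation: parallel arrays of atom attributes."""

    names: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    elements: np.ndarray
    xyz: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.names = np.asarray(self.names, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        n = len(self.names)
        if not (len(self.resids) == len(self.resnames) == len(self.elements) == len(self.xyz) == n):
            raise ValueError("atom attribute arrays have inconsistent lengths")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")
        keys = list(zip(self.resids.tolist(), self.names.tolist()))
        if len(set(keys)) != n:
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate (residue, atom name) pair {dup}")
        self._index = {k: i for i, k in enumerate(keys)}

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def residue_ids(self) -> np.ndarray:
        """Unique residue indices in order of first appearance."""
        _, first = np.unique(self.resids, return_index=True)
        return self.resids[np.sort(first)]

    def atom_index(self, resid: int, name: str) -> int:
        try:
            return self._index[(resid, name)]
        except KeyError:
            raise KeyError(f"no atom {name!r} in residue {resid}") from None

    def has_atom(self, resid: int, name: str) -> bool:
        return (resid, name) in self._index

    def mask(self, selection) -> np.ndarray:
        """Boolean mask from a selection string, boolean array or index array."""
        if isinstance(selection, str):
            return select(self, selection)
        arr = np.asarray(selection)
        if arr.dtype == bool:
            if arr.shape != (self.n_atoms,):
                raise ValueError("boolean mask has wrong length")
            return arr
        mask = np.zeros(self.n_atoms, dtype=bool)
        mask[arr] = True
        return mask

    def indices(self, selection) -> np.ndarray:
        return np.flatnonzero(self.mask(selection))

    def subset(self, selection) -> "StructureModel":
        m = self.mask(selection)
        return StructureModel(self.names[m], self.resids[m], self.resnames[m],
                              self.elements[m], self.xyz[m], label=self.label)

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(str(e).upper(), 12.0) for e in self.elements])

    def center_of_mass(self, selection="all") -> np.ndarray:
        m = self.mask(selection)
        w = self.masses()[m]
        return np.average(self.xyz[m], axis=0, weights=w)

    def with_coordinates(self, xyz: np.ndarray, label: str | None = None) -> "StructureModel":
        return StructureModel(self.names, self.resids, self.resnames, self.elements,
                              np.asarray(xyz, dtype=float),
                              label=self.label if label is None else label)

    def atom_signature(self) -> tuple:
        return tuple(zip(self.resids.tolist(), self.names.tolist()))


@dataclass
class EnsembleBundle:
    """Ordered conformations (e.g. an NMR bundle) sharing one topology."""

    models: list
    labels: list = field(default_factory=list)

    def __post_init__(self):
        if not self.models:
            raise ValueError("empty bundle")
        if not self.labels:
            self.labels = [m.label or f"model-{i + 1}" for i, m in enumerate(self.models)]
        if len(self.labels) != len(self.models):
            raise ValueError("labels/models length mismatch")
        sig = self.models[0].atom_signature()
        for i, m in enumerate(self.models[1:], start=2):
            if m.n_atoms != self.models[0].n_atoms:
                raise ValueError(
                    f"model {i} has {m.n_atoms} atoms, expected {self.models[0].n_atoms}")
            if m.atom_signature() != sig:
                raise ValueError(f"model {i} has a different (residue, atom-name) sequence")

    def __len__(self):
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i):
        return self.models[i]

    @property
    def topology(self) -> StructureModel:
        return self.models[0]

    def coordinates(self) -> np.ndarray:
        return np.stack([m.xyz for m in self.models])


@dataclass
class TrajectorySet:
    """Frames over one topology; coords (n_frames, n_atoms, 3) Å, times ps."""

    topology: StructureModel
    coordinates: np.ndarray
    times: np.ndarray | None = None
    box: np.ndarray | None = None  # per-frame [lx, ly, lz, alpha, beta, gamma]

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coordinates.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.n_frames:
            raise ValueError("times length mismatch")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(self.n_frames, -1)
            if self.box.shape[1] == 3:
                self.box = np.hstack([self.box, np.full((self.n_frames, 3), 90.0)])

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def __len__(self):
        return self.n_frames

    def frame(self, i: int) -> StructureModel:
        return self.topology.with_coordinates(self.coordinates[i], label=f"frame-{i}")

    def slice_frames(self, start: int, stop: int) -> "TrajectorySet":
        """Half-open frame range [start, stop)."""
        return TrajectorySet(self.topology, self.coordinates[start:stop],
                             self.times[start:stop],
                             None if self.box is None else self.box[start:stop])


@dataclass
class NOERestraint:
    """One distance restraint between two (possibly ambiguous) proton groups."""

    id: str
    group_a: list  # [(resid, atom name), ...]
    group_b: list
    lower: float
    upper: float
    target: float | None = None

    def __post_init__(self):
        if self.lower < 0:
            raise ValueError(f"restraint {self.id}: negative lower bound")
        if self.lower > self.upper:
            raise ValueError(
                f"restraint {self.id}: lower bound {self.lower} > upper bound {self.upper}")
        if self.target is not None and not (self.lower <= self.target <= self.upper):
            raise ValueError(f"restraint {self.id}: target outside [lower, upper]")
        if not self.group_a or not self.group_b:
            raise ValueError(f"restraint {self.id}: empty proton group")

    @property
    def residues(self) -> tuple:
        return (self.group_a[0][0], self.group_b[0][0])


@dataclass
class NOETable:
    restraints: list = field(default_factory=list)

    def __len__(self):
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def __getitem__(self, i):
        return self.restraints[i]

    def to_records(self) -> list:
        rows = []
        for r in self.restraints:
            rows.append({
                "id": r.id,
                "resid_a": r.group_a[0][0],
                "atoms_a": "|".join(n for _, n in r.group_a),
                "resid_b": r.group_b[0][0],
                "atoms_b": "|".join(n for _, n in r.group_b),
                "lower": r.lower,
                "upper": r.upper,
                "target": "" if r.target is None else r.target,
            })
        return rows
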