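"""Sequence, structural elements and monitored-interaction definitions.

A quadruplex–duplex system is described by a :class:`NucleicSequence`
plus a :class:`StructuralAnnotation` naming its tetrads, loops,
Watson–Crick duplex pairs and junction residues.  Tetrad membership is
detected geometrically from a structure (cyclic Hoogsteen pattern)
rather than hard-coded; loops/pairs/junction are curated annotation.

Hydrogen-bond classes follow the standard naming: the guanine tetrad is
held by N1–O6 and N2–N7 Hoogsteen bonds (four of each per tetrad), a
G·C Watson–Crick pair by O6–N4, N1–N3 and N2–O2, and the bifurcated
N1–N7 geometry is monitored as a force-field artifact indicator.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import yaml

from .core import StructureModel

DNA_ALPHABET = set("ACGT")
LOOP_CLASSES = ("propeller", "lateral", "diagonal", "V-shaped")
DIHEDRAL_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")

# IUPAC backbone torsion atom quadruples; offsets are relative residue indices
_DIHEDRAL_ATOMS = {
    "alpha":   [(-1, "O3'"), (0, "P"), (0, "O5'"), (0, "C5'")],
    "beta":    [(0, "P"), (0, "O5'"), (0, "C5'"), (0, "C4'")],
    "gamma":   [(0, "O5'"), (0, "C5'"), (0, "C4'"), (0, "C3'")],
    "delta":   [(0, "C5'"), (0, "C4'"), (0, "C3'"), (0, "O3'")],
    "epsilon": [(0, "C4'"), (0, "C3'"), (0, "O3'"), (1, "P")],
    "zeta":    [(0, "C3'"), (0, "O3'"), (1, "P"), (1, "O5'")],
}

GUANINE_RESNAMES = {"G", "DG", "GUA", "DG3", "DG5"}
CYTOSINE_RESNAMES = {"C", "DC", "CYT", "DC3", "DC5"}


@dataclass
class NucleicSequence:
    """Ordered DNA residues with contiguous 1-based indices."""

    residues: list  # [(index, base), ...]

    def __post_init__(self):
        for pos, (idx, base) in enumerate(self.residues, start=1):
            if idx != pos:
                raise ValueError(f"residue indices must be contiguous from 1; got {idx} at position {pos}")
            if base not in DNA_ALPHABET:
                raise ValueError(f"invalid base {base!r} at position {pos}")

    def __len__(self):
        return len(self.residues)

    def base(self, index: int) -> str:
        return self.residues[index - 1][1]

    def __str__(self):
        return "".join(b for _, b in self.residues)


def parse_sequence(text: str) -> NucleicSequence:
    """Parse a DNA sequence, optionally in d[...] bracket notation."""
    s = text.strip()
    if s.lower().startswith("d[") and s.endswith("]"):
        s = s[2:-1]
    elif s.startswith(">"):  # single-record FASTA
        lines = s.splitlines()
        s = "".join(lines[1:])
    s = "".join(s.split())
    if not s:
        raise ValueError("empty sequence")
    residues = []
    for pos, ch in enumerate(s, start=1):
        up = ch.upper()
        if up not in DNA_ALPHABET:
            raise ValueError(f"invalid base {ch!r} at position {pos}")
        residues.append((pos, up))
    return NucleicSequence(residues)


@dataclass
class StructuralAnnotation:
    """Tetrads, loops, duplex pairs and junction of one quadruplex–duplex fold.

    Tetrads are 4-residue groups in cyclic Hoogsteen donor order, listed
    bottom-to-top along the channel axis.
    """

    tetrads: list = field(default_factory=list)
    loops: list = field(default_factory=list)        # [(class, (lo, hi)), ...]
    duplex_pairs: list = field(default_factory=list)  # [(resid, resid), ...]
    junction: tuple | None = None

    def __post_init__(self):
        seen = set()
        for quartet in self.tetrads:
            if len(quartet) != 4:
                raise ValueError(f"tetrad {quartet} does not have 4 residues")
            if seen & set(quartet):
                raise ValueError("tetrads share residues")
            seen |= set(quartet)
        loop_seen = set()
        for cls, (lo, hi) in self.loops:
            if cls not in LOOP_CLASSES:
                raise ValueError(f"unknown loop class {cls!r}")
            if hi < lo:
                raise ValueError(f"loop range ({lo}, {hi}) inverted")
            rng = set(range(lo, hi + 1))
            if loop_seen & rng:
                raise ValueError("loops overlap")
            loop_seen |= rng
        pair_seen = set()
        for a, b in self.duplex_pairs:
            if a == b:
                raise ValueError("duplex pair references one residue twice")
            if pair_seen & {a, b}:
                raise ValueError("duplex pairs share residues")
            pair_seen |= {a, b}

    def loop_length(self, cls: str) -> int:
        for c, (lo, hi) in self.loops:
            if c == cls:
                return hi - lo + 1
        raise KeyError(f"no {cls!r} loop in annotation")

    def validate_against(self, sequence: NucleicSequence) -> None:
        n = len(sequence)
        referenced = ([r for q in self.tetrads for r in q]
                      + [r for _, (lo, hi) in self.loops for r in range(lo, hi + 1)]
                      + [r for p in self.duplex_pairs for r in p]
                      + (list(self.junction) if self.junction else []))
        for r in referenced:
            if not 1 <= r <= n:
                raise ValueError(f"annotation references residue {r} outside 1..{n}")
        for quartet in self.tetrads:
            for r in quartet:
                if sequence.base(r) != "G":
                    raise ValueError(f"tetrad residue {r} is {sequence.base(r)}, not G")


def load_annotation(path_or_stream) -> tuple[NucleicSequence | None, StructuralAnnotation]:
    if hasattr(path_or_stream, "read"):
        data = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            data = yaml.safe_load(fh)
    seq = parse_sequence(data["sequence"]) if data.get("sequence") else None
    ann = StructuralAnnotation(
        tetrads=[list(t) for t in data.get("tetrads") or []],
        loops=[(d["class"], tuple(d["range"])) for d in data.get("loops") or []],
        duplex_pairs=[tuple(p) for p in data.get("duplex_pairs") or []],
        junction=tuple(data["junction"]) if data.get("junction") else None,
    )
    if seq is not None:
        ann.validate_against(seq)
    return seq, ann


def save_annotation(sequence: NucleicSequence | None, annotation: StructuralAnnotation, path) -> None:
    data = {
        "sequence": None if sequence is None else str(sequence),
        "tetrads": [list(t) for t in annotation.tetrads],
        "loops": [{"class": c, "range": list(r)} for c, r in annotation.loops],
        "duplex_pairs": [list(p) for p in annotation.duplex_pairs],
        "junction": None if annotation.junction is None else list(annotation.junction),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def ltr3_annotation() -> tuple[NucleicSequence, StructuralAnnotation]:
    """The packaged HIV LTR-III annotation (tetrads left to geometric detection)."""
    ref = importlib.resources.files("g4validate.data") / "ltr3.yaml"
    with ref.open() as fh:
        return load_annotation(fh)


@dataclass
class HBondDefinition:
    """One monitored hydrogen bond.

    ``hydrogen`` lists candidate proton names on the donor (amino groups
    carry two); series computation takes the candidate giving the most
    linear donor–H–acceptor geometry in each frame.
    """

    donor: tuple           # (resid, atom name)
    hydrogen: tuple        # candidate atom names on the donor residue
    acceptor: tuple        # (resid, atom name)
    bond_class: str

    def __post_init__(self):
        if self.donor[0] == self.acceptor[0]:
            raise ValueError("donor and acceptor must belong to distinct residues")
        if isinstance(self.hydrogen, str):
            self.hydrogen = (self.hydrogen,)
        self.hydrogen = tuple(self.hydrogen)
        d, a = self.donor[1], self.acceptor[1]
        expect = {
            "N1-O6": ("N1", "O6"), "N2-N7": ("N2", "N7"), "O6-N4": ("N4", "O6"),
            "N1-N3": ("N1", "N3"), "N2-O2": ("N2", "O2"), "N1-N7": ("N1", "N7"),
        }
        if self.bond_class not in expect:
            raise ValueError(f"unknown bond class {self.bond_class!r}")
        if (d, a) != expect[self.bond_class]:
            raise ValueError(
                f"bond class {self.bond_class} inconsistent with atoms {d}->{a}")

    @property
    def label(self) -> str:
        return f"{self.donor[0]}{self.donor[1]}-{self.acceptor[0]}{self.acceptor[1]}({self.bond_class})"


def enumerate_hbond_definitions(annotation: StructuralAnnotation,
                                sequence: NucleicSequence | None = None,
                                include_bifurcated: bool = False) -> list[HBondDefinition]:
    """All monitored H-bonds: 8 per tetrad, 3 per G·C pair (+4 N1–N7 per tetrad).

    Tetrad donors follow the cyclic order stored in the annotation: each
    guanine donates N1→O6 and N2→N7 to the next residue of its quartet.
    """
    defs = []
    for quartet in annotation.tetrads:
        for g in range(4):
            don, acc = quartet[g], quartet[(g + 1) % 4]
            defs.append(HBondDefinition((don, "N1"), ("H1",), (acc, "O6"), "N1-O6"))
            defs.append(HBondDefinition((don, "N2"), ("H21", "H22"), (acc, "N7"), "N2-N7"))
    for a, b in annotation.duplex_pairs:
        if sequence is not None:
            ba, bb = sequence.base(a), sequence.base(b)
            if {ba, bb} != {"G", "C"}:
                raise ValueError(f"duplex pair ({a}, {b}) is {ba}·{bb}, not G·C")
            g_res, c_res = (a, b) if ba == "G" else (b, a)
        else:
            g_res, c_res = a, b
        defs.append(HBondDefinition((c_res, "N4"), ("H41", "H42"), (g_res, "O6"), "O6-N4"))
        defs.append(HBondDefinition((g_res, "N1"), ("H1",), (c_res, "N3"), "N1-N3"))
        defs.append(HBondDefinition((g_res, "N2"), ("H21", "H22"), (c_res, "O2"), "N2-O2"))
    if include_bifurcated:
        for quartet in annotation.tetrads:
            for g in range(4):
                don, acc = quartet[g], quartet[(g + 1) % 4]
                defs.append(HBondDefinition((don, "N1"), ("H1",), (acc, "N7"), "N1-N7"))
    return defs


@dataclass
class DihedralDefinition:
    """One backbone torsion; ``atoms`` is None when undefined at a terminus."""

    name: str
    resid: int
    atoms: list | None  # [(resid, atom name) x 4] in chain order

    def __post_init__(self):
        if self.name not in DIHEDRAL_NAMES:
            raise ValueError(f"unknown dihedral name {self.name!r}")

    @property
    def defined(self) -> bool:
        return self.atoms is not None


def enumerate_backbone_dihedrals(sequence: NucleicSequence,
                                 terminal_convention: str = "no-5p-phosphate"
                                 ) -> list[DihedralDefinition]:
    """Six torsions (alpha…zeta) per residue, termini marked missing.

    Under the default convention the 5' residue carries no phosphate
    (alpha and beta missing) and the 3' residue has no downstream P
    (epsilon and zeta missing) — standard PDB DNA deposition practice.
    """
    if terminal_convention != "no-5p-phosphate":
        raise ValueError(f"unknown terminal convention {terminal_convention!r}")
    n = len(sequence)
    out = []
    for resid in range(1, n + 1):
        for name in DIHEDRAL_NAMES:
            atoms = [(resid + off, at) for off, at in _DIHEDRAL_ATOMS[name]]
            ok = all(1 <= r <= n for r, _ in atoms)
            # residue 1 has no phosphate: any torsion touching P(1) is undefined
            if ok and any(r == 1 and at == "P" for r, at in atoms):
                ok = False
            out.append(DihedralDefinition(name, resid, atoms if ok else None))
    return out


def detect_tetrads(model: StructureModel, distance_cutoff: float = 3.5,
                   planarity_tolerance: float = 1.0) -> list[list[int]]:
    """Find guanine quartets closed by the cyclic Hoogsteen pattern.

    Each returned quartet is in donor order (residue i donates N1→O6 and
    N2→N7 to residue i+1) starting from its lowest residue index;
    quartets are sorted along the mean channel axis.
    """
    required = ("N1", "N2", "N7", "O6")
    candidates = []
    for resid in model.residue_ids:
        resname = str(model.resnames[model.resids == resid][0]).upper()
        has_all = all(model.has_atom(resid, a) for a in required)
        if has_all:
            candidates.append(int(resid))
        elif resname in GUANINE_RESNAMES:
            warnings.warn(f"guanine residue {resid} missing Hoogsteen atoms; skipped")
    if len(candidates) < 4:
        return []

    pos = {(r, a): model.xyz[model.atom_index(r, a)] for r in candidates for a in required}
    graph = nx.DiGraph()
    graph.add_nodes_from(candidates)
    for i in candidates:
        for j in candidates:
            if i == j:
                continue
            if (np.linalg.norm(pos[(i, "N1")] - pos[(j, "O6")]) <= distance_cutoff
                    and np.linalg.norm(pos[(i, "N2")] - pos[(j, "N7")]) <= distance_cutoff):
                graph.add_edge(i, j)

    quartets = []
    for cycle in nx.simple_cycles(graph, length_bound=4):
        if len(cycle) != 4:
            continue
        pts = np.array([pos[(r, a)] for r in cycle for a in required])
        centered = pts - pts.mean(axis=0)
        # smallest singular direction = plane normal; max |projection| = deviation
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        dev = np.abs(centered @ vt[2]).max()
        if dev > planarity_tolerance:
            continue
        k = int(np.argmin(cycle))
        quartets.append([int(r) for r in cycle[k:] + cycle[:k]])

    # enforce disjointness deterministically (lowest starting residue first)
    quartets.sort(key=lambda q: q[0])
    chosen, used = [], set()
    for q in quartets:
        if not used & set(q):
            chosen.append(q)
            used |= set(q)
    if len(chosen) > 1:
        cents = np.array([np.mean([pos[(r, "O6")] for r in q], axis=0) for q in chosen])
        spread = cents - cents.mean(axis=0)
        axis = np.linalg.svd(spread, full_matrices=False)[2][0]
        # deterministic axis sign: point along the largest-magnitude component
        if axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
        order = np.argsort(spread @ axis, kind="stable")
        chosen = [chosen[i] for i in order]
    return chosen
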