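"""Readers and writers for the formats the pipeline touches.

Structures travel as (multi-model) PDB, trajectories as DCD/XTC/TRR,
restraints as Amber DISANG namelists, NMR-STAR distance-constraint
loops, or a documented 8-column TSV.  Coordinates are Å, times ps.

Restraint dialect sniffing is deliberately refused: a silent misparse
of distance bounds is the worst failure mode a validation pipeline can
have, so the caller must name the dialect.
"""

from __future__ import annotations

import importlib.resources
import json
import re

import gemmi
import MDAnalysis as mda
import numpy as np
import pandas as pd
import yaml

from .core import (EnsembleBundle, NOERestraint, NOETable, StructureModel,
                   TrajectorySet, element_from_name)

NOE_DIALECTS = ("tsv", "disang", "nmr-star")
_TSV_COLUMNS = ["id", "resid_a", "atoms_a", "resid_b", "atoms_b", "lower", "upper", "target"]


# ---------------------------------------------------------------------------
# structures

def _prevalidate_pdb(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    raise ValueError(f"unparsable ATOM record at line {lineno} of {path}")


def read_structure_bundle(path) -> EnsembleBundle:
    """Read a (multi-model) PDB file into an ensemble bundle.

    Single-model files yield a bundle of size 1.  Models must share one
    atom ordering; a mismatch is reported with the offending model.
    """
    _prevalidate_pdb(path)
    st = gemmi.read_structure(str(path))
    models = []
    for model in st:
        names, resids, resnames, elements, xyz = [], [], [], [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    names.append(atom.name)
                    resids.append(res.seqid.num)
                    resnames.append(res.name.strip())
                    el = atom.element.name if atom.element else ""
                    elements.append(el or element_from_name(atom.name))
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        models.append(StructureModel(np.array(names, dtype=object), np.array(resids),
                                     np.array(resnames, dtype=object),
                                     np.array(elements, dtype=object), np.array(xyz),
                                     label=f"model-{len(models) + 1}"))
    if not models:
        raise ValueError(f"no models found in {path}")
    n0 = models[0].n_atoms
    for i, m in enumerate(models[1:], start=2):
        if m.n_atoms != n0:
            raise ValueError(f"model {i} of {path} has {m.n_atoms} atoms, expected {n0}")
    return EnsembleBundle(models)


def write_structure_bundle(bundle, path) -> None:
    """Write one model or a bundle as (multi-model) PDB."""
    models = bundle.models if isinstance(bundle, EnsembleBundle) else [bundle]
    st = gemmi.Structure()
    st.name = "g4validate"
    for model in models:
        gm = gemmi.Model(str(len(st) + 1))
        chain = gemmi.Chain("A")
        last_resid = None
        res = None
        for i in range(model.n_atoms):
            resid = int(model.resids[i])
            if resid != last_resid:
                res = gemmi.Residue()
                res.name = str(model.resnames[i])[:3]
                res.seqid = gemmi.SeqId(resid, " ")
                chain.add_residue(res)
                res = chain[-1]
                last_resid = resid
            atom = gemmi.Atom()
            atom.name = str(model.names[i])
            atom.element = gemmi.Element(str(model.elements[i]))
            atom.pos = gemmi.Position(*model.xyz[i])
            res.add_atom(atom)
        gm.add_chain(chain)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# trajectories

def read_trajectory(topology: StructureModel, path, fmt: str | None = None,
                    frames: tuple | None = None) -> TrajectorySet:
    """Load a trajectory over ``topology``; ``frames`` is a half-open range."""
    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    try:
        u.load_new(str(path), format=fmt)
    except Exception as exc:
        raise ValueError(f"cannot read trajectory {path}: {exc}") from exc
    if u.trajectory.n_atoms != topology.n_atoms:
        raise ValueError(
            f"trajectory atom count {u.trajectory.n_atoms} != topology "
            f"atom count {topology.n_atoms}")
    coords, times, boxes = [], [], []
    have_box = True
    try:
        for ts in u.trajectory:
            coords.append(ts.positions.astype(float).copy())
            times.append(float(ts.time))
            if ts.dimensions is None or not np.any(ts.dimensions[:3]):
                have_box = False
            else:
                boxes.append(ts.dimensions.astype(float).copy())
    except Exception as exc:
        raise ValueError(
            f"trajectory {path} truncated after frame {len(coords) - 1}: {exc}") from exc
    times = np.asarray(times)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(coords), dtype=float)
    traj = TrajectorySet(topology, np.array(coords), times,
                         np.array(boxes) if have_box and boxes else None)
    if frames is not None:
        traj = traj.slice_frames(*frames)
    return traj


def write_trajectory(traj: TrajectorySet, path, fmt: str | None = None) -> None:
    u = mda.Universe.empty(traj.n_atoms, trajectory=True)
    with mda.Writer(str(path), n_atoms=traj.n_atoms, format=fmt) as writer:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coordinates[f]
            ts = u.trajectory.ts
            ts.frame = f
            ts.time = traj.times[f]
            if traj.box is not None:
                ts.dimensions = traj.box[f]
            writer.write(u.atoms)


# ---------------------------------------------------------------------------
# NOE restraint tables

def load_pseudoatom_map() -> dict:
    ref = importlib.resources.files("g4validate.data") / "pseudoatoms.yaml"
    with ref.open() as fh:
        return yaml.safe_load(fh)


def _expand_group(resid: int, name: str, pseudo_map: dict) -> list:
    if name in pseudo_map:
        return [(resid, n) for n in pseudo_map[name]]
    if re.search(r"[#*]", name) or (name.startswith(("Q", "M")) and not name.startswith("MG")):
        raise ValueError(f"unmapped pseudoatom name {name!r} (residue {resid})")
    return [(resid, name)]


def _parse_group_field(resid_field: str, atoms_field: str, pseudo_map: dict) -> list:
    resid = int(resid_field)
    group = []
    for name in atoms_field.split("|"):
        group.extend(_expand_group(resid, name.strip(), pseudo_map))
    return group


def _read_noe_tsv(path, pseudo_map: dict) -> NOETable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TSV_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"TSV restraint table {path} lacks columns {missing}")
    restraints = []
    for _, row in df.iterrows():
        target = row.get("target", "")
        restraints.append(NOERestraint(
            id=row["id"],
            group_a=_parse_group_field(row["resid_a"], row["atoms_a"], pseudo_map),
            group_b=_parse_group_field(row["resid_b"], row["atoms_b"], pseudo_map),
            lower=float(row["lower"]),
            upper=float(row["upper"]),
            target=float(target) if str(target).strip() else None,
        ))
    return NOETable(restraints)


_NAMELIST_RE = re.compile(r"&rst(.*?)(?:&end|/)", re.DOTALL | re.IGNORECASE)


def _read_noe_disang(path, topology: StructureModel, pseudo_map: dict) -> NOETable:
    """Amber DISANG-style flat-bottom restraints (r2..r3 = lower..upper).

    Atom references are 1-based indices into ``topology``; igr1/igr2
    carry ambiguous groups when the corresponding iat entry is negative.
    """
    if topology is None:
        raise ValueError("the DISANG dialect needs a topology to map atom indices")
    text = open(path).read()
    restraints = []
    for k, match in enumerate(_NAMELIST_RE.finditer(text), start=1):
        fields = {}
        for key, val in re.findall(r"(\w+)\s*=\s*([^=&/]+?)(?=[,\s]*\w+\s*=|\s*$)",
                                   match.group(1), re.DOTALL):
            fields[key.lower()] = [v for v in re.split(r"[,\s]+", val.strip()) if v]
        if "iat" not in fields or "r2" not in fields or "r3" not in fields:
            raise ValueError(f"restraint {k} in {path}: missing iat/r2/r3")
        iat = [int(v) for v in fields["iat"][:2]]

        def group(slot, igr_key):
            if iat[slot] > 0:
                idx = [iat[slot]]
            else:
                idx = [int(v) for v in fields.get(igr_key, []) if int(v) != 0]
                if not idx:
                    raise ValueError(f"restraint {k} in {path}: empty {igr_key}")
            out = []
            for i in idx:
                if not 1 <= i <= topology.n_atoms:
                    raise ValueError(f"restraint {k} in {path}: atom index {i} out of range")
                out.append((int(topology.resids[i - 1]), str(topology.names[i - 1])))
            return out

        restraints.append(NOERestraint(
            id=f"disang-{k:04d}",
            group_a=group(0, "igr1"),
            group_b=group(1, "igr2"),
            lower=float(fields["r2"][0]),
            upper=float(fields["r3"][0]),
        ))
    return NOETable(restraints)


def _star_loops(path):
    """Yield (tags, rows) for every loop_ block of a STAR file."""
    tokens = []
    for line in open(path):
        line = line.split("#", 1)[0]
        tokens.extend(line.split())
    i = 0
    while i < len(tokens):
        if tokens[i].lower() != "loop_":
            i += 1
            continue
        i += 1
        tags = []
        while i < len(tokens) and tokens[i].startswith("_"):
            tags.append(tokens[i])
            i += 1
        values = []
        while i < len(tokens) and tokens[i].lower() not in ("stop_", "loop_"):
            values.append(tokens[i])
            i += 1
        if i < len(tokens) and tokens[i].lower() == "stop_":
            i += 1
        if tags and len(values) % len(tags) == 0:
            rows = [values[j:j + len(tags)] for j in range(0, len(values), len(tags))]
            yield tags, rows


def _read_noe_star(path, pseudo_map: dict) -> NOETable:
    """NMR-STAR distance-constraint loops (_Gen_dist_constraint.*).

    Rows sharing a constraint ID are merged into one restraint with
    ambiguous proton groups.
    """
    wanted = None
    for tags, rows in _star_loops(path):
        short = [t.split(".")[-1] for t in tags]
        if "Distance_upper_bound_val" in short and "Atom_ID_1" in short:
            wanted = (short, rows)
            break
    if wanted is None:
        raise ValueError(f"no distance-constraint loop found in {path}")
    short, rows = wanted

    def col(row, *names):
        for n in names:
            if n in short:
                v = row[short.index(n)]
                if v not in (".", "?"):
                    return v
        return None

    grouped: dict = {}
    order = []
    for row in rows:
        cid = col(row, "ID", "Constraint_ID") or str(len(order) + 1)
        if cid not in grouped:
            grouped[cid] = {"a": [], "b": [], "lower": None, "upper": None, "target": None}
            order.append(cid)
        g = grouped[cid]
        ra = col(row, "Comp_index_ID_1", "Seq_ID_1")
        rb = col(row, "Comp_index_ID_2", "Seq_ID_2")
        aa = col(row, "Atom_ID_1")
        ab = col(row, "Atom_ID_2")
        if None in (ra, rb, aa, ab):
            raise ValueError(f"incomplete constraint row in {path}: {row}")
        for member in _expand_group(int(ra), aa, pseudo_map):
            if member not in g["a"]:
                g["a"].append(member)
        for member in _expand_group(int(rb), ab, pseudo_map):
            if member not in g["b"]:
                g["b"].append(member)
        lo = col(row, "Distance_lower_bound_val")
        up = col(row, "Distance_upper_bound_val")
        tv = col(row, "Distance_val")
        g["lower"] = float(lo) if lo is not None else g["lower"]
        g["upper"] = float(up) if up is not None else g["upper"]
        g["target"] = float(tv) if tv is not None else g["target"]
    restraints = []
    for cid in order:
        g = grouped[cid]
        restraints.append(NOERestraint(
            id=f"star-{cid}", group_a=g["a"], group_b=g["b"],
            lower=g["lower"] if g["lower"] is not None else 0.0,
            upper=g["upper"], target=g["target"]))
    return NOETable(restraints)


def read_noe_table(path, dialect: str, topology: StructureModel | None = None) -> NOETable:
    """Parse a restraint table in the named dialect (no sniffing)."""
    if dialect not in NOE_DIALECTS:
        raise ValueError(f"unknown restraint dialect {dialect!r}; choose from {NOE_DIALECTS}")
    pseudo_map = load_pseudoatom_map()
    if dialect == "tsv":
        return _read_noe_tsv(path, pseudo_map)
    if dialect == "disang":
        return _read_noe_disang(path, topology, pseudo_map)
    return _read_noe_star(path, pseudo_map)


def write_noe_table(table: NOETable, path) -> None:
    """Write the documented 8-column TSV dialect."""
    df = pd.DataFrame(table.to_records(), columns=_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# reports

def write_report(results, path, fmt: str = "tsv") -> None:
    """Serialize analysis results deterministically (TSV or JSON).

    ``results`` may be a DataFrame, a list of records, or a flat mapping.
    Column order is preserved; floats are written at fixed precision so
    re-reading reproduces values.
    """
    if fmt not in ("tsv", "json"):
        raise ValueError(f"unknown report format {fmt!r}")
    if fmt == "json":
        if isinstance(results, pd.DataFrame):
            payload = results.to_dict(orient="records")
        else:
            payload = results

        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"unserializable {type(o)}")

        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=default)
            fh.write("\n")
        return
    if isinstance(results, dict):
        results = [results]
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(results)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
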