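"""Atom selection mini-grammar.

Selections are strings combining clauses with ``and``, ``or`` and ``not``
(evaluated left to right, no precedence — parenthesise mentally by
splitting into multiple selections if needed).  Clauses:

``all``
    every atom.
``heavy``
    atoms whose element is not hydrogen.
``resid 1-12`` / ``resid 1,3,5-7``
    1-based residue index ranges (inclusive) and comma lists.
``name N1 O6 H2'*``
    atom names; a trailing ``*`` matches any suffix.
``resname G DG``
    residue names.
``element K P``
    element symbols (case-insensitive).

This deliberately avoids depending on an external selection language:
masks here only ever combine residue-index ranges with atom-name lists.
"""

from __future__ import annotations

import fnmatch

import numpy as np

_KEYWORDS = {"resid", "name", "resname", "element", "heavy", "all", "and", "or", "not"}


class SelectionError(ValueError):
    pass


def _parse_ranges(tokens: list[str]) -> list[tuple[int, int]]:
    ranges = []
    for tok in tokens:
        for part in tok.split(","):
            if not part:
                continue
            if "-" in part[1:]:  # allow negative start, though resids are 1-based
                lo, hi = part.rsplit("-", 1)
                ranges.append((int(lo), int(hi)))
            else:
                ranges.append((int(part), int(part)))
    if not ranges:
        raise SelectionError("'resid' clause needs at least one index or range")
    return ranges


def _match_names(values: np.ndarray, patterns: list[str]) -> np.ndarray:
    mask = np.zeros(len(values), dtype=bool)
    for pat in patterns:
        if "*" in pat or "?" in pat:
            mask |= np.array([fnmatch.fnmatchcase(v, pat) for v in values])
        else:
            mask |= values == pat
    return mask


def select(model, expression: str) -> np.ndarray:
    """Evaluate ``expression`` against a StructureModel; return a boolean mask."""
    tokens = expression.split()
    if not tokens:
        raise SelectionError("empty selection")

    def clause(pos: int) -> tuple[np.ndarray, int]:
        negate = False
        while pos < len(tokens) and tokens[pos] == "not":
            negate = not negate
            pos += 1
        if pos >= len(tokens):
            raise SelectionError("dangling 'not'")
        kw = tokens[pos]
        pos += 1
        if kw == "all":
            mask = np.ones(model.n_atoms, dtype=bool)
        elif kw == "heavy":
            mask = np.char.upper(model.elements.astype(str)) != "H"
        elif kw in ("name", "resname", "element"):
            args = []
            while pos < len(tokens) and tokens[pos] not in _KEYWORDS:
                args.append(tokens[pos])
                pos += 1
            if not args:
                raise SelectionError(f"'{kw}' clause needs at least one argument")
            if kw == "name":
                mask = _match_names(model.names.astype(str), args)
            elif kw == "resname":
                mask = _match_names(model.resnames.astype(str), args)
            else:
                vals = np.char.upper(model.elements.astype(str))
                mask = _match_names(vals, [a.upper() for a in args])
        elif kw == "resid":
            args = []
            while pos < len(tokens) and tokens[pos] not in _KEYWORDS:
                args.append(tokens[pos])
                pos += 1
            mask = np.zeros(model.n_atoms, dtype=bool)
            for lo, hi in _parse_ranges(args):
                mask |= (model.resids >= lo) & (model.resids <= hi)
        else:
            raise SelectionError(f"unknown selection keyword {kw!r}")
        if negate:
            mask = ~mask
        return mask, pos

    mask, pos = clause(0)
    while pos < len(tokens):
        op = tokens[pos]
        if op not in ("and", "or"):
            raise SelectionError(f"expected 'and'/'or', got {op!r}")
        rhs, pos = clause(pos + 1)
        mask = (mask & rhs) if op == "and" else (mask | rhs)
    return mask
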