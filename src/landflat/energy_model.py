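"""Sequence/rotamer spaces and per-state pairwise energy matrices.

A design problem is described by a :class:`SequenceSpace` — a handful of
*mutable* positions, each with an allowed set of residue types, plus
*flexible* positions that keep a fixed type but can change rotamer — and one
:class:`EnergyMatrix` per thermodynamic state (apo, holo, transition-state
complex, ...).  The matrix stores side-chain↔backbone self energies
("diagonal" terms) and side-chain↔side-chain interaction energies
("pair" terms), all in kcal/mol, indexed by (position, type, rotamer).

Flexible positions are represented internally as single-type positions so
one code path handles both.  Pair energies absent from a file are exactly
zero (sparse storage).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "SequenceSpace",
    "EnergyMatrix",
    "StateAssignment",
    "Move",
    "MatrixFormatError",
    "count_sequences",
    "total_energy",
    "delta_energy",
    "load_energy_matrix",
    "save_energy_matrix",
]

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class MatrixFormatError(ValueError):
    """Raised for malformed energy-matrix files; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class SequenceSpace:
    """The discrete (position x type x rotamer) design space.

    Parameters
    ----------
    positions
        Ordered mutable-position identifiers (1-based integers by
        convention; arbitrary labels allowed).
    allowed_types
        Mapping position -> ordered string/sequence of one-letter type
        codes allowed there.
    rotamer_counts
        Either a single int (same count everywhere), or a mapping
        ``(position, type) -> count``.
    flexible
        Mapping position -> ``(type, rotamer_count)`` for non-mutating
        positions that only change rotamer.
    """

    positions: tuple[int, ...]
    allowed_types: tuple[tuple[str, ...], ...]
    rotamer_counts: Mapping[tuple[int, str], int]
    flexible_positions: tuple[int, ...] = ()
    flexible_types: tuple[str, ...] = ()

    def __init__(
        self,
        positions: Sequence[int],
        allowed_types: Mapping[int, Sequence[str]] | Sequence[Sequence[str]],
        rotamer_counts: int | Mapping[tuple[int, str], int] = 1,
        flexible: Mapping[int, tuple[str, int]] | None = None,
    ):
        positions = tuple(positions)
        if isinstance(allowed_types, Mapping):
            types = tuple(tuple(allowed_types[p]) for p in positions)
        else:
            types = tuple(tuple(t) for t in allowed_types)
        if len(types) != len(positions):
            raise ValueError("allowed_types must cover every mutable position")
        flexible = dict(flexible or {})
        flex_pos = tuple(flexible)
        flex_types = tuple(flexible[p][0] for p in flex_pos)
        all_pos = positions + flex_pos
        if len(set(all_pos)) != len(all_pos):
            raise ValueError("position identifiers must be unique")
        counts: dict[tuple[int, str], int] = {}
        for p, ts in zip(positions, types):
            if not ts:
                raise ValueError(f"position {p} has no allowed types")
            if len(set(ts)) != len(ts):
                raise ValueError(f"position {p} repeats a type code")
            for t in ts:
                if t not in AMINO_ACIDS:
                    raise ValueError(f"unknown residue type {t!r} at position {p}")
                n = rotamer_counts if isinstance(rotamer_counts, int) else rotamer_counts[(p, t)]
                if n < 1:
                    raise ValueError(f"position {p} type {t} needs >= 1 rotamer")
                counts[(p, t)] = int(n)
        for p, (t, n) in flexible.items():
            if t not in AMINO_ACIDS:
                raise ValueError(f"unknown residue type {t!r} at flexible position {p}")
            if n < 1:
                raise ValueError(f"flexible position {p} needs >= 1 rotamer")
            counts[(p, t)] = int(n)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "allowed_types", types)
        object.__setattr__(self, "rotamer_counts", counts)
        object.__setattr__(self, "flexible_positions", flex_pos)
        object.__setattr__(self, "flexible_types", flex_types)

    # -- uniform view: mutable positions first, then flexible -------------
    @property
    def all_positions(self) -> tuple[int, ...]:
        return self.positions + self.flexible_positions

    def types_at(self, pos: int) -> tuple[str, ...]:
        """Allowed types at any position (a single type if flexible)."""
        if pos in self.positions:
            return self.allowed_types[self.positions.index(pos)]
        if pos in self.flexible_positions:
            return (self.flexible_types[self.flexible_positions.index(pos)],)
        raise KeyError(f"unknown position {pos}")

    def rotamers_at(self, pos: int, t: str) -> int:
        try:
            return self.rotamer_counts[(pos, t)]
        except KeyError:
            raise KeyError(f"type {t!r} not allowed at position {pos}") from None

    @property
    def n_sequences(self) -> int:
        n = 1
        for ts in self.allowed_types:
            n *= len(ts)
        return n

    def sequences(self) -> Iterator[str]:
        """All sequences (type strings over mutable positions), mixed-radix
        order with the first position most significant."""
        import itertools

        for combo in itertools.product(*self.allowed_types):
            yield "".join(combo)

    def sequence_index(self, seq: str) -> int:
        idx = 0
        for ts, t in zip(self.allowed_types, seq):
            idx = idx * len(ts) + ts.index(t)
        return idx

    def contains_sequence(self, seq: str) -> bool:
        return len(seq) == len(self.positions) and all(
            t in ts for ts, t in zip(self.allowed_types, seq)
        )


def count_sequences(space: SequenceSpace) -> int:
    """Number of distinct sequences: product of allowed-type counts over
    mutable positions (e.g. three positions with 14 types each -> 2744)."""
    return space.n_sequences


@dataclass(frozen=True)
class StateAssignment:
    """A microstate: one (type, rotamer) choice at every position."""

    type_at: Mapping[int, str]
    rotamer_at: Mapping[int, int]

    def validate(self, space: SequenceSpace) -> None:
        for pos in space.all_positions:
            if pos not in self.type_at or pos not in self.rotamer_at:
                raise ValueError(f"assignment missing position {pos}")
            t = self.type_at[pos]
            if t not in space.types_at(pos):
                raise ValueError(f"type {t!r} not allowed at position {pos}")
            r = self.rotamer_at[pos]
            if not (0 <= r < space.rotamers_at(pos, t)):
                raise ValueError(
                    f"rotamer {r} out of range at position {pos} type {t!r}"
                )

    def sequence(self, space: SequenceSpace) -> str:
        """Sequence projection: types at the mutable positions."""
        return "".join(self.type_at[p] for p in space.positions)

    def replace(self, moves: "Move") -> "StateAssignment":
        t = dict(self.type_at)
        r = dict(self.rotamer_at)
        for pos, typ, rot in moves:
            t[pos] = typ
            r[pos] = rot
        return StateAssignment(t, r)


#: A proposed reassignment: list of (position, new type, new rotamer).
Move = list


@dataclass
class EnergyMatrix:
    """Per-state energy matrix over a :class:`SequenceSpace`.

    ``diag[(i, t, r)]`` holds the side-chain self + backbone interaction
    energy; ``pair[((i, t, r), (j, u, q))]`` (stored once with i < j in
    position order) holds the side-chain/side-chain interaction.  Missing
    pair entries are zero.
    """

    space: SequenceSpace
    state_label: str = ""
    diag: dict = field(default_factory=dict)
    pair: dict = field(default_factory=dict)

    def __post_init__(self):
        self._order = {p: k for k, p in enumerate(self.space.all_positions)}
        canon = {}
        for key, e in self.pair.items():
            canon[self._canonical(key)] = float(e)
        self.pair = canon
        self.validate()

    def _canonical(self, key):
        a, b = key
        if self._order[a[0]] > self._order[b[0]]:
            a, b = b, a
        return (a, b)

    def validate(self) -> None:
        space = self.space
        for pos in space.all_positions:
            for t in space.types_at(pos):
                for r in range(space.rotamers_at(pos, t)):
                    e = self.diag.get((pos, t, r), 0.0)
                    if not math.isfinite(e):
                        raise ValueError(f"non-finite diag energy at {(pos, t, r)}")
        for (pos, t, r) in self.diag:
            if t not in space.types_at(pos) or not (0 <= r < space.rotamers_at(pos, t)):
                raise ValueError(f"diag index {(pos, t, r)} inconsistent with space")
        for (a, b), e in self.pair.items():
            for (pos, t, r) in (a, b):
                if t not in space.types_at(pos) or not (0 <= r < space.rotamers_at(pos, t)):
                    raise ValueError(f"pair index {(a, b)} inconsistent with space")
            if a[0] == b[0]:
                raise ValueError(f"pair entry within a single position {a[0]}")
            if not math.isfinite(e):
                raise ValueError(f"non-finite pair energy at {(a, b)}")

    # -- lookups -----------------------------------------------------------
    def diag_energy(self, pos: int, t: str, r: int) -> float:
        return self.diag.get((pos, t, r), 0.0)

    def pair_energy(self, i, ti, ri, j, tj, rj) -> float:
        """Symmetric pair lookup; zero when absent."""
        return self.pair.get(self._canonical(((i, ti, ri), (j, tj, rj))), 0.0)

    def set_diag(self, pos, t, r, e) -> None:
        self.diag[(pos, t, r)] = float(e)

    def set_pair(self, i, ti, ri, j, tj, rj, e) -> None:
        self.pair[self._canonical(((i, ti, ri), (j, tj, rj)))] = float(e)

    def copy(self) -> "EnergyMatrix":
        return EnergyMatrix(self.space, self.state_label, dict(self.diag), dict(self.pair))

    def save(self, path) -> None:
        save_energy_matrix(self, path)


def total_energy(matrix: EnergyMatrix, state: StateAssignment) -> float:
    """Total energy of a microstate: sum of diagonal terms plus all
    pairwise terms for the assigned types/rotamers (kcal/mol)."""
    state.validate(matrix.space)
    positions = matrix.space.all_positions
    e = 0.0
    for pos in positions:
        e += matrix.diag_energy(pos, state.type_at[pos], state.rotamer_at[pos])
    for k, i in enumerate(positions):
        for j in positions[k + 1:]:
            e += matrix.pair_energy(
                i, state.type_at[i], state.rotamer_at[i],
                j, state.type_at[j], state.rotamer_at[j],
            )
    return e


def delta_energy(matrix: EnergyMatrix, state: StateAssignment, move: Move) -> float:
    """Incremental energy of a 1- or 2-position move.

    Equals ``total_energy(after) - total_energy(before)`` but touches only
    the terms involving the moved positions.
    """
    if not 1 <= len(move) <= 2:
        raise ValueError("move must touch 1 or 2 positions")
    moved = {m[0] for m in move}
    if len(moved) != len(move):
        raise ValueError("move touches a position twice")
    new_t = {pos: t for pos, t, _ in move}
    new_r = {pos: r for pos, _, r in move}
    dE = 0.0
    for pos in moved:
        dE += matrix.diag_energy(pos, new_t[pos], new_r[pos])
        dE -= matrix.diag_energy(pos, state.type_at[pos], state.rotamer_at[pos])
    for pos in moved:
        for other in matrix.space.all_positions:
            if other == pos or other in moved:
                continue
            ot, orr = state.type_at[other], state.rotamer_at[other]
            dE += matrix.pair_energy(pos, new_t[pos], new_r[pos], other, ot, orr)
            dE -= matrix.pair_energy(
                pos, state.type_at[pos], state.rotamer_at[pos], other, ot, orr
            )
    if len(move) == 2:
        (i, j) = sorted(moved, key=lambda p: matrix.space.all_positions.index(p))
        dE += matrix.pair_energy(i, new_t[i], new_r[i], j, new_t[j], new_r[j])
        dE -= matrix.pair_energy(
            i, state.type_at[i], state.rotamer_at[i],
            j, state.type_at[j], state.rotamer_at[j],
        )
    return dE


# ---------------------------------------------------------------------------
# File format
#
# Line-oriented text (``#`` comments)::
#
#     STATE apo
#     POSITION 13 MUTABLE A=3 C=2 ...
#     POSITION 5 FLEXIBLE W=4
#     DIAG 13 A 0 -1.234567890123
#     PAIR 13 A 0 297 C 1 0.5
#
# An equivalent JSON rendering (same schema) is accepted for ``.json``
# paths or content starting with ``{``.
# ---------------------------------------------------------------------------

def save_energy_matrix(matrix: EnergyMatrix, path) -> None:
    """Write the line-oriented text format (12 significant digits)."""
    space = matrix.space
    lines = [f"STATE {matrix.state_label}" if matrix.state_label else "STATE -"]
    for p, ts in zip(space.positions, space.allowed_types):
        decl = " ".join(f"{t}={space.rotamers_at(p, t)}" for t in ts)
        lines.append(f"POSITION {p} MUTABLE {decl}")
    for p, t in zip(space.flexible_positions, space.flexible_types):
        lines.append(f"POSITION {p} FLEXIBLE {t}={space.rotamers_at(p, t)}")
    for (pos, t, r) in sorted(matrix.diag, key=lambda k: (space.all_positions.index(k[0]), k[1], k[2])):
        lines.append(f"DIAG {pos} {t} {r} {matrix.diag[(pos, t, r)]:.12g}")
    for (a, b) in sorted(
        matrix.pair,
        key=lambda k: (space.all_positions.index(k[0][0]), space.all_positions.index(k[1][0]), k),
    ):
        (i, ti, ri), (j, tj, rj) = a, b
        lines.append(f"PAIR {i} {ti} {ri} {j} {tj} {rj} {matrix.pair[(a, b)]:.12g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_pos_decl(fields, lineno):
    decl = {}
    order = []
    for f in fields:
        if "=" not in f:
            raise MatrixFormatError(f"bad type declaration {f!r}", lineno)
        t, n = f.split("=", 1)
        try:
            decl[t] = int(n)
        except ValueError:
            raise MatrixFormatError(f"bad rotamer count {n!r}", lineno) from None
        order.append(t)
    return order, decl


def _finite_energy(tok, lineno):
    try:
        e = float(tok)
    except ValueError:
        raise MatrixFormatError(f"bad energy {tok!r}", lineno) from None
    if not math.isfinite(e):
        raise MatrixFormatError(f"non-finite energy {tok!r}", lineno)
    return e


def load_energy_matrix(path) -> EnergyMatrix:
    """Load and validate an energy matrix (text or JSON rendering).

    Errors name the offending line/record.
    """
    with open(path) as fh:
        text = fh.read()
    if str(path).endswith(".json") or text.lstrip().startswith("{"):
        return _matrix_from_json(json.loads(text))

    state_label = ""
    mut_pos: list[int] = []
    mut_types: list[list[str]] = []
    flex: dict[int, tuple[str, int]] = {}
    counts: dict[tuple[int, str], int] = {}
    diag_records = []
    pair_records = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        tag = fields[0].upper()
        if tag == "STATE":
            state_label = "" if fields[1:] == ["-"] else " ".join(fields[1:])
        elif tag == "POSITION":
            if len(fields) < 4:
                raise MatrixFormatError("POSITION needs id, kind and types", lineno)
            try:
                pos = int(fields[1])
            except ValueError:
                raise MatrixFormatError(f"bad position id {fields[1]!r}", lineno) from None
            kind = fields[2].upper()
            order, decl = _parse_pos_decl(fields[3:], lineno)
            if kind == "MUTABLE":
                mut_pos.append(pos)
                mut_types.append(order)
                for t, n in decl.items():
                    counts[(pos, t)] = n
            elif kind == "FLEXIBLE":
                if len(order) != 1:
                    raise MatrixFormatError("FLEXIBLE position takes one type", lineno)
                flex[pos] = (order[0], decl[order[0]])
                counts[(pos, order[0])] = decl[order[0]]
            else:
                raise MatrixFormatError(f"unknown position kind {kind!r}", lineno)
        elif tag == "DIAG":
            if len(fields) != 5:
                raise MatrixFormatError("DIAG needs: pos type rotamer energy", lineno)
            diag_records.append((lineno, fields[1:]))
        elif tag == "PAIR":
            if len(fields) != 8:
                raise MatrixFormatError(
                    "PAIR needs: pos type rot pos type rot energy", lineno
                )
            pair_records.append((lineno, fields[1:]))
        else:
            raise MatrixFormatError(f"unknown record {fields[0]!r}", lineno)
    if not mut_pos and not flex:
        raise MatrixFormatError("no POSITION declarations found")
    try:
        space = SequenceSpace(mut_pos, mut_types, counts, flexible=flex)
    except ValueError as exc:
        raise MatrixFormatError(str(exc)) from exc

    def check_index(pos, t, r, lineno):
        if pos not in space.all_positions:
            raise MatrixFormatError(f"undeclared position {pos}", lineno)
        if t not in space.types_at(pos):
            raise MatrixFormatError(f"type {t!r} not declared at position {pos}", lineno)
        if not 0 <= r < space.rotamers_at(pos, t):
            raise MatrixFormatError(
                f"rotamer index {r} exceeds declared count at position {pos} type {t!r}",
                lineno,
            )

    diag = {}
    for lineno, (p, t, r, e) in diag_records:
        try:
            pos, rot = int(p), int(r)
        except ValueError:
            raise MatrixFormatError("bad DIAG indices", lineno) from None
        check_index(pos, t, rot, lineno)
        diag[(pos, t, rot)] = _finite_energy(e, lineno)
    pair = {}
    for lineno, (p1, t1, r1, p2, t2, r2, e) in pair_records:
        try:
            i, ri, j, rj = int(p1), int(r1), int(p2), int(r2)
        except ValueError:
            raise MatrixFormatError("bad PAIR indices", lineno) from None
        check_index(i, t1, ri, lineno)
        check_index(j, t2, rj, lineno)
        if i == j:
            raise MatrixFormatError("PAIR within a single position", lineno)
        pair[((i, t1, ri), (j, t2, rj))] = _finite_energy(e, lineno)
    return EnergyMatrix(space, state_label, diag, pair)


def matrix_to_json(matrix: EnergyMatrix) -> dict:
    space = matrix.space
    return {
        "format": "landflat-energy-matrix",
        "state": matrix.state_label,
        "positions": [
            {
                "id": p,
                "kind": "mutable",
                "types": {t: space.rotamers_at(p, t) for t in ts},
            }
            for p, ts in zip(space.positions, space.allowed_types)
        ]
        + [
            {"id": p, "kind": "flexible", "types": {t: space.rotamers_at(p, t)}}
            for p, t in zip(space.flexible_positions, space.flexible_types)
        ],
        "diag": [[p, t, r, e] for (p, t, r), e in matrix.diag.items()],
        "pair": [
            [i, ti, ri, j, tj, rj, e]
            for ((i, ti, ri), (j, tj, rj)), e in matrix.pair.items()
        ],
    }


def _matrix_from_json(obj: dict) -> EnergyMatrix:
    if obj.get("format") != "landflat-energy-matrix":
        raise MatrixFormatError("not a landflat energy-matrix JSON document")
    known = {"format", "state", "positions", "diag", "pair"}
    extra = set(obj) - known
    if extra:
        raise MatrixFormatError(f"unknown fields {sorted(extra)}")
    mut_pos, mut_types, flex, counts = [], [], {}, {}
    for rec in obj["positions"]:
        pos = int(rec["id"])
        if rec.get("kind", "mutable") == "flexible":
            ((t, n),) = rec["types"].items()
            flex[pos] = (t, int(n))
        else:
            mut_pos.append(pos)
            mut_types.append(list(rec["types"]))
            for t, n in rec["types"].items():
                counts[(pos, t)] = int(n)
    space = SequenceSpace(mut_pos, mut_types, counts, flexible=flex)
    diag = {(int(p), t, int(r)): float(e) for p, t, r, e in obj.get("diag", [])}
    pair = {
        ((int(i), ti, int(ri)), (int(j), tj, int(rj))): float(e)
        for i, ti, ri, j, tj, rj, e in obj.get("pair", [])
    }
    m = EnergyMatrix(space, obj.get("state", ""), diag, pair)
    return m
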