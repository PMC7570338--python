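"""Molecular graphs and lossless I/O for MDL molfile V2000 and a JSON dialect.

A compound is modelled as an undirected labelled graph: atoms are nodes
carrying element, formal charge, stereo parity, isotope offset and 2-D/3-D
coordinates; bonds are edges carrying an integer order (1, 2, 3, or 4 for
aromatic, following the molfile convention) plus stereo annotations.  All
downstream algorithms (aromatic perception, atom coloring, compound
identifiers) operate on :class:`MolecularGraph`.

Internal atom indices are 0-based; the 1-based molfile convention is applied
only at the I/O boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "MolfileError",
    "JsonSchemaError",
    "DEFAULT_VALENCES",
    "parse_molfile",
    "write_molfile",
    "to_json",
    "from_json",
    "add_implicit_hydrogens",
]

#: Tokens accepted as generic R-group placeholders.  They are kept verbatim as
#: element symbols and participate in coloring; they are never expanded.
R_GROUP_TOKENS = frozenset({"R", "R#", "*", "X"})

#: Default valences used when adding implicit hydrogens.  The molfile format
#: does not carry this information, so the table is a package decision
#: (documented in docs/methods.md).
DEFAULT_VALENCES = {
    "H": 1,
    "B": 3,
    "C": 4,
    "N": 3,
    "O": 2,
    "F": 1,
    "Si": 4,
    "P": 3,
    "S": 2,
    "Cl": 1,
    "Br": 1,
    "I": 1,
}

# molfile charge-column code -> formal charge ("M  CHG" overrides these)
_CHARGE_CODES = {0: 0, 1: 3, 2: 2, 3: 1, 4: 0, 5: -1, 6: -2, 7: -3}


class MolfileError(ValueError):
    """Raised for malformed molfile input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class JsonSchemaError(ValueError):
    """Raised when a JSON document does not follow the graph dialect."""


@dataclass
class Atom:
    index: int
    element: str
    charge: int = 0
    stereo_parity: int = 0
    mass_delta: int = 0
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    is_aromatic: bool = False

    def copy(self) -> "Atom":
        return replace(self)


@dataclass
class Bond:
    a: int
    b: int
    order: int = 1
    wedge: int = 0
    cis_trans: str | None = None  # "cis" | "trans" | None

    def copy(self) -> "Bond":
        return replace(self)

    def other(self, idx: int) -> int:
        if idx == self.a:
            return self.b
        if idx == self.b:
            return self.a
        raise ValueError(f"atom {idx} is not an endpoint of bond {self.a}-{self.b}")

    @property
    def key(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


class MolecularGraph:
    """Atoms + bonds + a symmetric adjacency map.

    ``adjacency[i]`` is a dict mapping neighbor index -> the connecting
    :class:`Bond` object, kept exactly consistent with ``bonds``.
    """

    def __init__(
        self,
        atoms: Iterable[Atom] = (),
        bonds: Iterable[Bond] = (),
        source_id: str = "",
    ):
        self.atoms: list[Atom] = list(atoms)
        self.bonds: list[Bond] = []
        self.adjacency: dict[int, dict[int, Bond]] = {a.index: {} for a in self.atoms}
        self.source_id = source_id
        for b in bonds:
            self.add_bond(b)

    # -- construction -------------------------------------------------------

    def add_atom(self, atom: Atom) -> Atom:
        if atom.index in self.adjacency:
            raise ValueError(f"duplicate atom index {atom.index}")
        self.atoms.append(atom)
        self.adjacency[atom.index] = {}
        return atom

    def add_bond(self, bond: Bond) -> Bond:
        if bond.a == bond.b:
            raise ValueError(f"self-bond on atom {bond.a}")
        for end in (bond.a, bond.b):
            if end not in self.adjacency:
                raise ValueError(f"bond references nonexistent atom {end}")
        if bond.b in self.adjacency[bond.a]:
            raise ValueError(f"duplicate bond {bond.a}-{bond.b}")
        self.bonds.append(bond)
        self.adjacency[bond.a][bond.b] = bond
        self.adjacency[bond.b][bond.a] = bond
        return bond

    # -- queries -------------------------------------------------------------

    def atom(self, idx: int) -> Atom:
        a = self.atoms[idx]
        if a.index == idx:
            return a
        for a in self.atoms:  # pragma: no cover - non-contiguous indices
            if a.index == idx:
                return a
        raise KeyError(idx)

    def bond(self, i: int, j: int) -> Bond:
        return self.adjacency[i][j]

    def neighbors(self, idx: int) -> Iterator[int]:
        return iter(self.adjacency[idx])

    def __len__(self) -> int:
        return len(self.atoms)

    def check_consistency(self) -> None:
        """Assert the adjacency map mirrors the bond list exactly."""
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if self.adjacency[b.a].get(b.b) is not b or self.adjacency[b.b].get(b.a) is not b:
                raise AssertionError(f"adjacency inconsistent for bond {b.a}-{b.b}")
            if b.key in seen:
                raise AssertionError(f"duplicate bond {b.key}")
            seen.add(b.key)
        n_adj = sum(len(nbrs) for nbrs in self.adjacency.values())
        if n_adj != 2 * len(self.bonds):
            raise AssertionError("adjacency entry count does not match bond count")

    def copy(self) -> "MolecularGraph":
        return MolecularGraph(
            (a.copy() for a in self.atoms),
            (b.copy() for b in self.bonds),
            self.source_id,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularGraph):
            return NotImplemented
        return to_json(self) == to_json(other)

    def __repr__(self) -> str:
        return (
            f"MolecularGraph(source_id={self.source_id!r}, "
            f"n_atoms={len(self.atoms)}, n_bonds={len(self.bonds)})"
        )


# ---------------------------------------------------------------------------
# molfile V2000 I/O
# ---------------------------------------------------------------------------


def parse_molfile(text: str, source_id: str = "") -> MolecularGraph:
    """Parse an MDL molfile V2000 document into a :class:`MolecularGraph`.

    The counts line fixes the atom/bond block sizes; ``M  CHG`` and ``M  ISO``
    property lines override the atom-block charge and mass-difference columns
    (per the molfile standard, the presence of any ``M  CHG`` line resets all
    atom-block charges first).  V3000 documents are rejected.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileError("document too short: no counts line", line=len(lines))
    counts_line_no = 4  # 1-based: three header lines, then counts
    counts = lines[3]
    if "V3000" in counts:
        raise MolfileError("V3000 molfiles are not supported", line=counts_line_no)
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise MolfileError(f"malformed counts line: {counts!r}", line=counts_line_no) from None
    if n_atoms < 0 or n_bonds < 0:
        raise MolfileError(f"negative counts: {counts!r}", line=counts_line_no)

    g = MolecularGraph(source_id=source_id or (lines[0].strip() if lines[0].strip() else ""))

    atom_start = 4
    for i in range(n_atoms):
        ln = atom_start + i
        if ln >= len(lines):
            raise MolfileError("truncated atom block", line=ln + 1)
        row = lines[ln]
        try:
            x = float(row[0:10])
            y = float(row[10:20])
            z = float(row[20:30])
            element = row[31:34].strip()
            mass_delta = int(row[34:36]) if row[34:36].strip() else 0
            charge_code = int(row[36:39]) if row[36:39].strip() else 0
            parity = int(row[39:42]) if len(row) > 39 and row[39:42].strip() else 0
        except ValueError:
            raise MolfileError(f"malformed atom line: {row!r}", line=ln + 1) from None
        if not element:
            raise MolfileError("empty element symbol", line=ln + 1)
        g.add_atom(
            Atom(
                index=i,
                element=element,
                charge=_CHARGE_CODES.get(charge_code, 0),
                stereo_parity=parity,
                mass_delta=mass_delta,
                x=x,
                y=y,
                z=z,
            )
        )

    bond_start = atom_start + n_atoms
    for i in range(n_bonds):
        ln = bond_start + i
        if ln >= len(lines):
            raise MolfileError("truncated bond block", line=ln + 1)
        row = lines[ln]
        try:
            a = int(row[0:3])
            b = int(row[3:6])
            order = int(row[6:9])
            wedge = int(row[9:12]) if len(row) > 9 and row[9:12].strip() else 0
        except ValueError:
            raise MolfileError(f"malformed bond line: {row!r}", line=ln + 1) from None
        if not (1 <= a <= n_atoms) or not (1 <= b <= n_atoms):
            raise MolfileError(
                f"bond references atom {max(a, b)} but only {n_atoms} atoms declared",
                line=ln + 1,
            )
        try:
            g.add_bond(Bond(a=a - 1, b=b - 1, order=order, wedge=wedge))
        except ValueError as exc:
            raise MolfileError(str(exc), line=ln + 1) from None

    # property block
    saw_chg = False
    saw_end = False
    for off, row in enumerate(lines[bond_start + n_bonds:]):
        ln = bond_start + n_bonds + off + 1
        if row.startswith("M  END"):
            saw_end = True
            break
        if row.startswith("M  CHG") or row.startswith("M  ISO"):
            tag = row[3:6]
            try:
                count = int(row[6:9])
                fields = row[9:].split()
                pairs = [(int(fields[2 * k]), int(fields[2 * k + 1])) for k in range(count)]
            except (ValueError, IndexError):
                raise MolfileError(f"malformed property line: {row!r}", line=ln) from None
            if tag == "CHG" and not saw_chg:
                # property-block charges supersede the atom-block column
                for atom in g.atoms:
                    atom.charge = 0
                saw_chg = True
            for one_based, value in pairs:
                if not (1 <= one_based <= n_atoms):
                    raise MolfileError(f"property references atom {one_based}", line=ln)
                atom = g.atom(one_based - 1)
                if tag == "CHG":
                    atom.charge = value
                else:
                    atom.mass_delta = value
    if not saw_end:
        raise MolfileError("missing 'M  END' terminator", line=len(lines))
    g.check_consistency()
    return g


def write_molfile(g: MolecularGraph, title: str | None = None) -> str:
    """Serialize a graph back to molfile V2000 text.

    Charges and isotope offsets are emitted as ``M  CHG`` / ``M  ISO``
    property lines (the modern convention), so ``parse_molfile(write_molfile(g))``
    reproduces ``g`` exactly.  Atoms must have contiguous 0-based indices.
    """
    order = sorted(g.atoms, key=lambda a: a.index)
    pos = {a.index: k for k, a in enumerate(order)}
    lines = [title if title is not None else g.source_id, "  molcolor", ""]
    lines.append(f"{len(order):3d}{len(g.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for a in order:
        lines.append(
            f"{a.x:10.4f}{a.y:10.4f}{a.z:10.4f} {a.element:<3s} 0  0{a.stereo_parity:3d}"
            "  0  0  0  0  0  0  0  0  0"
        )
    for b in sorted(g.bonds, key=lambda b: (pos[b.a], pos[b.b])):
        lines.append(f"{pos[b.a] + 1:3d}{pos[b.b] + 1:3d}{b.order:3d}{b.wedge:3d}  0  0  0")
    charged = [(pos[a.index] + 1, a.charge) for a in order if a.charge]
    for k in range(0, len(charged), 8):
        chunk = charged[k:k + 8]
        lines.append(
            f"M  CHG{len(chunk):3d}" + "".join(f"{i:4d}{v:4d}" for i, v in chunk)
        )
    iso = [(pos[a.index] + 1, a.mass_delta) for a in order if a.mass_delta]
    for k in range(0, len(iso), 8):
        chunk = iso[k:k + 8]
        lines.append(
            f"M  ISO{len(chunk):3d}" + "".join(f"{i:4d}{v:4d}" for i, v in chunk)
        )
    lines.append("M  END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# JSON dialect (documented in docs/graph_json.md)
# ---------------------------------------------------------------------------

_ATOM_FIELDS = {
    "index": int,
    "element": str,
    "charge": int,
    "stereo_parity": int,
    "mass_delta": int,
    "x": float,
    "y": float,
    "z": float,
    "is_aromatic": bool,
}
_BOND_FIELDS = {"a": int, "b": int, "order": int, "wedge": int, "cis_trans": (str, type(None))}


def to_json(g: MolecularGraph, indent: int | None = None) -> str:
    """Canonical JSON serialization: atoms ordered by index, bonds by
    endpoint pair, so graph equality is insensitive to listing order."""
    doc = {
        "source_id": g.source_id,
        "atoms": [
            {
                "index": a.index,
                "element": a.element,
                "charge": a.charge,
                "stereo_parity": a.stereo_parity,
                "mass_delta": a.mass_delta,
                "x": a.x,
                "y": a.y,
                "z": a.z,
                "is_aromatic": a.is_aromatic,
            }
            for a in sorted(g.atoms, key=lambda a: a.index)
        ],
        "bonds": [
            {
                # endpoint order is semantic for wedge bonds, so a/b are
                # emitted as stored; only the listing order is canonicalized
                "a": b.a,
                "b": b.b,
                "order": b.order,
                "wedge": b.wedge,
                "cis_trans": b.cis_trans,
            }
            for b in sorted(g.bonds, key=lambda b: b.key)
        ],
    }
    return json.dumps(doc, indent=indent, sort_keys=True)


def _check(doc: dict, key: str, types, where: str):
    if key not in doc:
        raise JsonSchemaError(f"{where}: missing required key {key!r}")
    if not isinstance(doc[key], types):
        raise JsonSchemaError(
            f"{where}: key {key!r} has type {type(doc[key]).__name__}, "
            f"expected {types}"
        )
    return doc[key]


def from_json(text: str) -> MolecularGraph:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise JsonSchemaError(f"not valid JSON: {exc}") from None
    if not isinstance(doc, dict):
        raise JsonSchemaError("top-level document must be an object")
    for key in ("atoms", "bonds"):
        _check(doc, key, list, "document")
    g = MolecularGraph(source_id=doc.get("source_id", ""))
    for k, rec in enumerate(doc["atoms"]):
        if not isinstance(rec, dict):
            raise JsonSchemaError(f"atoms[{k}] is not an object")
        g.add_atom(
            Atom(
                index=_check(rec, "index", int, f"atoms[{k}]"),
                element=_check(rec, "element", str, f"atoms[{k}]"),
                charge=rec.get("charge", 0),
                stereo_parity=rec.get("stereo_parity", 0),
                mass_delta=rec.get("mass_delta", 0),
                x=float(rec.get("x", 0.0)),
                y=float(rec.get("y", 0.0)),
                z=float(rec.get("z", 0.0)),
                is_aromatic=bool(rec.get("is_aromatic", False)),
            )
        )
    for k, rec in enumerate(doc["bonds"]):
        if not isinstance(rec, dict):
            raise JsonSchemaError(f"bonds[{k}] is not an object")
        try:
            g.add_bond(
                Bond(
                    a=_check(rec, "a", int, f"bonds[{k}]"),
                    b=_check(rec, "b", int, f"bonds[{k}]"),
                    order=rec.get("order", 1),
                    wedge=rec.get("wedge", 0),
                    cis_trans=rec.get("cis_trans"),
                )
            )
        except ValueError as exc:
            raise JsonSchemaError(f"bonds[{k}]: {exc}") from None
    g.check_consistency()
    return g


# ---------------------------------------------------------------------------
# implicit hydrogens
# ---------------------------------------------------------------------------


def _effective_valence(atom: Atom) -> int:
    """Default valence adjusted for formal charge.

    Lone-pair-bearing elements (N, O, S, P, halogens) gain a bond per positive
    charge and lose one per negative charge (N+ binds 4, O- binds 1).  Carbon
    loses a bond for either charge sign (carbanion and carbenium both bind 3).
    Boron behaves oppositely to N/O (borate B- binds 4).
    """
    if atom.element not in DEFAULT_VALENCES:
        raise ValueError(
            f"no default valence known for element {atom.element!r}; "
            "cannot add implicit hydrogens"
        )
    v = DEFAULT_VALENCES[atom.element]
    if atom.element == "C":
        return v - abs(atom.charge)
    if atom.element == "B":
        return v - atom.charge
    return v + atom.charge


def add_implicit_hydrogens(g: MolecularGraph) -> MolecularGraph:
    """Return a copy of ``g`` with explicit hydrogens appended to heavy atoms.

    Each heavy atom receives ``max(0, effective_valence - bond order sum)``
    hydrogens.  Aromatic bonds (order 4) count 1.5 toward the sum, floored per
    atom after summation, which reproduces one hydrogen per aromatic CH carbon
    without Kekulé information.  Original atom indices are unchanged;
    hydrogens are appended after all existing atoms, so the operation is
    idempotent (a saturated atom gains nothing on a second pass).  Hydrogens
    are placed at a small fixed offset from their parent; their coordinates
    never enter stereo perception, which only considers heavy substituents.
    """
    out = g.copy()
    next_idx = max((a.index for a in out.atoms), default=-1) + 1
    for atom in list(out.atoms):
        if atom.element == "H" or atom.element in R_GROUP_TOKENS:
            continue
        total = 0.0
        for nbr, bond in out.adjacency[atom.index].items():
            total += 1.5 if bond.order == 4 else bond.order
        n_h = max(0, _effective_valence(atom) - int(total))
        for k in range(n_h):
            h = Atom(
                index=next_idx,
                element="H",
                x=atom.x + 0.3 + 0.1 * k,
                y=atom.y + 0.3,
                z=atom.z,
            )
            out.add_atom(h)
            out.add_bond(Bond(a=atom.index, b=next_idx, order=1))
            next_idx += 1
    out.check_consistency()
    return out
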