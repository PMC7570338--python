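"""Structural normalization before coloring.

Databases draw the same compound differently: aromatic rings appear with
alternating single/double (Kekulé) bonds placed arbitrarily, and double-bond
cis/trans geometry is implicit in the 2-D drawing.  This module makes
equivalent drawings render identical graphs:

* aromatic substructures are found by subgraph-isomorphism against a library
  of reference fragments (Kekulé-insensitive matching), optionally augmented
  by a heuristic that pulls ring O/S atoms into otherwise-aromatic rings;
* all bonds inside a detected (fused) aromatic system are rewritten to the
  aromatic order 4;
* acyclic C=C double bonds get an explicit cis/trans label computed from the
  2-D coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
from networkx.algorithms import isomorphism

from .coloring import ColoringConfig, zero_layer_color
from .molgraph import Bond, MolecularGraph, parse_molfile

__all__ = [
    "AromaticSubstructure",
    "ReferenceLibrary",
    "extract_labeled_substructures",
    "detect_by_reference",
    "detect_heuristic",
    "normalize_aromatic_bonds",
    "assign_double_bond_stereo",
    "normalize_compound",
]

#: bond orders treated as interchangeable when matching reference fragments,
#: so Kekulé (1/2) and aromatic (4) drawings of the same ring all match
_KEKULE_EQUIVALENT = frozenset({1, 2, 4})


@dataclass
class AromaticSubstructure:
    """One fused aromatic system: an induced fragment of a parent graph.

    ``fragment`` keeps the parent's atom indices; every fragment bond lies on
    a ring of the fragment (bridge bonds between ring systems are excluded).
    ``origin`` records provenance: a reference-library id or ``"heuristic"``.
    """

    fragment: MolecularGraph
    origin: str = "heuristic"

    @property
    def atom_indices(self) -> frozenset[int]:
        return frozenset(a.index for a in self.fragment.atoms)

    def __len__(self) -> int:
        return len(self.fragment.atoms)


def _to_networkx(g: MolecularGraph) -> nx.Graph:
    nxg = nx.Graph()
    for a in g.atoms:
        nxg.add_node(a.index, element=a.element)
    for b in g.bonds:
        nxg.add_edge(b.a, b.b, order=b.order)
    return nxg


def _ring_fragments(g: MolecularGraph, atom_set: set[int], origin: str) -> list[AromaticSubstructure]:
    """Induced subgraphs on ``atom_set``, split at bonds lying on no ring.

    Dropping bridge bonds enforces the fragment invariant (every bond is part
    of a ring) and keeps e.g. the two rings of biphenyl as separate fragments
    while fused ring systems stay connected through their shared atoms.
    """
    if not atom_set:
        return []
    sub = _to_networkx(g).subgraph(atom_set).copy()
    sub.remove_edges_from(list(nx.bridges(sub)))
    sub.remove_nodes_from([n for n in list(sub.nodes) if sub.degree[n] == 0])
    frags = []
    for comp in nx.connected_components(sub):
        comp = set(comp)
        fragment = MolecularGraph(
            (g.atom(i).copy() for i in sorted(comp)),
            (
                b.copy()
                for b in g.bonds
                if b.a in comp and b.b in comp and sub.has_edge(b.a, b.b)
            ),
            source_id=g.source_id,
        )
        frags.append(AromaticSubstructure(fragment=fragment, origin=origin))
    frags.sort(key=lambda f: min(f.atom_indices))
    return frags


def extract_labeled_substructures(
    g: MolecularGraph, aromatic_atoms: set[int]
) -> list[AromaticSubstructure]:
    """Fused aromatic systems induced by a set of externally labelled atoms.

    This mirrors how curated per-atom aromaticity annotations (KCF-style) are
    turned into reference fragments: the induced subgraph on the labelled
    atoms, with connected fused ring systems emitted as single fragments.
    """
    unknown = aromatic_atoms - {a.index for a in g.atoms}
    if unknown:
        raise ValueError(f"labelled atoms not in graph: {sorted(unknown)}")
    return _ring_fragments(g, set(aromatic_atoms), origin="labeled")


class ReferenceLibrary:
    """Deduplicated collection of reference aromatic fragments.

    Entries are deduplicated by their loose compound coloring identifier, so
    the same ring system contributed twice (possibly in different Kekulé
    drawings, after normalization) is stored once.
    """

    def __init__(self, entries: "list[AromaticSubstructure] | None" = None):
        self.entries: list[AromaticSubstructure] = []
        self._keys: set[str] = set()
        for e in entries or []:
            self.add(e)

    def add(self, sub: AromaticSubstructure) -> bool:
        from .identifiers import compound_identifier
        from .coloring import color_compound

        frag = normalize_aromatic_bonds(
            sub.fragment, [AromaticSubstructure(sub.fragment, sub.origin)]
        )
        key = compound_identifier(
            color_compound(frag, ColoringConfig.loose()), mode="loose"
        ).text
        if key in self._keys:
            return False
        self._keys.add(key)
        self.entries.append(AromaticSubstructure(fragment=frag, origin=sub.origin))
        return True

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_directory(cls, path: str | Path) -> "ReferenceLibrary":
        lib = cls()
        for mol in sorted(Path(path).glob("*.mol")):
            g = parse_molfile(mol.read_text(), source_id=mol.stem)
            lib.add(AromaticSubstructure(fragment=g, origin=mol.stem))
        if not lib.entries:
            raise ValueError(f"no .mol fragments found in {path}")
        return lib

    @classmethod
    def default(cls) -> "ReferenceLibrary":
        """Small bundled library (benzene, pyridine, pyrrole, furan,
        thiophene, imidazole, naphthalene) for tests and examples."""
        lib = cls()
        root = resources.files("molcolor").joinpath("data/aromatic_library")
        for entry in sorted(root.iterdir(), key=lambda p: p.name):
            if entry.name.endswith(".mol"):
                g = parse_molfile(entry.read_text(), source_id=entry.name[:-4])
                lib.add(AromaticSubstructure(fragment=g, origin=entry.name[:-4]))
        return lib


def _kekule_edge_match(e1: dict, e2: dict) -> bool:
    o1, o2 = e1["order"], e2["order"]
    return o1 == o2 or (o1 in _KEKULE_EQUIVALENT and o2 in _KEKULE_EQUIVALENT)


def detect_by_reference(
    g: MolecularGraph, lib: ReferenceLibrary
) -> list[AromaticSubstructure]:
    """Find every embedding of a library fragment in ``g``.

    Matching is induced subgraph isomorphism (VF2) with exact element
    compatibility; bond orders compare under the {1, 2, aromatic}
    equivalence so any Kekulé placement matches the stored fragment.  To keep
    saturated rings from matching (a single-bonded C6 ring is not benzene),
    every carbon of an embedding must carry at least one double or aromatic
    bond somewhere in the host — true of all Kekulé and aromatic drawings,
    including quinoid carbons with exocyclic doubles.  Overlapping and fused
    matches are merged into maximal fragments.
    """
    if not len(lib):
        raise ValueError("reference library is empty")
    host = _to_networkx(g)

    def carbon_unsaturated(i: int) -> bool:
        if g.atom(i).element != "C":
            return True
        return any(b.order in (2, 4) for b in g.adjacency[i].values())

    matched: set[int] = set()
    origins: list[str] = []
    for entry in lib.entries:
        pattern = _to_networkx(entry.fragment)
        gm = isomorphism.GraphMatcher(
            host,
            pattern,
            node_match=lambda n1, n2: n1["element"] == n2["element"],
            edge_match=_kekule_edge_match,
        )
        hit = False
        for mapping in gm.subgraph_isomorphisms_iter():
            if not all(carbon_unsaturated(i) for i in mapping):
                continue
            matched.update(mapping.keys())
            hit = True
        if hit:
            origins.append(entry.origin)
    origin = "+".join(origins) if origins else "reference"
    return _ring_fragments(g, matched, origin=origin)


def detect_heuristic(
    g: MolecularGraph, aromatic_atoms: set[int] | None = None, max_ring: int = 8
) -> list[AromaticSubstructure]:
    """Pull ring oxygen/sulfur atoms into otherwise-aromatic rings.

    Curated per-atom aromaticity annotations lack O/S aromatic types, so a
    furan- or thiophene-like ring arrives with its carbons labelled aromatic
    but not its heteroatom.  For each small ring (size <= ``max_ring``, from a
    minimum cycle basis) containing O or S in which *every* other member is an
    already aromatic-labelled C or N, the O/S atoms are marked aromatic and
    the ring emitted as a fragment.  Rings whose carbons carry no aromatic
    label (e.g. a 1,4-dioxin bridging two aromatic rings) are left alone.
    """
    labelled = set(aromatic_atoms) if aromatic_atoms is not None else {
        a.index for a in g.atoms if a.is_aromatic
    }
    nxg = _to_networkx(g)
    out: list[AromaticSubstructure] = []
    for ring in nx.minimum_cycle_basis(nxg):
        if len(ring) > max_ring:
            continue
        ring_set = set(ring)
        os_atoms = {i for i in ring_set if g.atom(i).element in ("O", "S")}
        if not os_atoms:
            continue
        rest = ring_set - os_atoms
        if rest and all(
            g.atom(i).element in ("C", "N") and i in labelled for i in rest
        ):
            for i in os_atoms:
                g.atom(i).is_aromatic = True
            out.extend(_ring_fragments(g, ring_set, origin="heuristic"))
    return out


def normalize_aromatic_bonds(
    g: MolecularGraph, frags: list[AromaticSubstructure]
) -> MolecularGraph:
    """Rewrite every bond interior to an aromatic fragment to order 4.

    Endpoint atoms are flagged aromatic; all other bonds are untouched.
    Idempotent, and independent of which Kekulé drawing the input used —
    this is what gives every drawing of an aromatic compound one graph and
    hence one compound identifier.
    """
    out = g.copy()
    for frag in frags:
        for fb in frag.fragment.bonds:
            bond = out.adjacency.get(fb.a, {}).get(fb.b)
            if bond is None:
                raise ValueError(f"fragment bond {fb.a}-{fb.b} not present in graph")
            bond.order = 4
            out.atom(fb.a).is_aromatic = True
            out.atom(fb.b).is_aromatic = True
    return out


# ---------------------------------------------------------------------------
# double-bond cis/trans labelling from 2-D geometry
# ---------------------------------------------------------------------------

_LOOSE = ColoringConfig.loose()


def _reference_substituent(g: MolecularGraph, end: int, partner: int) -> int | None:
    """Heavy substituent used as the geometric reference on one end of a
    double bond: lowest loose 0_layer string, ties broken by lowest index."""
    cands = [
        n
        for n in g.adjacency[end]
        if n != partner and g.atom(n).element != "H"
    ]
    if not cands:
        return None
    return min(cands, key=lambda n: (zero_layer_color(g.atom(n), _LOOSE), n))


def assign_double_bond_stereo(g: MolecularGraph) -> MolecularGraph:
    """Label acyclic C=C-style double bonds cis/trans from 2-D coordinates.

    For each non-ring order-2 bond whose two ends each carry at least one
    heavy substituent besides the partner, the reference substituent is
    chosen on each end and the sign of the 2-D cross product of each
    substituent vector with the bond axis compared: same sign means both
    references sit on the same side (cis), opposite signs trans, and nearly
    collinear geometry (|cross| < 1e-6 after unit normalization) yields no
    label.  Requires meaningful coordinates.
    """
    if g.bonds and all(a.x == 0.0 and a.y == 0.0 for a in g.atoms):
        raise ValueError(
            "all coordinates are zero; supply 2-D geometry before assigning "
            "double-bond stereo"
        )
    out = g.copy()
    bridges = set()
    nxg = _to_networkx(out)
    ring_edges = set()
    for ring in nx.cycle_basis(nxg):
        for i in range(len(ring)):
            e = tuple(sorted((ring[i], ring[(i + 1) % len(ring)])))
            ring_edges.add(e)
    for bond in out.bonds:
        if bond.order != 2 or bond.key in ring_edges:
            continue
        sa = _reference_substituent(out, bond.a, bond.b)
        sb = _reference_substituent(out, bond.b, bond.a)
        if sa is None or sb is None:
            continue
        ax, ay = out.atom(bond.a).x, out.atom(bond.a).y
        bx, by = out.atom(bond.b).x, out.atom(bond.b).y
        dx, dy = bx - ax, by - ay
        norm = math.hypot(dx, dy)
        if norm < 1e-12:
            continue
        dx, dy = dx / norm, dy / norm

        def side(sub: int, ox: float, oy: float) -> float:
            vx, vy = out.atom(sub).x - ox, out.atom(sub).y - oy
            n = math.hypot(vx, vy)
            if n < 1e-12:
                return 0.0
            return dx * (vy / n) - dy * (vx / n)

        ca = side(sa, ax, ay)
        cb = side(sb, bx, by)
        if abs(ca) < 1e-6 or abs(cb) < 1e-6:
            bond.cis_trans = None
        elif (ca > 0) == (cb > 0):
            bond.cis_trans = "cis"
        else:
            bond.cis_trans = "trans"
    return out


def normalize_compound(
    g: MolecularGraph,
    lib: ReferenceLibrary | None = None,
    heuristic: bool = True,
    bond_stereo: bool = False,
) -> MolecularGraph:
    """Reference detection + O/S heuristic + aromatic bond normalization,
    optionally followed by cis/trans labelling; the standard preprocessing
    before coloring."""
    lib = lib or ReferenceLibrary.default()
    frags = detect_by_reference(g, lib)
    out = normalize_aromatic_bonds(g, frags)
    if heuristic:
        frags2 = detect_heuristic(out)
        out = normalize_aromatic_bonds(out, frags2)
    if bond_stereo:
        out = assign_double_bond_stereo(out)
    return out
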