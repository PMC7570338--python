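"""Neighborhood-specific graph coloring of atoms.

Every atom receives an identifier string accumulated from its own chemical
information (the ``0_layer``) plus successively wider breadth-first shells of
neighbor information.  Two atoms end up with the same identifier exactly when
they are symmetric, i.e. lie in the same orbit of the molecular graph's
automorphism group (restricted to the chemical layers that are switched on).

The pipeline is: :func:`color_atoms` (BFS name extension), then
:func:`validate_symmetry` (layer-by-layer neighborhood comparison of atoms
sharing an identifier), then :func:`recolor` (re-extension of flagged
pseudosymmetric atoms using full identifiers instead of 0_layer strings).
:func:`color_compound` chains them and guarantees a symmetry-consistent map.

Which chemistry enters the strings is controlled by :class:`ColoringConfig`:
the *loose* preset keeps only atom type and bond type, absorbing
cross-database representation differences in charge/stereo/isotope
annotation; the *tight* preset switches every layer on.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from .molgraph import Atom, MolecularGraph

__all__ = [
    "ColoringConfig",
    "AtomColorMap",
    "SymmetryReport",
    "ColoringError",
    "zero_layer_color",
    "bond_token",
    "color_atoms",
    "validate_symmetry",
    "recolor",
    "color_compound",
    "color_hash",
    "symmetry_orbits_oracle",
]

_BOND_TOKENS = {1: "-", 2: "=", 3: "#", 4: ":"}
_CIS_TRANS_TOKENS = {"cis": "/c", "trans": "/t"}


class ColoringError(RuntimeError):
    """Raised when validation/recoloring cannot reach a symmetry-consistent map."""


@dataclass(frozen=True)
class ColoringConfig:
    """Chemical information layers included in atom color strings.

    ``use_atom_type`` is always on (an identifier without the element would be
    meaningless).  ``min_rounds`` BFS expansion rounds are applied to every
    atom before the uniqueness check; ``max_rounds`` caps total rounds and
    exists for diagnostics/testing only (``None`` = unbounded).
    """

    use_bond_type: bool = True
    use_charge: bool = False
    use_atom_stereo: bool = False
    use_bond_stereo: bool = False
    use_isotope: bool = False
    include_hydrogen: bool = False
    min_rounds: int = 3
    max_rounds: int | None = None

    use_atom_type: bool = field(default=True, init=False)

    @staticmethod
    def loose(**kw) -> "ColoringConfig":
        """Atom type + bond type only: the cross-database harmonization preset."""
        return ColoringConfig(**kw)

    @staticmethod
    def tight(**kw) -> "ColoringConfig":
        """All chemical layers on (charge, atom/bond stereo, isotope)."""
        return ColoringConfig(
            use_charge=True,
            use_atom_stereo=True,
            use_bond_stereo=True,
            use_isotope=True,
            **kw,
        )

    @property
    def mode(self) -> str:
        tight = ColoringConfig.tight(
            include_hydrogen=self.include_hydrogen,
            min_rounds=self.min_rounds,
            max_rounds=self.max_rounds,
        )
        return "tight" if self == tight else "loose"


@dataclass
class AtomColorMap:
    """Output of the coloring algorithm.

    ``zero_layer`` maps atom index -> the atom's own-information string;
    ``full`` maps atom index -> the accumulated identifier.  Atoms share a
    ``full`` string iff they are in the same symmetry class (after the
    validate/recolor pipeline has finished).
    """

    zero_layer: dict[int, str]
    full: dict[int, str]
    rounds_used: int = 0

    def classes(self) -> list[frozenset[int]]:
        """Partition of colorable atoms by full identifier."""
        by_color: dict[str, set[int]] = {}
        for idx, color in self.full.items():
            by_color.setdefault(color, set()).add(idx)
        return sorted((frozenset(v) for v in by_color.values()), key=min)

    def copy(self) -> "AtomColorMap":
        return AtomColorMap(dict(self.zero_layer), dict(self.full), self.rounds_used)


@dataclass
class SymmetryReport:
    groups: list[frozenset[int]]
    invalid_groups: list[frozenset[int]]

    @property
    def ok(self) -> bool:
        return not self.invalid_groups


# ---------------------------------------------------------------------------
# string building blocks
# ---------------------------------------------------------------------------


def zero_layer_color(atom: Atom, cfg: ColoringConfig) -> str:
    """The atom's own-information string under ``cfg``.

    Fields appear in the fixed order element | charge | atom stereo | isotope;
    disabled or zero-valued fields are omitted.  The markers (``+/-``, ``@``,
    ``*``) cannot occur inside element symbols, so the encoding is injective
    over the enabled layers.
    """
    s = atom.element
    if cfg.use_charge and atom.charge:
        s += f"{atom.charge:+d}"
    if cfg.use_atom_stereo and atom.stereo_parity:
        s += f"@{atom.stereo_parity}"
    if cfg.use_isotope and atom.mass_delta:
        s += f"*{atom.mass_delta:+d}"
    return s


def bond_token(bond, cfg: ColoringConfig) -> str:
    """Bond descriptor contributed to layer strings (empty if bond type is off)."""
    if not cfg.use_bond_type:
        return ""
    tok = _BOND_TOKENS.get(bond.order, str(bond.order))
    if cfg.use_bond_stereo and bond.cis_trans in _CIS_TRANS_TOKENS:
        tok += _CIS_TRANS_TOKENS[bond.cis_trans]
    return tok


def color_hash(identifier: str) -> str:
    """Stable short digest of an identifier, for display/indexing only.

    Equality of identifiers is always defined on the full strings; this is
    sha256 truncated to 16 hex characters.
    """
    return hashlib.sha256(identifier.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# BFS machinery
# ---------------------------------------------------------------------------


class _Expansion:
    """Per-atom BFS state: visited set and current frontier.

    The frontier at round r holds the atoms at distance r from the start (in
    the hydrogen-filtered graph).  For each frontier member the connecting
    bond descriptor is the lexicographically smallest token among its bonds
    into the visited set — deterministic and invariant under atom relabeling.
    """

    def __init__(self, g: MolecularGraph, start: int, colorable: set[int]):
        self.g = g
        self.colorable = colorable
        self.visited = {start}
        self.frontier = sorted(n for n in g.adjacency[start] if n in colorable)

    def layer_items(self, tokens: dict[int, str], cfg: ColoringConfig) -> list[str]:
        """Sorted (bond descriptor + token) strings for the current frontier."""
        items = []
        for f in self.frontier:
            tok = min(
                bond_token(self.g.adjacency[f][v], cfg)
                for v in self.g.adjacency[f]
                if v in self.visited
            )
            items.append(tok + tokens[f])
        items.sort()
        return items

    def advance(self) -> None:
        new_visited = self.visited | set(self.frontier)
        nxt: set[int] = set()
        for f in self.frontier:
            for n in self.g.adjacency[f]:
                if n in self.colorable and n not in new_visited:
                    nxt.add(n)
        self.visited = new_visited
        self.frontier = sorted(nxt)

    @property
    def exhausted(self) -> bool:
        return not self.frontier


def _colorable_atoms(g: MolecularGraph, cfg: ColoringConfig) -> set[int]:
    return {
        a.index
        for a in g.atoms
        if cfg.include_hydrogen or a.element != "H"
    }


def _layer_string(items: list[str]) -> str:
    return "(" + ",".join(items) + ")"


def color_atoms(g: MolecularGraph, cfg: ColoringConfig | None = None) -> AtomColorMap:
    """Run the BFS name-extension coloring for every colorable atom.

    Each atom starts from its 0_layer string; each round appends a bracketed,
    lexicographically sorted layer of (bond descriptor, neighbor 0_layer)
    pairs drawn from the current BFS frontier, then advances the frontier to
    unvisited neighbors-of-frontier.  ``cfg.min_rounds`` rounds are applied to
    all atoms; afterwards only atoms whose identifier is still shared keep
    extending, until every identifier is unique or the frontier is exhausted
    (every atom of the component has entered the name).
    """
    cfg = cfg or ColoringConfig.loose()
    colorable = _colorable_atoms(g, cfg)
    zero = {i: zero_layer_color(g.atom(i), cfg) for i in colorable}
    ident = dict(zero)
    state = {i: _Expansion(g, i, colorable) for i in colorable}

    rounds = 0

    def extend(targets) -> bool:
        nonlocal rounds
        progressed = False
        for i in targets:
            st = state[i]
            if st.exhausted:
                continue
            ident[i] += _layer_string(st.layer_items(zero, cfg))
            st.advance()
            progressed = True
        rounds += 1
        return progressed

    for _ in range(cfg.min_rounds):
        if cfg.max_rounds is not None and rounds >= cfg.max_rounds:
            break
        if not extend(sorted(colorable)):
            break

    while cfg.max_rounds is None or rounds < cfg.max_rounds:
        shared: dict[str, list[int]] = {}
        for i in colorable:
            shared.setdefault(ident[i], []).append(i)
        targets = [
            i
            for members in shared.values()
            if len(members) > 1
            for i in members
            if not state[i].exhausted
        ]
        if not targets or not extend(sorted(targets)):
            break

    return AtomColorMap(zero_layer=zero, full=ident, rounds_used=rounds)


# ---------------------------------------------------------------------------
# validation and recoloring
# ---------------------------------------------------------------------------


def _group_layers_match(
    g: MolecularGraph,
    members: list[int],
    tokens: dict[int, str],
    cfg: ColoringConfig,
    colorable: set[int],
) -> bool:
    """Simultaneous BFS from every member, comparing layer multisets.

    Valid only if at every layer all members see identical sorted lists of
    (bond descriptor, token) pairs, until every member's expansion has
    consumed its whole connected component.
    """
    states = [_Expansion(g, m, colorable) for m in members]
    while True:
        if all(st.exhausted for st in states):
            return True
        layers = [st.layer_items(tokens, cfg) for st in states]
        if any(layer != layers[0] for layer in layers[1:]):
            return False
        for st in states:
            st.advance()


def validate_symmetry(
    g: MolecularGraph, colors: AtomColorMap, cfg: ColoringConfig | None = None
) -> SymmetryReport:
    """Check that atoms sharing a full identifier really have matching
    neighborhoods, layer by layer, over the whole compound.

    The shell comparison uses the atoms' *full* identifiers, not their
    0_layer strings: shells of 0_layer symbols can agree for asymmetric atoms
    (mirror-symmetric ring systems broken by a remote substituent produce
    equal element/bond shell multisets), whereas full identifiers are
    automorphism-invariant and genuinely distinguish such neighborhoods.
    """
    cfg = cfg or ColoringConfig.loose()
    colorable = _colorable_atoms(g, cfg)
    groups = colors.classes()
    invalid = [
        grp
        for grp in groups
        if len(grp) > 1
        and not _group_layers_match(g, sorted(grp), colors.full, cfg, colorable)
    ]
    return SymmetryReport(groups=groups, invalid_groups=invalid)


def recolor(
    g: MolecularGraph,
    colors: AtomColorMap,
    report: SymmetryReport,
    cfg: ColoringConfig | None = None,
) -> AtomColorMap:
    """Separate pseudosymmetric atoms flagged by :func:`validate_symmetry`.

    Members of each invalid group are re-extended by BFS exactly as in
    :func:`color_atoms`, except that layer strings are built from frontier
    atoms' *full* identifiers instead of their 0_layer strings, and extension
    stops as soon as the members' accumulated strings diverge.  Atoms outside
    invalid groups are untouched.  If a subset of members fails to diverge
    after consuming the whole graph, it is accepted only if its members'
    neighborhoods genuinely match (they are symmetric); otherwise a
    :class:`ColoringError` is raised.
    """
    cfg = cfg or ColoringConfig.loose()
    if not report.invalid_groups:
        return colors.copy()
    colorable = _colorable_atoms(g, cfg)
    new_full = dict(colors.full)
    for grp in report.invalid_groups:
        members = sorted(grp)
        ident = {m: colors.full[m] for m in members}
        states = {m: _Expansion(g, m, colorable) for m in members}
        while True:
            if len(set(ident.values())) == len(members):
                break
            progressed = False
            for m in members:
                st = states[m]
                if st.exhausted:
                    continue
                ident[m] += _layer_string(st.layer_items(colors.full, cfg))
                st.advance()
                progressed = True
            if not progressed:
                # frontier exhausted with duplicates left: acceptable only for
                # genuinely symmetric subsets
                leftover: dict[str, list[int]] = {}
                for m in members:
                    leftover.setdefault(ident[m], []).append(m)
                for same in leftover.values():
                    if len(same) > 1 and not _group_layers_match(
                        g, same, colors.full, cfg, colorable
                    ):
                        raise ColoringError(
                            f"atoms {same} could not be distinguished by "
                            "recoloring although their neighborhoods differ"
                        )
                break
        for m in members:
            new_full[m] = ident[m]
    return AtomColorMap(
        zero_layer=dict(colors.zero_layer), full=new_full, rounds_used=colors.rounds_used
    )


def color_compound(g: MolecularGraph, cfg: ColoringConfig | None = None) -> AtomColorMap:
    """Full color -> validate -> recolor -> validate pipeline.

    Iterates recoloring (each pass refines the full-identifier dictionary the
    next pass reads) until validation reports no invalid group.  Raises
    :class:`ColoringError` if no consistent map is reached within one pass per
    atom, which would indicate a defect rather than an input property.
    """
    cfg = cfg or ColoringConfig.loose()
    colors = color_atoms(g, cfg)
    for _ in range(max(1, len(g.atoms))):
        report = validate_symmetry(g, colors, cfg)
        if report.ok:
            return colors
        colors = recolor(g, colors, report, cfg)
    report = validate_symmetry(g, colors, cfg)
    if report.ok:
        return colors
    raise ColoringError(
        f"validation still fails after recoloring: {report.invalid_groups}"
    )


# ---------------------------------------------------------------------------
# exact automorphism-orbit oracle
# ---------------------------------------------------------------------------


def symmetry_orbits_oracle(
    g: MolecularGraph, cfg: ColoringConfig | None = None, max_atoms: int = 30
) -> list[frozenset[int]]:
    """Orbits of the automorphism group of the colored graph, by backtracking.

    Independent of the coloring code: node labels are tuples of the enabled
    atom layers, edge labels tuples of the enabled bond layers, and the
    automorphisms are enumerated exhaustively (with degree/label pruning).
    Intended as a test oracle; refuses graphs with more than ``max_atoms``
    colorable atoms.
    """
    cfg = cfg or ColoringConfig.loose()
    atoms = sorted(_colorable_atoms(g, cfg))
    n = len(atoms)
    if n > max_atoms:
        raise ValueError(f"{n} colorable atoms exceeds the oracle bound {max_atoms}")
    if n == 0:
        return []

    colorable = set(atoms)

    def node_label(i: int):
        a = g.atom(i)
        return (
            a.element,
            a.charge if cfg.use_charge else None,
            a.stereo_parity if cfg.use_atom_stereo else None,
            a.mass_delta if cfg.use_isotope else None,
        )

    def edge_label(i: int, j: int):
        b = g.adjacency[i].get(j)
        if b is None:
            return None
        return (
            b.order if cfg.use_bond_type else True,
            b.cis_trans if cfg.use_bond_stereo else None,
        )

    labels = {i: node_label(i) for i in atoms}
    adj = {i: {j for j in g.adjacency[i] if j in colorable} for i in atoms}
    degree = {i: len(adj[i]) for i in atoms}
    # invariant used for pruning candidate images
    signature = {
        i: (labels[i], degree[i], tuple(sorted((labels[j], edge_label(i, j)) for j in adj[i])))
        for i in atoms
    }

    # order atoms: rarest signature first, then prefer atoms adjacent to
    # already-placed ones (keeps the partial map connected where possible)
    from collections import Counter

    sig_count = Counter(signature.values())
    order: list[int] = []
    placed: set[int] = set()
    remaining = set(atoms)
    while remaining:
        frontier = {j for i in placed for j in adj[i] if j in remaining}
        pool = frontier or remaining
        nxt = min(pool, key=lambda i: (sig_count[signature[i]], i))
        order.append(nxt)
        placed.add(nxt)
        remaining.discard(nxt)

    parent = {i: i for i in atoms}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    mapping: dict[int, int] = {}
    used: set[int] = set()

    def backtrack(k: int):
        if k == n:
            for src, dst in mapping.items():
                union(src, dst)
            return
        i = order[k]
        for cand in atoms:
            if cand in used or signature[cand] != signature[i]:
                continue
            ok = True
            for placed_i, placed_img in mapping.items():
                if edge_label(i, placed_i) != edge_label(cand, placed_img):
                    ok = False
                    break
            if not ok:
                continue
            mapping[i] = cand
            used.add(cand)
            backtrack(k + 1)
            del mapping[i]
            used.discard(cand)

    backtrack(0)

    orbits: dict[int, set[int]] = {}
    for i in atoms:
        orbits.setdefault(find(i), set()).add(i)
    return sorted((frozenset(v) for v in orbits.values()), key=min)
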