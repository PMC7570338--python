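"""Deterministic molecule and database generators with planted ground truth.

Every test molecule — Kekulé-variant aromatic pairs, molecules with known
symmetry classes, a pseudosymmetric tricyclic trap, charge-discrepant twins —
is built programmatically here, together with seeded random molecules and
paired toy "databases" (directories of molfiles plus reaction/cross-reference
tables) whose correct harmonization outcome is recorded at generation time.
Same name/parameters/seed always yields byte-identical output.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

from .molgraph import Atom, Bond, MolecularGraph, write_molfile

__all__ = [
    "Fixture",
    "NAMED_FIXTURES",
    "make_named_fixture",
    "random_molecule",
    "PlantedPair",
    "DatabasePair",
    "make_database_pair",
]


@dataclass(frozen=True)
class Fixture:
    """A named test molecule with its declared properties.

    ``orbits`` is the planted symmetry-class partition of the heavy atoms
    under loose coloring *after* aromatic normalization (``None`` where the
    fixture is not used for orbit checks); ``aromatic_atoms`` is the
    externally-curated aromatic label set where one is meaningful.
    """

    name: str
    graph: MolecularGraph
    orbits: tuple[frozenset[int], ...] | None = None
    aromatic_atoms: frozenset[int] | None = None
    description: str = ""

    @property
    def molfile(self) -> str:
        return write_molfile(self.graph, title=self.name)


def _mol(name: str, atoms, bonds) -> MolecularGraph:
    """atoms: (element, x, y[, charge]); bonds: (a, b, order)."""
    g = MolecularGraph(source_id=name)
    for i, spec in enumerate(atoms):
        element, x, y = spec[0], spec[1], spec[2]
        charge = spec[3] if len(spec) > 3 else 0
        # molfile coordinate columns carry 4 decimals; keep fixtures exact
        g.add_atom(Atom(index=i, element=element, x=round(x, 4), y=round(y, 4),
                        charge=charge))
    for a, b, order in bonds:
        g.add_bond(Bond(a=a, b=b, order=order))
    return g


def _hexagon() -> list[tuple[float, float]]:
    return [
        (round(math.cos(math.radians(60 * k)), 4), round(math.sin(math.radians(60 * k)), 4))
        for k in range(6)
    ]


def _pentagon() -> list[tuple[float, float]]:
    return [
        (round(math.cos(math.radians(90 + 72 * k)), 4), round(math.sin(math.radians(90 + 72 * k)), 4))
        for k in range(5)
    ]


_HEX = _hexagon()
_PENT = _pentagon()
_RING6 = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)]
_RING5 = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)]


def _ring6_bonds(doubles: set[tuple[int, int]]) -> list[tuple[int, int, int]]:
    return [(a, b, 2 if (a, b) in doubles else 1) for a, b in _RING6]


def _build_benzene(variant: str) -> MolecularGraph:
    doubles = {(0, 1), (2, 3), (4, 5)} if variant == "A" else {(1, 2), (3, 4), (5, 0)}
    return _mol(
        f"benzene_kekule{variant}",
        [("C", x, y) for x, y in _HEX],
        _ring6_bonds(doubles),
    )


_NAPH_COORDS = _HEX + [(1.0, 1.7321), (2.0, 1.7321), (2.5, 0.8660), (2.0, 0.0)]
_NAPH_BONDS = _RING6 + [(1, 6), (6, 7), (7, 8), (8, 9), (9, 0)]


def _build_naphthalene(variant: str) -> MolecularGraph:
    if variant == "A":
        name, doubles = "naphthalene", {(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)}
    else:
        name, doubles = "naphthalene_kekuleB", {(2, 3), (4, 5), (1, 6), (7, 8), (9, 0)}
    bonds = [(a, b, 2 if (a, b) in doubles else 1) for a, b in _NAPH_BONDS]
    return _mol(name, [("C", x, y) for x, y in _NAPH_COORDS], bonds)


def _build_toluene(variant: str = "A") -> MolecularGraph:
    # unlike benzene, the two Kekulé placements of a substituted ring are
    # NOT isomorphic as raw graphs: the ipso carbon either carries a ring
    # double bond or it does not
    name = "toluene" if variant == "A" else "toluene_kekuleB"
    doubles = {(0, 1), (2, 3), (4, 5)} if variant == "A" else {(1, 2), (3, 4), (5, 0)}
    atoms = [("C", x, y) for x, y in _HEX] + [("C", 2.0, 0.0)]
    bonds = _ring6_bonds(doubles) + [(0, 6, 1)]
    return _mol(name, atoms, bonds)


def _build_furan_like() -> MolecularGraph:
    atoms = [("O", *_PENT[0])] + [("C", *_PENT[k]) for k in range(1, 5)]
    bonds = [(0, 1, 1), (1, 2, 2), (2, 3, 1), (3, 4, 2), (4, 0, 1)]
    return _mol("furan_like", atoms, bonds)


def _build_dioxin_flanked() -> MolecularGraph:
    # central 1,4-dioxin (not aromatic), a phenyl hung off each double-bond
    # carbon; only the phenyl atoms carry curated aromatic labels
    ring = [("O", 0.0, 1.0), ("C", 0.87, 0.5), ("C", 0.87, -0.5),
            ("O", 0.0, -1.0), ("C", -0.87, -0.5), ("C", -0.87, 0.5)]
    phenyl1 = [("C", 1.87 + x, 0.5 + y) for x, y in _HEX]
    phenyl2 = [("C", -1.87 - x, -0.5 - y) for x, y in _HEX]
    bonds = [(0, 1, 1), (1, 2, 2), (2, 3, 1), (3, 4, 1), (4, 5, 2), (5, 0, 1)]
    for base in (6, 12):
        bonds += [(base + a, base + b, 2 if (a, b) in {(0, 1), (2, 3), (4, 5)} else 1)
                  for a, b in _RING6]
    bonds += [(1, 6, 1), (4, 12, 1)]
    return _mol("dioxin_flanked", ring + phenyl1 + phenyl2, bonds)


def _build_biphenyl() -> MolecularGraph:
    ring1 = [("C", x, y) for x, y in _HEX]
    ring2 = [("C", 3.0 + x, y) for x, y in _HEX]
    bonds = _ring6_bonds({(0, 1), (2, 3), (4, 5)})
    bonds += [(6 + a, 6 + b, 2 if (a, b) in {(0, 1), (2, 3), (4, 5)} else 1)
              for a, b in _RING6]
    bonds.append((0, 9, 1))  # para-para link
    return _mol("biphenyl", ring1 + ring2, bonds)


def _build_glycerol() -> MolecularGraph:
    atoms = [("C", 0.0, 0.0), ("C", 1.0, 0.0), ("C", 2.0, 0.0),
             ("O", 0.0, 1.0), ("O", 1.0, 1.0), ("O", 2.0, 1.0)]
    bonds = [(0, 1, 1), (1, 2, 1), (0, 3, 1), (1, 4, 1), (2, 5, 1)]
    return _mol("glycerol", atoms, bonds)


def _build_n_propanol() -> MolecularGraph:
    atoms = [("C", 0.0, 0.0), ("C", 1.0, 0.5), ("C", 2.0, 0.0), ("O", 3.0, 0.5)]
    bonds = [(0, 1, 1), (1, 2, 1), (2, 3, 1)]
    return _mol("n_propanol", atoms, bonds)


def _build_butene(kind: str) -> MolecularGraph:
    y3 = 1.3 if kind == "cis" else -1.3
    atoms = [("C", -0.75, 1.3), ("C", 0.0, 0.0), ("C", 1.5, 0.0), ("C", 2.25, y3)]
    bonds = [(0, 1, 1), (1, 2, 2), (2, 3, 1)]
    return _mol(f"butene_{kind}", atoms, bonds)


def _build_pseudosym_triring() -> MolecularGraph:
    # Two mutually symmetric fused six-rings (a decalin-like core whose mirror
    # swaps them) plus a five-ring fused onto a bond of one ring *off* the
    # mirror axis: the core-symmetric atom pairs (e.g. 3 and 8) are then
    # asymmetric, but share identifiers under an under-informative coloring.
    ring_a = [(1.0, 0.0), (0.5, 0.866), (-0.5, 0.866), (-1.0, 0.0),
              (-0.5, -0.866), (0.5, -0.866)]
    ring_b = [(1.93, -1.0), (2.43, -1.87), (1.93, -2.73), (0.99, -2.73)]
    extra = [(0.6, 1.9), (0.0, 2.5), (-0.6, 1.9)]
    atoms = [("C", x, y) for x, y in ring_a + ring_b + extra]
    bonds = [(a, b, 1) for a, b in _RING6]                      # ring A: 0..5
    bonds += [(5, 6, 1), (6, 7, 1), (7, 8, 1), (8, 9, 1), (9, 0, 1)]  # ring B
    bonds += [(1, 10, 1), (10, 11, 1), (11, 12, 1), (12, 2, 1)]       # extra ring
    return _mol("pseudosym_triring", atoms, bonds)


def _build_charge_pair(which: str) -> MolecularGraph:
    charge = -1 if which == "B" else 0
    atoms = [("C", 0.0, 0.0), ("C", 1.0, 0.0), ("O", 1.7, 0.7),
             ("O", 1.7, -0.7, charge)]
    bonds = [(0, 1, 1), (1, 2, 2), (1, 3, 1)]
    return _mol(f"charge_pair{which}", atoms, bonds)


def _build_tetrahydropyran() -> MolecularGraph:
    atoms = [("O", *_HEX[0])] + [("C", *_HEX[k]) for k in range(1, 6)]
    return _mol("tetrahydropyran", atoms, [(a, b, 1) for a, b in _RING6])


def _orbits(*groups) -> tuple[frozenset[int], ...]:
    return tuple(frozenset(g) for g in groups)


def _fixture_table() -> dict[str, Fixture]:
    singles13 = _orbits(*[{i} for i in range(13)])
    table = [
        Fixture("benzene_kekuleA", _build_benzene("A"),
                _orbits(set(range(6))),
                description="benzene, one Kekulé placement of the double bonds"),
        Fixture("benzene_kekuleB", _build_benzene("B"),
                _orbits(set(range(6))),
                description="benzene, double bonds shifted by one ring position"),
        Fixture("naphthalene", _build_naphthalene("A"),
                _orbits({0, 1}, {2, 5, 6, 9}, {3, 4, 7, 8}),
                description="naphthalene, one Kekulé drawing"),
        Fixture("naphthalene_kekuleB", _build_naphthalene("B"),
                _orbits({0, 1}, {2, 5, 6, 9}, {3, 4, 7, 8}),
                description="naphthalene, alternative Kekulé drawing"),
        Fixture("toluene", _build_toluene(),
                _orbits({0}, {1, 5}, {2, 4}, {3}, {6}),
                description="methylbenzene; the methyl carbon is outside the ring"),
        Fixture("toluene_kekuleB", _build_toluene("B"),
                _orbits({0}, {1, 5}, {2, 4}, {3}, {6}),
                description="methylbenzene with the ring double bonds shifted; "
                            "not isomorphic to the other drawing before normalization"),
        Fixture("furan_like", _build_furan_like(),
                _orbits({0}, {1, 4}, {2, 3}),
                aromatic_atoms=frozenset({1, 2, 3, 4}),
                description="five-ring with O; curated labels mark only the carbons"),
        Fixture("dioxin_flanked", _build_dioxin_flanked(),
                _orbits({0, 3}, {1, 4}, {2, 5}, {6, 12}, {7, 11, 13, 17},
                        {8, 10, 14, 16}, {9, 15}),
                aromatic_atoms=frozenset(range(6, 18)),
                description="non-aromatic 1,4-dioxin ring flanked by two labelled phenyls"),
        Fixture("biphenyl", _build_biphenyl(),
                _orbits({0, 9}, {1, 5, 8, 10}, {2, 4, 7, 11}, {3, 6}),
                description="two benzene rings joined by a non-ring single bond"),
        Fixture("glycerol", _build_glycerol(),
                _orbits({0, 2}, {1}, {3, 5}, {4}),
                description="heavy-atom propane-1,2,3-triol: a mirror swaps the end carbons"),
        Fixture("n_propanol", _build_n_propanol(),
                _orbits({0}, {1}, {2}, {3}),
                description="heavy-atom chain with no symmetry at all"),
        Fixture("butene_cis", _build_butene("cis"),
                _orbits({0, 3}, {1, 2}),
                description="2-butene drawn with both methyls on the same side"),
        Fixture("butene_trans", _build_butene("trans"),
                _orbits({0, 3}, {1, 2}),
                description="2-butene drawn with the methyls on opposite sides"),
        Fixture("pseudosym_triring", _build_pseudosym_triring(), singles13,
                description="tricyclic trap: no symmetric atoms, but an "
                            "under-informative coloring merges mirror-image pairs"),
        Fixture("charge_pairA", _build_charge_pair("A"),
                _orbits({0}, {1}, {2}, {3}),
                description="C-C(=O)-O skeleton, all atoms neutral"),
        Fixture("charge_pairB", _build_charge_pair("B"),
                _orbits({0}, {1}, {2}, {3}),
                description="same skeleton, single O carries formal charge -1"),
        Fixture("tetrahydropyran", _build_tetrahydropyran(),
                _orbits({0}, {1, 5}, {2, 4}, {3}),
                description="saturated O-containing six-ring; nothing aromatic"),
    ]
    return {f.name: f for f in table}


NAMED_FIXTURES: dict[str, Fixture] = _fixture_table()


def make_named_fixture(name: str) -> Fixture:
    try:
        return NAMED_FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(NAMED_FIXTURES)}"
        ) from None


# ---------------------------------------------------------------------------
# seeded random molecules
# ---------------------------------------------------------------------------

_ELEMENTS = ["C", "C", "C", "C", "C", "C", "N", "N", "O", "O", "S", "P"]
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3}


def random_molecule(
    seed: int,
    n_atoms: int = 12,
    ring_probability: float = 0.3,
    double_bond_probability: float = 0.15,
) -> MolecularGraph:
    """Connected, valence-respecting random heavy-atom molecule.

    Grown as a random tree (each new atom bonds to a uniformly chosen atom
    with free valence; occasional double bonds), then closed into rings by
    extra single bonds between non-adjacent atoms that both retain free
    valence.  Deterministic per ``(seed, n_atoms, ring_probability)``.
    """
    if not 2 <= n_atoms <= 30:
        raise ValueError("n_atoms must be in [2, 30]")
    rng = random.Random(seed)
    g = MolecularGraph(source_id=f"random_{seed}")
    free: dict[int, int] = {}

    def place(i: int) -> None:
        angle = 2 * math.pi * i / n_atoms
        el = rng.choice(_ELEMENTS)
        g.add_atom(Atom(index=i, element=el,
                        x=round(2.0 * math.cos(angle), 4),
                        y=round(2.0 * math.sin(angle), 4)))
        free[i] = _VALENCE[el]

    place(0)
    for i in range(1, n_atoms):
        place(i)
        hosts = sorted(j for j in range(i) if free[j] >= 1)
        if not hosts:
            raise ValueError(
                f"seed {seed}: no free valence left to attach atom {i}"
            )
        host = rng.choice(hosts)
        order = 1
        if (
            free[host] >= 2
            and free[i] >= 2
            and rng.random() < double_bond_probability
        ):
            # keep at least one open valence while atoms remain to attach
            remaining_free = sum(free.values()) - free[host] - free[i]
            if i == n_atoms - 1 or remaining_free + (free[host] - 2) + (free[i] - 2) >= 1:
                order = 2
        g.add_bond(Bond(a=host, b=i, order=order))
        free[host] -= order
        free[i] -= order

    for _ in range(n_atoms):
        if rng.random() >= ring_probability:
            continue
        open_atoms = sorted(i for i, f in free.items() if f >= 1)
        cands = [
            (i, j)
            for k, i in enumerate(open_atoms)
            for j in open_atoms[k + 1:]
            if j not in g.adjacency[i]
        ]
        if not cands:
            break
        i, j = rng.choice(cands)
        g.add_bond(Bond(a=i, b=j, order=1))
        free[i] -= 1
        free[j] -= 1

    g.check_consistency()
    return g


# ---------------------------------------------------------------------------
# paired toy databases with planted correspondences
# ---------------------------------------------------------------------------

NOISE_CLASSES = frozenset(
    {"kekule_flip", "charge_shift", "atom_reorder", "stereo_drop", "unmatched_extras"}
)


@dataclass(frozen=True)
class PlantedPair:
    left_id: str
    right_id: str
    mode: str                 # expected strongest match mode
    id_confirmed: bool
    reaction_status: str


@dataclass
class DatabasePair:
    dir_left: Path
    dir_right: Path
    planted: list[PlantedPair] = field(default_factory=list)
    extras_left: list[str] = field(default_factory=list)
    extras_right: list[str] = field(default_factory=list)


def _permuted(g: MolecularGraph, rng: random.Random) -> MolecularGraph:
    idx = [a.index for a in g.atoms]
    shuffled = idx[:]
    rng.shuffle(shuffled)
    relabel = dict(zip(idx, shuffled))
    out = MolecularGraph(source_id=g.source_id)
    for a in sorted(g.atoms, key=lambda a: relabel[a.index]):
        new = a.copy()
        new.index = relabel[a.index]
        out.add_atom(new)
    for b in g.bonds:
        nb = b.copy()
        nb.a, nb.b = relabel[b.a], relabel[b.b]
        out.add_bond(nb)
    return out


def _kekule_base(i: int) -> tuple[MolecularGraph, MolecularGraph]:
    """Alternating aromatic fixtures drawn in two Kekulé placements."""
    pairs = [
        ("benzene_kekuleA", "benzene_kekuleB"),
        ("naphthalene", "naphthalene_kekuleB"),
    ]
    a, b = pairs[i % len(pairs)]
    return NAMED_FIXTURES[a].graph.copy(), NAMED_FIXTURES[b].graph.copy()


def _charge_shifted(g: MolecularGraph, rng: random.Random) -> MolecularGraph | None:
    out = g.copy()
    cands = sorted(
        a.index for a in out.atoms if a.element in ("O", "S", "N") and a.charge == 0
    )
    if not cands:
        return None
    out.atom(rng.choice(cands)).charge = -1
    return out


def _stereo_dropped(g: MolecularGraph) -> MolecularGraph:
    out = g.copy()
    for a in out.atoms:
        a.stereo_parity = 0
    for b in out.bonds:
        b.wedge = 0
    return out


def make_database_pair(
    seed: int,
    n_compounds: int = 50,
    noise_profile: frozenset[str] | set[str] = frozenset(
        {"kekule_flip", "charge_shift", "atom_reorder", "unmatched_extras"}
    ),
    out_dir: str | Path | None = None,
) -> DatabasePair:
    """Write two toy database directories with a planted correspondence table.

    Every base compound appears in both databases; the right-hand copy is
    perturbed according to ``noise_profile``.  Representation noise the
    coloring method absorbs (Kekulé placement, atom order, stereo annotation
    under loose coloring) keeps the planted pair tight-matchable; a formal
    charge shift leaves it matchable only loosely.  Reaction tables plant the
    four EC-validation outcomes in rotation, and cross-reference tables
    confirm every second pair.  Base compounds are deduplicated by normalized
    loose identifier at generation time so the planted table is exactly the
    set of true correspondences.
    """
    unknown = set(noise_profile) - NOISE_CLASSES
    if unknown:
        raise ValueError(f"unknown noise classes: {sorted(unknown)}")
    from .coloring import ColoringConfig, color_compound
    from .identifiers import compound_identifier
    from .perception import ReferenceLibrary, normalize_compound

    rng = random.Random(seed)
    lib = ReferenceLibrary.default()
    loose = ColoringConfig.loose()

    def loose_key(g: MolecularGraph) -> str:
        return compound_identifier(
            color_compound(normalize_compound(g, lib), loose), mode="loose"
        ).text

    # -- assemble base compounds with unique loose identifiers --------------
    bases: list[tuple[MolecularGraph, MolecularGraph]] = []  # (left, right)
    seen: set[str] = set()
    kekule_count = 0
    attempt = 0
    while len(bases) < n_compounds:
        attempt += 1
        if attempt > 50 * n_compounds:
            raise RuntimeError("could not assemble enough distinct compounds")
        if "kekule_flip" in noise_profile and len(bases) % 5 == 0 and kekule_count < 2:
            gl, gr = _kekule_base(kekule_count)
            kekule_count += 1
        else:
            mol_seed = seed * 100003 + attempt
            g = random_molecule(mol_seed, n_atoms=rng.randint(5, 14))
            gl, gr = g, g.copy()
        key = loose_key(gl)
        if key in seen:
            continue
        seen.add(key)
        bases.append((gl, gr))

    planted: list[PlantedPair] = []
    db_l: dict[str, MolecularGraph] = {}
    db_r: dict[str, MolecularGraph] = {}
    crossrefs_l: list[tuple[str, str, str]] = []
    crossrefs_r: list[tuple[str, str, str]] = []
    reactions_l: list[tuple[str, str, str]] = []
    reactions_r: list[tuple[str, str, str]] = []

    for i, (gl, gr) in enumerate(bases):
        lid, rid = f"L{i:04d}", f"R{i:04d}"
        mode = "tight"
        if "charge_shift" in noise_profile and i % 7 == 3:
            shifted = _charge_shifted(gr, rng)
            if shifted is not None:
                gr, mode = shifted, "loose"
        if "stereo_drop" in noise_profile and i % 7 == 5:
            gl = gl.copy()
            gl.atoms[0].stereo_parity = 1
            gr = _stereo_dropped(gr)
            mode = "loose"
        if "atom_reorder" in noise_profile:
            gr = _permuted(gr, rng)
        gl.source_id, gr.source_id = lid, rid
        db_l[lid], db_r[rid] = gl, gr

        confirmed = i % 2 == 0
        if confirmed:
            chebi = f"CHEBI:{10000 + i}"
            crossrefs_l.append((lid, "CHEBI", chebi))
            crossrefs_r.append((rid, "CHEBI", chebi))

        bucket = i % 4
        if bucket == 0:
            status = "no_reactions"
        elif bucket == 1:
            status = "in_reactions"
            reactions_l.append((f"RL{i:04d}", f"1.{i + 1}.1.1", lid))
            reactions_r.append((f"RR{i:04d}", f"2.{i + 1}.1.1", rid))
        elif bucket == 2:
            status = "ec3_verified"
            reactions_l.append((f"RL{i:04d}", f"3.1.{i + 1}.-", lid))
            reactions_r.append((f"RR{i:04d}", f"3.1.{i + 1}.9", rid))
        else:
            status = "ec4_verified"
            reactions_l.append((f"RL{i:04d}", f"4.1.2.{i + 1}", lid))
            reactions_r.append((f"RR{i:04d}", f"4.1.2.{i + 1}", rid))
        planted.append(PlantedPair(lid, rid, mode, confirmed, status))

    extras_l: list[str] = []
    extras_r: list[str] = []
    if "unmatched_extras" in noise_profile:
        n_extra = max(1, n_compounds // 5)
        for side, store, extras, prefix in (
            ("left", db_l, extras_l, "LX"),
            ("right", db_r, extras_r, "RX"),
        ):
            k = 0
            attempt = 0
            while k < n_extra:
                attempt += 1
                if attempt > 50 * n_extra:
                    raise RuntimeError("could not assemble distinct extras")
                mol_seed = seed * 200003 + attempt + (0 if side == "left" else 7919)
                g = random_molecule(mol_seed, n_atoms=rng.randint(5, 14))
                key = loose_key(g)
                if key in seen:
                    continue
                seen.add(key)
                cid = f"{prefix}{k:04d}"
                g.source_id = cid
                store[cid] = g
                extras.append(cid)
                k += 1

    # -- write directories ---------------------------------------------------
    out_dir = Path(out_dir) if out_dir is not None else Path(".")
    dirs = (out_dir / "left", out_dir / "right")
    for d, db, crossrefs, reactions in (
        (dirs[0], db_l, crossrefs_l, reactions_l),
        (dirs[1], db_r, crossrefs_r, reactions_r),
    ):
        d.mkdir(parents=True, exist_ok=True)
        for cid in sorted(db):
            (d / f"{cid}.mol").write_text(write_molfile(db[cid], title=cid))
        lines = ["reaction_id\tec\tparticipants"]
        lines += [f"{rid}\t{ec}\t{parts}" for rid, ec, parts in reactions]
        (d / "reactions.tsv").write_text("\n".join(lines) + "\n")
        lines = ["compound_id\tnamespace\tforeign_id"]
        lines += [f"{cid}\t{ns}\t{fid}" for cid, ns, fid in crossrefs]
        (d / "crossrefs.tsv").write_text("\n".join(lines) + "\n")

    return DatabasePair(
        dir_left=dirs[0],
        dir_right=dirs[1],
        planted=planted,
        extras_left=extras_l,
        extras_right=extras_r,
    )
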