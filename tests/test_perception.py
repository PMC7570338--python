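"""Aromatic detection/normalization and double-bond stereo perception."""

import itertools

import pytest

from molcolor.fixtures import NAMED_FIXTURES
from molcolor.molgraph import Atom, Bond, MolecularGraph, to_json, write_molfile
from molcolor.perception import (
    AromaticSubstructure,
    ReferenceLibrary,
    assign_double_bond_stereo,
    detect_by_reference,
    detect_heuristic,
    extract_labeled_substructures,
    normalize_aromatic_bonds,
    normalize_compound,
)


def brute_force_substructure_atoms(host, pattern):
    """Independent oracle: enumerate every injective atom mapping of the
    pattern into the host and keep those preserving elements and bonds
    (orders equivalent within {1, 2, 4}).  Exponential; hosts must be small.
    """
    host_atoms = [a.index for a in host.atoms]
    pat_atoms = [a.index for a in pattern.atoms]
    equiv = {1, 2, 4}

    def order_ok(o1, o2):
        return o1 == o2 or (o1 in equiv and o2 in equiv)

    matched = set()
    for perm in itertools.permutations(host_atoms, len(pat_atoms)):
        mapping = dict(zip(pat_atoms, perm))
        ok = all(
            host.atom(mapping[p]).element == pattern.atom(p).element
            for p in pat_atoms
        )
        if ok:
            for p, q in itertools.combinations(pat_atoms, 2):
                pb = pattern.adjacency[p].get(q)
                hb = host.adjacency[mapping[p]].get(mapping[q])
                if (pb is None) != (hb is None) or (
                    pb is not None and not order_ok(pb.order, hb.order)
                ):
                    ok = False
                    break
        if ok:
            matched.update(mapping.values())
    return matched


class TestExtractLabeled:
    def test_fused_rings_are_one_fragment(self):
        g = NAMED_FIXTURES["naphthalene"].graph
        frags = extract_labeled_substructures(g, set(range(10)))
        assert [len(f) for f in frags] == [10]

    def test_biphenyl_rings_stay_separate(self):
        # the inter-ring bond lies on no ring, so it is not a fragment bond
        g = NAMED_FIXTURES["biphenyl"].graph
        frags = extract_labeled_substructures(g, set(range(12)))
        assert sorted(len(f) for f in frags) == [6, 6]
        assert all(
            all(len(f.fragment.adjacency[a.index]) >= 2 for a in f.fragment.atoms)
            for f in frags
        )

    def test_empty_label_set(self):
        assert extract_labeled_substructures(NAMED_FIXTURES["toluene"].graph, set()) == []


class TestDetectByReference:
    def test_toluene_matches_only_the_ring(self, library):
        frags = detect_by_reference(NAMED_FIXTURES["toluene"].graph, library)
        assert [sorted(f.atom_indices) for f in frags] == [[0, 1, 2, 3, 4, 5]]

    def test_no_heteroatom_pattern_no_match(self):
        benzene_only = ReferenceLibrary(
            [AromaticSubstructure(NAMED_FIXTURES["benzene_kekuleA"].graph.copy(), "benzene")]
        )
        assert detect_by_reference(NAMED_FIXTURES["furan_like"].graph, benzene_only) == []

    def test_both_kekule_placements_match(self, library):
        for name in ("benzene_kekuleA", "benzene_kekuleB"):
            frags = detect_by_reference(NAMED_FIXTURES[name].graph, library)
            assert [sorted(f.atom_indices) for f in frags] == [[0, 1, 2, 3, 4, 5]]

    def test_saturated_ring_is_not_aromatic(self, library):
        cyclohexane = MolecularGraph(
            [Atom(i, "C", x=float(i), y=0.0) for i in range(6)],
            [Bond(i, (i + 1) % 6, 1) for i in range(6)],
        )
        assert detect_by_reference(cyclohexane, library) == []

    @pytest.mark.parametrize("name", ["toluene", "furan_like", "biphenyl", "glycerol"])
    def test_agrees_with_brute_force_enumeration(self, name, library):
        host = NAMED_FIXTURES[name].graph
        # keep the exhaustive enumeration tractable: patterns of <= 6 atoms
        small = ReferenceLibrary(
            [e for e in library.entries if len(e.fragment) <= min(6, len(host))]
        )
        expected = set()
        for entry in small.entries:
            expected |= brute_force_substructure_atoms(host, entry.fragment)
        got = set().union(*(f.atom_indices for f in detect_by_reference(host, small)), set())
        # the oracle has no unsaturation filter; restrict to its carbon rule
        expected = {
            i for i in expected
            if host.atom(i).element != "C"
            or any(b.order in (2, 4) for b in host.adjacency[i].values())
        }
        assert got == expected


class TestHeuristic:
    def test_ring_oxygen_joins_labelled_carbons(self):
        fx = NAMED_FIXTURES["furan_like"]
        g = fx.graph.copy()
        frags = detect_heuristic(g, aromatic_atoms=set(fx.aromatic_atoms))
        assert [sorted(f.atom_indices) for f in frags] == [[0, 1, 2, 3, 4]]
        assert g.atom(0).is_aromatic

    def test_dioxin_ring_with_unlabelled_carbons_not_emitted(self):
        fx = NAMED_FIXTURES["dioxin_flanked"]
        g = fx.graph.copy()
        assert detect_heuristic(g, aromatic_atoms=set(fx.aromatic_atoms)) == []
        assert not g.atom(0).is_aromatic

    def test_saturated_ring_untouched(self):
        g = NAMED_FIXTURES["tetrahydropyran"].graph.copy()
        assert detect_heuristic(g) == []
        assert not any(a.is_aromatic for a in g.atoms)


class TestNormalize:
    def test_kekule_forms_become_identical(self, library):
        a = normalize_compound(NAMED_FIXTURES["benzene_kekuleA"].graph, library)
        b = normalize_compound(NAMED_FIXTURES["benzene_kekuleB"].graph, library)
        a.source_id = b.source_id = "benzene"
        assert write_molfile(a) == write_molfile(b)

    def test_idempotent(self, library):
        once = normalize_compound(NAMED_FIXTURES["naphthalene"].graph, library)
        twice = normalize_compound(once, library)
        assert to_json(once) == to_json(twice)

    def test_exocyclic_bonds_untouched(self, library):
        g = normalize_compound(NAMED_FIXTURES["toluene"].graph, library)
        assert sum(b.order == 4 for b in g.bonds) == 6
        assert g.bond(0, 6).order == 1

    def test_empty_fragment_list_is_identity(self):
        g = NAMED_FIXTURES["toluene"].graph
        assert to_json(normalize_aromatic_bonds(g, [])) == to_json(g)


class TestDoubleBondStereo:
    @pytest.mark.parametrize("name,expected", [("butene_cis", "cis"), ("butene_trans", "trans")])
    def test_two_butene_geometries(self, name, expected):
        g = assign_double_bond_stereo(NAMED_FIXTURES[name].graph)
        labels = [b.cis_trans for b in g.bonds if b.order == 2]
        assert labels == [expected]

    def test_terminal_alkene_unlabelled(self):
        g = MolecularGraph(
            [Atom(0, "C", x=0, y=0), Atom(1, "C", x=1, y=0), Atom(2, "C", x=1.7, y=0.7)],
            [Bond(0, 1, 2), Bond(1, 2, 1)],
        )
        assert [b.cis_trans for b in assign_double_bond_stereo(g).bonds] == [None, None]

    def test_ring_internal_double_bond_unlabelled(self):
        g = assign_double_bond_stereo(NAMED_FIXTURES["furan_like"].graph)
        assert all(b.cis_trans is None for b in g.bonds)

    def test_missing_geometry_raises(self):
        g = MolecularGraph(
            [Atom(0, "C"), Atom(1, "C"), Atom(2, "C"), Atom(3, "C")],
            [Bond(0, 1, 1), Bond(1, 2, 2), Bond(2, 3, 1)],
        )
        with pytest.raises(ValueError, match="geometry"):
            assign_double_bond_stereo(g)


def test_library_deduplicates_by_loose_identifier():
    benzene = NAMED_FIXTURES["benzene_kekuleA"].graph
    other_kekule = NAMED_FIXTURES["benzene_kekuleB"].graph
    lib = ReferenceLibrary(
        [
            AromaticSubstructure(benzene.copy(), "a"),
            AromaticSubstructure(other_kekule.copy(), "b"),
        ]
    )
    assert len(lib) == 1
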