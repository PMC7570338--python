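"""Atom coloring, symmetry validation/recoloring, and the orbit oracle."""

import random

import pytest

from molcolor.coloring import (
    ColoringConfig,
    color_atoms,
    color_compound,
    recolor,
    symmetry_orbits_oracle,
    validate_symmetry,
    zero_layer_color,
)
from molcolor.fixtures import NAMED_FIXTURES, _permuted, random_molecule
from molcolor.molgraph import Atom, Bond, MolecularGraph

LOOSE = ColoringConfig.loose()
TIGHT = ColoringConfig.tight()


class TestZeroLayer:
    def test_loose_is_element_only(self):
        assert zero_layer_color(Atom(0, "C", charge=-1, stereo_parity=1), LOOSE) == "C"

    def test_tight_separates_charge_states(self):
        neutral = zero_layer_color(Atom(0, "O"), TIGHT)
        anion = zero_layer_color(Atom(0, "O", charge=-1), TIGHT)
        assert neutral == "O"
        assert anion != neutral and "O" in anion and "-1" in anion

    def test_r_group_token_verbatim(self):
        assert zero_layer_color(Atom(0, "R#"), LOOSE) == "R#"


class TestColorAtoms:
    def test_benzene_single_class(self, library):
        from molcolor.perception import normalize_compound

        g = normalize_compound(NAMED_FIXTURES["benzene_kekuleA"].graph, library)
        colors = color_atoms(g, LOOSE)
        assert len(set(colors.full.values())) == 1

    def test_glycerol_classes_match_known_symmetry(self):
        colors = color_compound(NAMED_FIXTURES["glycerol"].graph, LOOSE)
        assert set(colors.classes()) == {
            frozenset({0, 2}),
            frozenset({1}),
            frozenset({3, 5}),
            frozenset({4}),
        }

    def test_asymmetric_chain_all_unique(self):
        colors = color_compound(NAMED_FIXTURES["n_propanol"].graph, LOOSE)
        assert len(set(colors.full.values())) == 4

    def test_single_atom_graph(self):
        g = MolecularGraph([Atom(0, "P")])
        colors = color_atoms(g, LOOSE)
        assert colors.full == {0: "P"}

    def test_hydrogens_excluded_by_default(self):
        g = MolecularGraph(
            [Atom(0, "C"), Atom(1, "H"), Atom(2, "O")],
            [Bond(0, 1, 1), Bond(0, 2, 1)],
        )
        colors = color_atoms(g, LOOSE)
        assert set(colors.full) == {0, 2}


class TestValidationAndRecolor:
    def test_true_symmetry_not_flagged(self, library):
        from molcolor.perception import normalize_compound

        g = normalize_compound(NAMED_FIXTURES["benzene_kekuleA"].graph, library)
        colors = color_atoms(g, LOOSE)
        assert validate_symmetry(g, colors, LOOSE).ok

    def test_all_singletons_vacuously_valid(self):
        g = NAMED_FIXTURES["n_propanol"].graph
        colors = color_atoms(g, LOOSE)
        assert validate_symmetry(g, colors, LOOSE).ok

    def test_pseudosymmetric_pair_flagged_and_separated(self):
        """An under-informative coloring merges mirror-image atoms of the
        tricyclic trap; validation must catch it and recoloring repair it."""
        g = NAMED_FIXTURES["pseudosym_triring"].graph
        weak = ColoringConfig.loose(min_rounds=1, max_rounds=1)
        colors = color_atoms(g, weak)
        assert colors.full[3] == colors.full[8]
        report = validate_symmetry(g, colors, weak)
        assert any({3, 8} <= grp for grp in report.invalid_groups)
        repaired = recolor(g, colors, report, weak)
        assert repaired.full[3] != repaired.full[8]

    def test_recolor_with_no_invalid_groups_is_identity(self):
        g = NAMED_FIXTURES["glycerol"].graph
        colors = color_compound(g, LOOSE)
        report = validate_symmetry(g, colors, LOOSE)
        assert report.ok
        assert recolor(g, colors, report, LOOSE).full == colors.full

    def test_full_pipeline_reaches_oracle_orbits(self):
        g = NAMED_FIXTURES["pseudosym_triring"].graph
        weak = ColoringConfig.loose(min_rounds=1, max_rounds=1)
        final = color_compound(g, weak)
        assert set(final.classes()) == set(symmetry_orbits_oracle(g, weak))


class TestOracle:
    def test_benzene_one_orbit(self, library):
        from molcolor.perception import normalize_compound

        g = normalize_compound(NAMED_FIXTURES["benzene_kekuleA"].graph, library)
        assert symmetry_orbits_oracle(g, LOOSE) == [frozenset(range(6))]

    def test_glycerol_orbits_by_hand(self):
        # hand-checkable 6-atom case: the mirror swaps the terminal C/O pairs
        orbits = symmetry_orbits_oracle(NAMED_FIXTURES["glycerol"].graph, LOOSE)
        assert set(orbits) == {
            frozenset({0, 2}),
            frozenset({1}),
            frozenset({3, 5}),
            frozenset({4}),
        }

    def test_size_bound_enforced(self):
        g = random_molecule(7, n_atoms=12)
        with pytest.raises(ValueError, match="oracle bound"):
            symmetry_orbits_oracle(g, LOOSE, max_atoms=10)

    def test_random_tree_orbits_equal_coloring_classes(self):
        g = random_molecule(42, n_atoms=12, ring_probability=0.0)
        assert set(color_compound(g, LOOSE).classes()) == set(
            symmetry_orbits_oracle(g, LOOSE)
        )


class TestInvariants:
    @pytest.mark.parametrize("seed", [3, 11, 29])
    def test_permutation_leaves_identifier_multiset_unchanged(self, seed):
        g = random_molecule(seed, n_atoms=14)
        base = sorted(color_compound(g, LOOSE).full.values())
        rng = random.Random(seed)
        for _ in range(5):
            perm = _permuted(g, rng)
            assert sorted(color_compound(perm, LOOSE).full.values()) == base

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_tight_classes_refine_loose_classes(self, seed):
        g = random_molecule(seed, n_atoms=12)
        loose_of = color_compound(g, LOOSE).full
        tight_of = color_compound(g, TIGHT).full
        by_tight = {}
        for i, c in tight_of.items():
            by_tight.setdefault(c, set()).add(i)
        for members in by_tight.values():
            assert len({loose_of[i] for i in members}) == 1

    def test_explicit_hydrogens_do_not_change_heavy_atom_classes(self):
        from molcolor.molgraph import add_implicit_hydrogens

        g = NAMED_FIXTURES["glycerol"].graph
        with_h = add_implicit_hydrogens(g)
        bare = color_compound(g, LOOSE)
        hydrogenated = color_compound(with_h, LOOSE)
        assert {i: hydrogenated.full[i] for i in bare.full} == bare.full

    def test_two_runs_are_byte_identical(self):
        g = random_molecule(99, n_atoms=18)
        assert color_compound(g, TIGHT).full == color_compound(g, TIGHT).full


def test_symmetry_classes_agree_with_rdkit_ranking():
    """Independent cross-check: rdkit's canonical ranking with ties kept
    groups atoms exactly by symmetry class on neutral fixtures."""
    from rdkit import Chem

    for name in ("glycerol", "n_propanol", "toluene", "naphthalene"):
        fx = NAMED_FIXTURES[name]
        mol = Chem.MolFromMolBlock(fx.molfile, sanitize=True, removeHs=True)
        assert mol is not None, name
        ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
        rd_classes = {}
        for i, r in enumerate(ranks):
            rd_classes.setdefault(r, set()).add(i)
        from molcolor.perception import normalize_compound

        g = normalize_compound(fx.graph)
        ours = set(color_compound(g, LOOSE).classes())
        assert {frozenset(v) for v in rd_classes.values()} == ours, name
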