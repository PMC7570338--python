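"""EC numbers, cross-database matching, pair classification and reporting."""

import pytest

from molcolor.harmonize import (
    CorrespondencePair,
    ECNumber,
    ECParseError,
    confirm_with_ids,
    harmonization_report,
    harmonize_directories,
    match_compounds,
    validate_with_ec,
    ReactionRecord,
)
from molcolor.identifiers import CompoundIndex


def _index(mode, mapping):
    return CompoundIndex(mode=mode, mapping=mapping, failures={})


class TestECNumber:
    @pytest.mark.parametrize(
        "text,depth", [("1.1.1.1", 4), ("2.3.1.-", 3), ("4.2.-", 2), ("1", 1), ("EC 1.2.3.4", 4)]
    )
    def test_parse_and_depth(self, text, depth):
        assert ECNumber.parse(text).specified_depth == depth

    @pytest.mark.parametrize("bad", ["a.b.c", "1.0.1.1", "1..2", "-.1.1.1"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ECParseError):
            ECNumber.parse(bad)

    def test_agreement_prefix_logic(self):
        a, b = ECNumber.parse("1.1.1.1"), ECNumber.parse("1.1.1.2")
        assert a.agrees(b, 3) and not a.agrees(b, 4)
        wild = ECNumber.parse("2.3.1.-")
        full = ECNumber.parse("2.3.1.9")
        assert wild.agrees(full, 3) and not wild.agrees(full, 4)

    def test_str_roundtrip(self):
        assert str(ECNumber.parse("2.3.1.-")) == "2.3.1.-"


class TestMatchCompounds:
    def test_shared_singleton_key_one_pair(self):
        pairs = match_compounds(_index("loose", {"k": ["L1"]}), _index("loose", {"k": ["R1"]}))
        assert [(p.left_id, p.right_id) for p in pairs] == [("L1", "R1")]

    def test_one_to_many_preserved(self):
        pairs = match_compounds(
            _index("loose", {"k": ["L1"]}), _index("loose", {"k": ["R1", "R2"]})
        )
        assert [(p.left_id, p.right_id) for p in pairs] == [("L1", "R1"), ("L1", "R2")]

    def test_disjoint_keys_empty(self):
        assert match_compounds(_index("loose", {"a": ["L"]}), _index("loose", {"b": ["R"]})) == []

    def test_mode_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mode mismatch"):
            match_compounds(_index("tight", {}), _index("loose", {}))

    def test_transposing_inputs_transposes_pairs(self):
        left = _index("loose", {"k": ["L1", "L2"], "j": ["L3"]})
        right = _index("loose", {"k": ["R1"], "j": ["R2", "R3"]})
        fwd = {(p.left_id, p.right_id) for p in match_compounds(left, right)}
        rev = {(p.right_id, p.left_id) for p in match_compounds(right, left)}
        assert fwd == rev


class TestConfirmWithIds:
    PAIR = [CorrespondencePair("L1", "R1", "loose")]

    def test_shared_foreign_id_confirms(self):
        out = confirm_with_ids(
            self.PAIR, [("L1", "CHEBI", "CHEBI:1")], [("R1", "CHEBI", "CHEBI:1")]
        )
        assert out[0].id_confirmed

    def test_direct_link_to_partner_id_confirms(self):
        out = confirm_with_ids(
            self.PAIR, [], [("R1", "LDB", "L1")], left_namespace="LDB"
        )
        assert out[0].id_confirmed

    def test_no_shared_reference_unconfirmed(self):
        out = confirm_with_ids(
            self.PAIR, [("L1", "CHEBI", "CHEBI:1")], [("R1", "CHEBI", "CHEBI:2")]
        )
        assert not out[0].id_confirmed


class TestValidateWithEC:
    def _run(self, ec_left, ec_right):
        pairs = [CorrespondencePair("L1", "R1", "loose")]
        rl = [ReactionRecord("RL", frozenset({"L1"}), tuple(ECNumber.parse(e) for e in ec_left))]
        rr = [ReactionRecord("RR", frozenset({"R1"}), tuple(ECNumber.parse(e) for e in ec_right))]
        return validate_with_ec(pairs, rl, rr)[0].reaction_status

    def test_three_level_agreement(self):
        assert self._run(["1.1.1.1"], ["1.1.1.2"]) == "ec3_verified"

    def test_wildcard_caps_at_three_levels(self):
        assert self._run(["2.3.1.-"], ["2.3.1.9"]) == "ec3_verified"

    def test_four_level_agreement(self):
        assert self._run(["2.3.1.9"], ["2.3.1.9", "1.1.1.1"]) == "ec4_verified"

    def test_disagreement_stays_in_reactions(self):
        assert self._run(["1.1.1.1"], ["2.1.1.1"]) == "in_reactions"

    def test_side_without_reactions(self):
        pairs = [CorrespondencePair("L1", "R1", "loose")]
        rr = [ReactionRecord("RR", frozenset({"R1"}), (ECNumber.parse("1.1.1.1"),))]
        assert validate_with_ec(pairs, [], rr)[0].reaction_status == "no_reactions"


class TestReport:
    def test_pairs_in_both_modes_counted_once_as_tight(self):
        tight = [CorrespondencePair("L1", "R1", "tight")]
        loose = [
            CorrespondencePair("L1", "R1", "loose"),
            CorrespondencePair("L2", "R2", "loose"),
        ]
        rep = harmonization_report(tight, loose)
        assert len(rep.pairs) == 2
        assert rep.count(mode="tight") == 1 and rep.count(mode="loose") == 1

    def test_empty_inputs_all_zero(self):
        rep = harmonization_report([], [])
        assert rep.pairs == [] and rep.count() == 0
        assert rep.one_to_many_left == rep.one_to_many_right == 0

    def test_single_mode_run_accepted(self):
        rep = harmonization_report(pairs_tight=[CorrespondencePair("L", "R", "tight")])
        assert rep.count(mode="tight") == 1 and rep.count(mode="loose") == 0

    def test_one_to_many_counted(self):
        loose = [
            CorrespondencePair("L1", "R1", "loose"),
            CorrespondencePair("L1", "R2", "loose"),
        ]
        rep = harmonization_report([], loose)
        assert rep.one_to_many_left == 1 and rep.one_to_many_right == 0


class TestDirectoryPipeline:
    def test_planted_truth_recovered_on_small_database(self, tmp_path):
        from molcolor.fixtures import make_database_pair

        pair = make_database_pair(
            seed=3,
            n_compounds=12,
            noise_profile={"kekule_flip", "charge_shift", "atom_reorder"},
            out_dir=tmp_path,
        )
        rep = harmonize_directories(pair.dir_left, pair.dir_right)
        got = {
            (p.left_id, p.right_id): (p.mode, p.id_confirmed, p.reaction_status)
            for p in rep.pairs
        }
        want = {
            (p.left_id, p.right_id): (p.mode, p.id_confirmed, p.reaction_status)
            for p in pair.planted
        }
        assert got == want

    def test_tight_pairs_subset_of_loose_pairs(self, tmp_path):
        from molcolor.coloring import ColoringConfig
        from molcolor.fixtures import make_database_pair
        from molcolor.harmonize import load_database
        from molcolor.identifiers import build_index
        from molcolor.perception import normalize_compound

        pair = make_database_pair(
            seed=4, n_compounds=10,
            noise_profile={"charge_shift", "atom_reorder"}, out_dir=tmp_path,
        )
        dbs = [load_database(pair.dir_left), load_database(pair.dir_right)]
        by_mode = {}
        for cfg in (ColoringConfig.tight(), ColoringConfig.loose()):
            idx = [
                build_index(
                    sorted((cid, normalize_compound(g)) for cid, g in db.compounds.items()),
                    cfg,
                )
                for db in dbs
            ]
            by_mode[cfg.mode] = {
                (p.left_id, p.right_id) for p in match_compounds(idx[0], idx[1])
            }
        assert by_mode["tight"] <= by_mode["loose"]
        assert by_mode["tight"] != by_mode["loose"]  # charge noise is loose-only
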