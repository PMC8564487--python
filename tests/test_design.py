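"""Scaffold grafting, point substitution, saturation libraries, conservativeness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepscaffold import (
    E7_WT,
    H2DB_ANCHORS,
    NATURAL_AMINO_ACIDS,
    TRP2_WT,
    apply_substitutions,
    flag_conservative,
    graft,
    inc_library,
    motif_from_display,
    parse_peptide,
    parse_substitution,
    point_substitute,
    saturation_library,
    scaffold_with_point,
)
from pepscaffold.alphabet import NATURAL_RESIDUES, default_registry

random_9mers = st.text(alphabet=list(NATURAL_AMINO_ACIDS), min_size=9, max_size=9)
anchor_letters = st.tuples(*[st.sampled_from(NATURAL_AMINO_ACIDS)] * 4)


def motif_from_anchor_letters(letters):
    display = "".join(
        {2: letters[0], 3: letters[1], 5: letters[2], 9: letters[3]}.get(p, "x")
        for p in range(1, 10)
    )
    return motif_from_display(display)


class TestGraft:
    def test_e7_scaffold_substitution_accounting(self, e7_wt, h2db_motif, anchors):
        result = graft(e7_wt, h2db_motif, anchors)
        assert str(result.designed) == "RALYNIVTL"
        assert result.notation == ("H3L", "F9L")

    def test_trp2_scaffold_substitution_accounting(self, trp2_wt, h2db_motif, anchors):
        result = graft(trp2_wt, h2db_motif, anchors)
        assert str(result.designed) == "SALDNFVWL"
        assert result.notation == ("V2A", "Y3L", "F5N")

    def test_fixed_point(self, h2db_motif, anchors):
        scaffolded = parse_peptide("RALYNIVTL")
        result = graft(scaffolded, h2db_motif, anchors)
        assert result.designed == scaffolded
        assert result.substitutions == ()

    @settings(max_examples=100, derandomize=True)
    @given(random_9mers, anchor_letters)
    def test_idempotence_and_tcr_preservation(self, seq, letters):
        wt = parse_peptide(seq)
        motif = motif_from_anchor_letters(letters)
        first = graft(wt, motif, H2DB_ANCHORS)
        second = graft(first.designed, motif, H2DB_ANCHORS)
        assert second.designed == first.designed
        assert second.substitutions == ()
        for pos in H2DB_ANCHORS.tcr_positions:
            assert first.designed.at(pos).code == wt.at(pos).code
        for pos in H2DB_ANCHORS.anchor_positions:
            assert first.designed.at(pos).code == motif.fixed[pos].code

    def test_tcr_positions_untouched_over_many_random_cases(self, h2db_motif):
        rng = np.random.default_rng(123)
        for _ in range(500):
            seq = "".join(rng.choice(list(NATURAL_AMINO_ACIDS), size=9))
            wt = parse_peptide(seq)
            designed = graft(wt, h2db_motif, H2DB_ANCHORS).designed
            assert all(
                designed.at(p).code == wt.at(p).code
                for p in H2DB_ANCHORS.tcr_positions
            )

    def test_length_mismatch_rejected(self, h2db_motif, anchors):
        with pytest.raises(ValueError):
            graft(parse_peptide("RAHYNIVT"), h2db_motif, anchors)

    @settings(max_examples=50, derandomize=True)
    @given(random_9mers, anchor_letters)
    def test_substitution_round_trip(self, seq, letters):
        wt = parse_peptide(seq)
        result = graft(wt, motif_from_anchor_letters(letters), H2DB_ANCHORS)
        assert apply_substitutions(wt, result.substitutions) == result.designed


class TestPointSubstitute:
    def test_e7_y4w(self, e7_wt):
        result = point_substitute(e7_wt, 4, "W")
        assert str(result.designed) == "RAHWNIVTF"
        assert result.notation == ("Y4W",)

    def test_trp2_d4c(self, trp2_wt):
        result = point_substitute(trp2_wt, 4, "C")
        assert str(result.designed) == "SVYCFFVWL"
        assert result.notation == ("D4C",)

    def test_identity_substitution_rejected(self, e7_wt):
        with pytest.raises(ValueError, match="no-op"):
            point_substitute(e7_wt, 4, "Y")

    def test_non_natural_nal_at_p4(self, e7_wt, registry):
        nal = registry.resolve("1")
        result = point_substitute(e7_wt, 4, nal)
        assert result.designed.at(4).label == "NAL"
        assert result.notation == ("Y41",)


class TestSaturationLibrary:
    def test_mix_library_has_twenty_members_one_wt(self, e7_wt):
        lib = saturation_library(e7_wt, 4)
        assert len(lib) == 20
        wt_members = [m for m in lib.members if m.designed == e7_wt]
        assert len(wt_members) == 1
        assert wt_members[0].substitutions == ()
        others = [m for m in lib.members if m.designed != e7_wt]
        assert all(len(m.substitutions) == 1 and m.substitutions[0].position == 4
                   for m in others)

    def test_members_distinct(self, trp2_wt):
        lib = saturation_library(trp2_wt, 4)
        assert len(set(lib.sequences())) == 20

    def test_singleton_alphabet(self, e7_wt):
        lib = saturation_library(e7_wt, 4, alphabet=["W"])
        assert lib.sequences() == ("RAHWNIVTF",)

    def test_alphabet_extended_with_non_natural(self, e7_wt, registry):
        alphabet = [NATURAL_RESIDUES[a] for a in NATURAL_AMINO_ACIDS]
        alphabet.append(registry.resolve("1"))
        lib = saturation_library(e7_wt, 4, alphabet=alphabet)
        assert len(lib) == 21

    def test_position_out_of_range(self, e7_wt):
        with pytest.raises(IndexError):
            saturation_library(e7_wt, 10)


class TestIncLibrary:
    def test_default_named_variants(self, e7_wt, trp2_wt):
        e7 = inc_library(e7_wt, ("Y4V", "Y4W"))
        trp2 = inc_library(trp2_wt, ("D4C", "D4Q", "D4W"))
        assert e7.sequences() == ("RAHVNIVTF", "RAHWNIVTF")
        assert trp2.sequences() == ("SVYCFFVWL", "SVYQFFVWL", "SVYWFFVWL")

    def test_notation_must_match_wt(self, e7_wt):
        with pytest.raises(ValueError, match="does not match"):
            inc_library(e7_wt, ("D4C",))  # E7 p4 is Y, not D


class TestComposites:
    def test_scaffold_then_nal_at_p4(self, e7_wt, h2db_motif, anchors, registry):
        result = scaffold_with_point(e7_wt, h2db_motif, anchors, 4, registry.resolve("1"))
        assert str(result.designed) == "RAL1NIVTL"
        assert result.notation == ("H3L", "Y41", "F9L")

    def test_point_at_anchor_rejected(self, e7_wt, h2db_motif, anchors):
        with pytest.raises(ValueError, match="anchor"):
            scaffold_with_point(e7_wt, h2db_motif, anchors, 2, "G")


class TestConservativeFlag:
    @pytest.mark.parametrize(
        "notation, expected",
        [
            ("L4I", True),    # BLOSUM62 score 2
            ("D4W", False),   # score -4
            ("F9L", False),   # score 0: not > 0 under this scheme
            ("V2A", False),   # score 0
        ],
    )
    def test_blosum62_positive_score_rule(self, notation, expected):
        assert flag_conservative(parse_substitution(notation)) is expected

    def test_non_natural_is_unknown(self, registry):
        sub = parse_substitution("Y41", registry)
        assert flag_conservative(sub) is None

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            flag_conservative(parse_substitution("L4I"), scheme="pam250")


def test_wild_type_fixtures_consistent_with_named_substitutions():
    """Every printed substitution notation resolves against the fixtures."""
    registry = default_registry()
    e7, trp2 = parse_peptide(E7_WT), parse_peptide(TRP2_WT)
    for notation in ("H3L", "F9L", "Y4V", "Y4W"):
        sub = parse_substitution(notation, registry)
        assert e7.at(sub.position).code == sub.wt_residue.code
    for notation in ("V2A", "Y3L", "F5N", "D4C", "D4Q", "D4W"):
        sub = parse_substitution(notation, registry)
        assert trp2.at(sub.position).code == sub.wt_residue.code
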