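import numpy as np
import pytest

import oracles
from orfrate.datatypes import OrfRecord
from orfrate.errors import ConfigurationError, ValidationError
from orfrate.protein_features import (
    HYDROPHOBICITY,
    POLARITY,
    SECONDARY_STRUCTURE,
    aa_composition,
    ctd_block,
    protein_feature_vector,
    to_group_sequence,
)


class TestAaComposition:
    def test_homopolymer(self):
        comp = aa_composition("AAAA")
        assert comp["aa.A"] == 1.0
        assert sum(comp.values()) == pytest.approx(1.0)

    def test_four_distinct(self):
        comp = aa_composition("ACDE")
        for aa in "ACDE":
            assert comp[f"aa.{aa}"] == 0.25

    def test_illegal_residue_names_position(self):
        with pytest.raises(ValidationError, match="position 2"):
            aa_composition("ACXE")


class TestGroupSequences:
    def test_hydrophobicity_groups(self):
        # A is neutral (group 2), C is hydrophobic (group 1)
        assert to_group_sequence("AAACCC", HYDROPHOBICITY).tolist() == [2, 2, 2, 1, 1, 1]

    def test_polarity_lysine_in_polar_group(self):
        assert to_group_sequence("KKK", POLARITY).tolist() == [1, 1, 1]

    def test_annotation_overrides_residue_identity(self):
        seq = to_group_sequence("AAA", SECONDARY_STRUCTURE, annotation="HHC")
        assert seq.tolist() == [1, 1, 3]

    def test_missing_annotation_without_fallback(self):
        with pytest.raises(ConfigurationError):
            to_group_sequence("AAA", SECONDARY_STRUCTURE, fallback=False)


class TestCtdBlock:
    def test_two_block_sequence_three_groups(self):
        block = ctd_block([2, 2, 2, 1, 1, 1], 3)
        assert block["comp.g1"] == 0.5
        assert block["comp.g2"] == 0.5
        assert block["comp.g3"] == 0.0
        assert block["trans.g12"] == pytest.approx(0.2)
        assert block["trans.g13"] == 0.0
        assert block["trans.g23"] == 0.0
        assert block["dist.g1.first"] == pytest.approx(4 / 6)
        assert block["dist.g1.q25"] == pytest.approx(4 / 6)
        assert block["dist.g1.q50"] == pytest.approx(5 / 6)
        assert block["dist.g1.q75"] == pytest.approx(6 / 6)
        assert block["dist.g1.last"] == pytest.approx(6 / 6)
        assert len(block) == 21

    def test_single_group_sequence(self):
        block = ctd_block([1, 1, 1, 1], 3)
        assert block["comp.g1"] == 1.0
        assert all(block[f"trans.g{p}"] == 0.0 for p in ("12", "13", "23"))
        assert [
            block[f"dist.g1.{m}"] for m in ("first", "q25", "q50", "q75", "last")
        ] == [0.25, 0.25, 0.5, 0.75, 1.0]
        assert all(block[f"dist.g2.{m}"] == 0.0 for m in ("first", "last"))

    def test_two_group_block_has_seven_values(self):
        block = ctd_block([1, 2, 1, 2, 2], 2)
        assert len(block) == 7
        assert set(block) == {
            "comp.g1", "comp.g2", "trans.g12",
            "dist.g1.first", "dist.g1.q25", "dist.g1.q50", "dist.g1.q75",
        }

    def test_constant_sequence_no_transitions(self):
        block = ctd_block([2] * 9, 3)
        assert all(v == 0.0 for k, v in block.items() if k.startswith("trans"))

    def test_matches_enumeration_oracle_on_random_sequences(self, rng):
        for _ in range(200):
            groups = int(rng.integers(2, 4))
            length = int(rng.integers(2, 31))
            seq = rng.integers(1, groups + 1, size=length).tolist()
            expected = oracles.ctd(seq, groups)
            got = ctd_block(np.array(seq), groups)
            assert set(got) == set(expected)
            for key in expected:
                assert got[key] == pytest.approx(expected[key], abs=1e-12), key

    def test_invariant_ranges_and_monotone_distribution(self, rng):
        for _ in range(50):
            length = int(rng.integers(2, 40))
            seq = rng.integers(1, 4, size=length)
            block = ctd_block(seq, 3)
            comp = [block[f"comp.g{g}"] for g in (1, 2, 3)]
            assert sum(comp) == pytest.approx(1.0)
            for key, value in block.items():
                assert 0.0 <= value <= 1.0, key
            for g in (1, 2, 3):
                landmarks = [
                    block[f"dist.g{g}.{m}"]
                    for m in ("first", "q25", "q50", "q75", "last")
                ]
                assert landmarks == sorted(landmarks)


class TestProteinVector:
    def test_length_132_and_deterministic(self):
        record = OrfRecord(orf_id="x", cds="ATGGCT", protein="MACDEFGHIKLNPQRSTVWY")
        vec = protein_feature_vector(record)
        assert len(vec) == 132
        assert vec == protein_feature_vector(record)

    def test_fallback_off_requires_annotations(self):
        record = OrfRecord(orf_id="x", cds="ATG", protein="MAC")
        with pytest.raises(ConfigurationError):
            protein_feature_vector(record, fallback=False)

    def test_real_annotations_override_fallback(self):
        base = OrfRecord(orf_id="x", cds="ATG", protein="MACD")
        annotated = OrfRecord(
            orf_id="x", cds="ATG", protein="MACD",
            ss_annotation="HHEE", acc_annotation="EBEB",
        )
        v1 = protein_feature_vector(base)
        v2 = protein_feature_vector(annotated)
        assert v1 != v2
        # non-annotation families are unaffected
        assert all(
            v1[k] == v2[k] for k in v1 if not k.startswith(("ss.", "acc."))
        )
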