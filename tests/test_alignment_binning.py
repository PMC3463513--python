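"""Residue records, group assignment, RSA binning and bin concatenation."""

import numpy as np
import pandas as pd
import pytest

from resevol.alignment_binning import (
    CodonAlignment,
    ResidueRecord,
    assign_groups,
    bin_residues,
    concatenate_bin_alignment,
    map_codons_to_structure,
)

TAXA = ("w", "x", "y", "z")


def make_alignment(columns):
    """columns: list of 4-tuples of codon strings."""
    seqs = tuple("".join(col[t] for col in columns) for t in range(4))
    return CodonAlignment(TAXA, seqs)


def make_record(pid, idx, rsa, codon="ATT"):
    return ResidueRecord(pid, idx, rsa, (codon,) * 4, gapless=True)


class TestCodonAlignment:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            CodonAlignment(TAXA, ("ATG", "ATGATG", "ATG", "ATG"))

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            CodonAlignment(TAXA, ("ATGA",) * 4)

    @pytest.mark.parametrize(
        "codon,expected",
        [("ATT", True), ("---", False), ("ANT", False), ("TAA", False), ("A-T", False)],
    )
    def test_column_sense_detection(self, codon, expected):
        aln = make_alignment([("ATG", "ATG", "ATG", codon)])
        assert aln.column_is_sense(0) is expected


class TestMapCodonsToStructure:
    def test_full_coverage_all_gapless(self, rsa_profile_factory):
        cols = [("ATT", "ATT", "ATC", "ATT")] * 10
        records = map_codons_to_structure(
            make_alignment(cols), rsa_profile_factory(np.linspace(0, 90, 10)), "P1"
        )
        assert len(records) == 10
        assert all(r.gapless for r in records)

    def test_gap_column_flagged(self, rsa_profile_factory):
        cols = [("ATT",) * 4, ("ATT", "ATT", "---", "ATT"), ("ATT",) * 4]
        records = map_codons_to_structure(
            make_alignment(cols), rsa_profile_factory([1.0, 2.0, 3.0]), "P1"
        )
        assert [r.gapless for r in records] == [True, False, True]

    def test_missing_rsa_flagged(self, rsa_profile_factory):
        cols = [("ATT",) * 4] * 3
        records = map_codons_to_structure(
            make_alignment(cols), rsa_profile_factory([1.0, np.nan, 3.0]), "P1"
        )
        assert [r.gapless for r in records] == [True, False, True]
        assert sum(r.gapless for r in records) == 2

    def test_length_mismatch_names_protein(self, rsa_profile_factory):
        with pytest.raises(ValueError, match="P77"):
            map_codons_to_structure(
                make_alignment([("ATT",) * 4] * 3), rsa_profile_factory([1.0]), "P77"
            )


class TestAssignGroups:
    @staticmethod
    def proteins(n, rng=None):
        rng = rng or np.random.default_rng(1)
        return pd.DataFrame(
            {
                "protein_id": [f"P{i:03d}" for i in range(n)],
                "avg_rsa": rng.uniform(10, 60, n),
                "expression": rng.uniform(0, 1, n),
            }
        )

    def test_tertiles_of_nine(self):
        df = pd.DataFrame(
            {
                "protein_id": [f"P{i}" for i in range(9)],
                "avg_rsa": np.arange(9, dtype=float),
                "expression": np.arange(9, dtype=float)[::-1],
            }
        )
        out = assign_groups(df, fraction=1 / 3)
        assert (out.core_class == "large_core").sum() == 3
        assert (out.core_class == "small_core").sum() == 3
        assert set(out.loc[out.core_class == "large_core", "protein_id"]) == {
            "P0", "P1", "P2"
        }
        # expression ranked independently (here reversed)
        assert set(out.loc[out.expr_class == "low_expr", "protein_id"]) == {
            "P8", "P7", "P6"
        }

    def test_half_fraction_leaves_no_mid(self):
        out = assign_groups(self.proteins(10), fraction=0.5)
        assert (out.core_class == "mid").sum() == 0
        assert (out.expr_class == "mid").sum() == 0

    def test_extreme_class_sizes_are_floor_of_fraction(self):
        for n in (10, 11, 12, 13):
            out = assign_groups(self.proteins(n), fraction=0.25)
            assert (out.core_class == "large_core").sum() == int(np.floor(0.25 * n))

    def test_all_tied_proxy_is_unrankable(self):
        df = self.proteins(9)
        df["expression"] = 1.0
        with pytest.raises(ValueError, match="unrankable"):
            assign_groups(df)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            assign_groups(self.proteins(9), fraction=0.6)

    def test_axes_are_independent(self):
        df = self.proteins(15)
        out1 = assign_groups(df)
        shuffled = df.copy()
        shuffled["expression"] = df["expression"].sample(frac=1, random_state=3).values
        out2 = assign_groups(shuffled)
        assert list(out1.core_class) == list(out2.core_class)


class TestBinResidues:
    def test_basic_assignment(self):
        records = [make_record("P", 1, 10.0), make_record("P", 2, 90.0)]
        out = bin_residues(records, edges=(0, 50, 100))
        assert [b.count for b, _ in out] == [1, 1]

    @pytest.mark.parametrize("rsa,expected_bin", [(50.0, 1), (100.0, 1), (49.999, 0)])
    def test_half_open_and_closed_last(self, rsa, expected_bin):
        out = bin_residues([make_record("P", 1, rsa)], edges=(0, 50, 100))
        counts = [b.count for b, _ in out]
        assert counts[expected_bin] == 1

    def test_representative_x_is_member_mean(self):
        records = [make_record("P", i, v) for i, v in enumerate([10.0, 30.0], 1)]
        out = bin_residues(records, edges=(0, 50, 100))
        assert out[0][0].x == pytest.approx(20.0)

    def test_empty_bin_flagged(self):
        with pytest.warns(UserWarning, match="empty"):
            out = bin_residues([make_record("P", 1, 10.0)], edges=(0, 50, 100))
        assert out[1][0].empty

    def test_out_of_range_rsa_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            bin_residues([make_record("P", 1, 120.0)])

    def test_gapped_record_rejected(self):
        rec = ResidueRecord("P", 1, 10.0, ("---",) * 4, gapless=False)
        with pytest.raises(ValueError, match="gapless"):
            bin_residues([rec])

    def test_conservation_and_permutation_invariance(self):
        rng = np.random.default_rng(11)
        records = [
            make_record(f"P{i%5}", i, float(r))
            for i, r in enumerate(rng.uniform(0, 100, 200), 1)
        ]
        for edges in [(0, 50, 100), (0, 10, 30, 70, 100), tuple(range(0, 101, 10))]:
            out = bin_residues(records, edges=edges)
            assert sum(b.count for b, _ in out) == len(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        a = bin_residues(records, edges=(0, 25, 50, 75, 100))
        b = bin_residues(shuffled, edges=(0, 25, 50, 75, 100))
        for (bin_a, mem_a), (bin_b, mem_b) in zip(a, b):
            key = lambda r: (r.protein_id, r.residue_index)
            assert sorted(mem_a, key=key) == sorted(mem_b, key=key)
            assert bin_a.x == pytest.approx(bin_b.x)


class TestConcatenateBinAlignment:
    def test_three_members_three_columns(self):
        members = [make_record("P", i, 10.0) for i in range(1, 4)]
        out = concatenate_bin_alignment(members, taxa=TAXA)
        assert out.codons.shape == (4, 3)

    def test_protein_major_ordering(self):
        r1 = make_record("B", 1, 5.0, codon="TTT")
        r2 = make_record("A", 2, 5.0, codon="AAA")
        r3 = make_record("A", 1, 5.0, codon="GGG")
        out = concatenate_bin_alignment([r1, r2, r3], taxa=TAXA)
        from resevol.codons import SENSE_CODONS

        first_row = [SENSE_CODONS[i] for i in out.codons[0]]
        assert first_row == ["GGG", "AAA", "TTT"]

    def test_empty_bin_unusable(self):
        out = concatenate_bin_alignment([], taxa=TAXA)
        assert not out.usable
        assert out.n_codons == 0

    def test_gapped_member_rejected(self):
        rec = ResidueRecord("P", 1, 10.0, ("---",) * 4, gapless=False)
        with pytest.raises(ValueError, match="gapped|gapless"):
            concatenate_bin_alignment([rec], taxa=TAXA)
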