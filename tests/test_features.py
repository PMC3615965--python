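"""Feature encodings: worked examples, brute-force oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cppred import (Peptide, PeptideDataset, aa_composition, binary_profile,
                    dipeptide_composition, encode_dataset, encode_peptide,
                    physchem_features, position_frequency_matrix,
                    terminal_composition)
from cppred.errors import (SequenceTooShortError, WindowTooLongError)
from cppred.features import (BINARY_SCHEMES, DIPEPTIDES, decode_binary_profile,
                             isoelectric_point)
from cppred.peptide_core import AMINO_ACIDS, validate_peptide

peptide_seqs = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=30)


def comp(fv, aa):
    return fv.values[AMINO_ACIDS.index(aa)]


class TestAAComposition:
    @pytest.mark.parametrize("seq, expected", [
        ("AAAA", {"A": 100.0}),
        ("RKRK", {"R": 50.0, "K": 50.0}),
        # Tat(48-57) fragment: 6R, 2K, 1G, 1Q over N=10
        ("GRKKRRQRRR", {"R": 60.0, "K": 20.0, "G": 10.0, "Q": 10.0}),
    ])
    def test_hand_counts(self, seq, expected):
        fv = aa_composition(Peptide(seq))
        for aa in AMINO_ACIDS:
            assert comp(fv, aa) == pytest.approx(expected.get(aa, 0.0))

    @given(peptide_seqs)
    @settings(deadline=None)
    def test_sums_to_100(self, seq):
        fv = aa_composition(Peptide(seq))
        assert len(fv) == 20
        assert fv.values.sum() == pytest.approx(100.0, abs=1e-9)
        assert (fv.values >= 0).all()


class TestTerminalComposition:
    def test_terminal_windows(self):
        p = Peptide("RRRRRKKKKK")
        assert comp(terminal_composition(p, "N", 5), "R") == 100.0
        assert comp(terminal_composition(p, "C", 5), "K") == 100.0

    @given(peptide_seqs)
    @settings(deadline=None)
    def test_full_window_equals_overall(self, seq):
        p = Peptide(seq)
        for end in ("N", "C"):
            tc = terminal_composition(p, end, len(p))
            np.testing.assert_allclose(tc.values, aa_composition(p).values)

    def test_window_too_long(self):
        with pytest.raises(WindowTooLongError):
            terminal_composition(Peptide("RRR"), "N", 4)


class TestDipeptideComposition:
    def test_homopolymer(self):
        fv = dipeptide_composition(Peptide("AAA"))
        assert fv.values[DIPEPTIDES.index("AA")] == 1.0
        assert fv.values.sum() == 1.0

    def test_two_overlapping_pairs(self):
        fv = dipeptide_composition(Peptide("AGA"))
        assert fv.values[DIPEPTIDES.index("AG")] == 0.5
        assert fv.values[DIPEPTIDES.index("GA")] == 0.5

    def test_length_one_rejected(self):
        with pytest.raises(SequenceTooShortError):
            dipeptide_composition(Peptide("A"))

    @given(st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=30))
    @settings(deadline=None)
    def test_matches_dictionary_count_oracle(self, seq):
        fv = dipeptide_composition(Peptide(seq))
        counts = {}
        for i in range(len(seq) - 1):
            counts[seq[i:i + 2]] = counts.get(seq[i:i + 2], 0) + 1
        assert fv.values.sum() == pytest.approx(1.0, abs=1e-9)
        for dp, n in counts.items():
            assert fv.values[DIPEPTIDES.index(dp)] == pytest.approx(
                n / (len(seq) - 1))


class TestBinaryProfile:
    def test_single_residue_pads_remaining_blocks(self):
        fv = binary_profile(Peptide("A"), "N5")
        assert len(fv) == 100
        assert fv.values[0] == 1.0           # A one-hot in block 1
        assert fv.values[1:20].sum() == 0
        assert fv.values[20:].sum() == 0     # blocks 2-5 all-zero pads

    def test_overlapping_joined_windows(self):
        fv = binary_profile(Peptide("R" * 10), "N10C10")
        assert len(fv) == 400
        assert fv.values.sum() == 20.0       # every block filled (windows overlap)

    @given(peptide_seqs, st.sampled_from(sorted(BINARY_SCHEMES)))
    @settings(deadline=None)
    def test_one_hot_blocks_decode_to_windowed_residues(self, seq, scheme):
        p = Peptide(seq)
        fv = binary_profile(p, scheme)
        n_k, c_k = BINARY_SCHEMES[scheme]
        assert len(fv) == 20 * (n_k + c_k)
        blocks = fv.values.reshape(-1, 20)
        assert (blocks.sum(axis=1) <= 1).all()
        decoded = decode_binary_profile(fv)
        expected = [seq[i] if i < len(seq) else None for i in range(n_k)]
        expected += [seq[len(seq) - c_k + i] if len(seq) - c_k + i >= 0 else None
                     for i in range(c_k)]
        assert decoded == expected


class TestPhyschem:
    def test_net_charge_of_polyarginine(self):
        fv = physchem_features(Peptide("RRRRR"))
        assert dict(zip(fv.names, fv.values))["charge"] == 5.0

    def test_length_and_polarity_partition(self):
        p = Peptide("GRKKRRQRRR")
        vals = dict(zip(physchem_features(p).names, physchem_features(p).values))
        assert vals["length"] == len(p)
        assert vals["polar_count"] + vals["nonpolar_count"] == len(p)

    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=15),
           st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=15))
    @settings(deadline=None, max_examples=30)
    def test_charge_is_additive_over_concatenation(self, s1, s2):
        def charge(seq):
            fv = physchem_features(Peptide(seq))
            return dict(zip(fv.names, fv.values))["charge"]
        assert charge(s1 + s2) == pytest.approx(charge(s1) + charge(s2))

    def test_molecular_weight_close_to_biopython(self):
        from Bio.SeqUtils import molecular_weight
        seq = "GRKKRRQRRRPPQ"
        vals = dict(zip(physchem_features(Peptide(seq)).names,
                        physchem_features(Peptide(seq)).values))
        assert vals["molecular_weight"] == pytest.approx(
            molecular_weight(seq, seq_type="protein"), rel=1e-3)

    def test_pi_acidic_vs_basic(self):
        assert isoelectric_point("DDDDD") < 5 < 9 < isoelectric_point("RRRRR")


class TestPositionFrequencyMatrix:
    def test_hand_count(self):
        d = PeptideDataset([Peptide("RA", label="positive"),
                            Peptide("KA", label="positive")])
        pfm, skipped = position_frequency_matrix(d, "N", 2)
        assert skipped == 0
        assert pfm.loc["R", "N1"] == 0.5
        assert pfm.loc["K", "N1"] == 0.5
        assert pfm.loc["A", "N2"] == 1.0

    def test_columns_sum_to_one_and_short_peptides_skipped(self, small_dataset):
        pfm, skipped = position_frequency_matrix(small_dataset, "C", 10)
        np.testing.assert_allclose(pfm.sum(axis=0), 1.0)
        assert skipped == sum(1 for p in small_dataset if len(p) < 10)


class TestEncodeDataset:
    def test_shapes_and_row_consistency(self, small_dataset):
        for scheme, width in [("composition", 20), ("dipeptide", 400),
                              ("N10C10", 400), ("physchem", 11)]:
            X, y = encode_dataset(small_dataset, scheme)
            assert X.shape == (len(small_dataset), width)
            assert y.sum() == 60
            # row 0 equals the single-peptide encoding
            np.testing.assert_allclose(
                X.iloc[0].to_numpy(),
                encode_peptide(small_dataset[0], scheme).values)

    def test_unknown_scheme(self, small_dataset):
        with pytest.raises(ValueError):
            encode_dataset(small_dataset, "nope")
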