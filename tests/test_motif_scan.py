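"""Motif parsing, PWM scoring, exact p-values, scanning, evaluation."""

import math

import numpy as np
import pytest

from cppred import (GeneratorConfig, Motif, make_dataset, motif_only_evaluate,
                    parse_meme_motifs, scan_peptide, score_pvalue,
                    score_window)
from cppred.errors import AlphabetError, FormatError, LengthMismatchError
from cppred.motif_scan import (E_VALUE_LADDER, _binned_window_score,
                               _pvalue_from_bin, default_motifs)
from cppred.peptide_core import AMINO_ACIDS, Peptide, validate_peptide

MINIMAL_HEADER = """MEME version 4

ALPHABET= ACDEFGHIKLMNPQRSTVWY

Background letter frequencies
A 0.05 C 0.05 D 0.05 E 0.05 F 0.05 G 0.05 H 0.05 I 0.05 K 0.05 L 0.05
M 0.05 N 0.05 P 0.05 Q 0.05 R 0.05 S 0.05 T 0.05 V 0.05 W 0.05 Y 0.05

"""


def uniform_row():
    return " ".join(["0.05"] * 20)


class TestParser:
    def test_bundled_fixture_parses(self):
        ms = default_motifs()
        assert [m.id for m in ms] == ["polyR", "RxR", "LKrepeat"]
        assert [m.width for m in ms] == [7, 5, 8]
        for m in ms:
            np.testing.assert_allclose(m.pwm.sum(axis=0), 1.0, atol=1e-3)
            assert m.background.sum() == pytest.approx(1.0, abs=1e-2)

    def test_bad_row_sum_raises_format_error(self, tmp_path):
        bad = MINIMAL_HEADER + (
            "MOTIF bad\nletter-probability matrix: alength= 20 w= 2\n"
            + uniform_row() + "\n" + " ".join(["0.2"] * 20) + "\n")
        p = tmp_path / "bad.meme"
        p.write_text(bad)
        with pytest.raises(FormatError, match="sums"):
            parse_meme_motifs(p)

    def test_nucleotide_alphabet_rejected(self, tmp_path):
        p = tmp_path / "dna.meme"
        p.write_text("MEME version 4\n\nALPHABET= ACGT\n\nMOTIF x\n")
        with pytest.raises(AlphabetError):
            parse_meme_motifs(p)

    def test_missing_background_defaults_to_uniform(self, tmp_path):
        text = ("MEME version 4\n\nALPHABET= ACDEFGHIKLMNPQRSTVWY\n\n"
                "MOTIF u\nletter-probability matrix: alength= 20 w= 2\n"
                + uniform_row() + "\n" + uniform_row() + "\n")
        p = tmp_path / "u.meme"
        p.write_text(text)
        (m,) = parse_meme_motifs(p)
        np.testing.assert_allclose(m.background, 1 / 20)

    def test_missing_version_header(self, tmp_path):
        p = tmp_path / "x.meme"
        p.write_text("MOTIF x\n")
        with pytest.raises(FormatError, match="version"):
            parse_meme_motifs(p)


class TestScoreWindow:
    def test_uniform_pwm_scores_zero_everywhere(self):
        m = Motif("u", np.full((20, 3), 1 / 20))
        assert score_window(m, "ARW") == pytest.approx(0.0, abs=1e-12)

    def test_consensus_is_argmax(self, motifs, rng):
        poly = motifs[0]
        consensus = "R" * poly.width
        best = score_window(poly, consensus)
        for _ in range(200):
            w = "".join(rng.choice(list(AMINO_ACIDS), poly.width))
            assert score_window(poly, w) <= best

    def test_equals_per_position_sum_oracle(self, motifs, rng):
        m = motifs[2]
        for _ in range(50):
            w = "".join(rng.choice(list(AMINO_ACIDS), m.width))
            expected = sum(
                math.log2(max(m.pwm[AMINO_ACIDS.index(ch), pos], 1e-4)
                          / m.background[AMINO_ACIDS.index(ch)])
                for pos, ch in enumerate(w))
            assert score_window(m, w) == pytest.approx(expected)

    def test_length_mismatch(self, motifs):
        with pytest.raises(LengthMismatchError):
            score_window(motifs[0], "RR")


class TestScorePvalue:
    def test_extremes(self, motifs):
        m = motifs[0]
        assert score_pvalue(m, float("-inf")) == 1.0
        assert score_pvalue(m, 1e9) == 0.0

    def test_non_increasing_in_score(self, motifs):
        m = motifs[1]
        grid = np.linspace(-20, 25, 80)
        ps = [score_pvalue(m, s) for s in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_width2_matches_enumeration_over_400_windows(self, rng):
        # independent oracle: enumerate every dipeptide window, weight by
        # background, sum the tail mass above each achievable score
        pwm = rng.dirichlet(np.ones(20), size=2).T
        bg = rng.dirichlet(np.ones(20))
        m = Motif("w2", pwm, bg)
        windows = [(a + b, bg[i] * bg[j])
                   for i, a in enumerate(AMINO_ACIDS)
                   for j, b in enumerate(AMINO_ACIDS)]
        binned = [( _binned_window_score(m, w), prob) for w, prob in windows]
        for sbin in sorted({b for b, _ in binned}):
            expected = sum(prob for b, prob in binned if b >= sbin)
            assert _pvalue_from_bin(m, sbin) == pytest.approx(expected,
                                                              abs=1e-9)


class TestScanPeptide:
    def test_planted_consensus_recovered_at_offset(self, motifs):
        p = validate_peptide("AAAA" + "RRRRRRR" + "AAAA", id="planted")
        hits = scan_peptide(p, motifs, e_threshold=10.0)
        poly = [h for h in hits if h.motif_id == "polyR"]
        assert poly and poly[0].offset == 4

    def test_background_peptides_rarely_hit_at_strict_threshold(self):
        d, _ = make_dataset(GeneratorConfig(n_pos=0, n_neg=50, seed=21))
        hits = sum(bool(scan_peptide(p, default_motifs(), 1e-7)) for p in d)
        assert hits <= 2

    def test_lowering_threshold_never_adds_hits(self, motifs, small_dataset):
        for p in small_dataset.entries[:20]:
            loose = {h.motif_id for h in scan_peptide(p, motifs, 10.0)}
            strict = {h.motif_id for h in scan_peptide(p, motifs, 0.01)}
            assert strict <= loose

    def test_order_independent_of_motif_file_order(self, motifs,
                                                   small_dataset):
        rev = list(reversed(motifs))
        for p in small_dataset.entries[:10]:
            a = {(h.motif_id, h.offset, h.evalue)
                 for h in scan_peptide(p, motifs, 10.0)}
            b = {(h.motif_id, h.offset, h.evalue)
                 for h in scan_peptide(p, rev, 10.0)}
            assert a == b

    def test_planted_positives_covered(self):
        cfg = GeneratorConfig(n_pos=60, n_neg=0, seed=13,
                              plant_motif="RRRRRRR", plant_prob=1.0)
        d, _ = make_dataset(cfg)
        covered = sum(bool(scan_peptide(p, default_motifs(), 10.0)) for p in d)
        assert covered >= 0.95 * len(d)


class TestMotifOnlyEvaluate:
    def test_planted_only_in_positives_gives_high_pcp(self, motifs):
        cfg = GeneratorConfig(n_pos=40, n_neg=40, seed=17,
                              plant_motif="RRRRRRR", plant_prob=1.0,
                              enrichment=())  # positives = background + motif
        d, _ = make_dataset(cfg)
        summaries = motif_only_evaluate(d, motifs, e_thresholds=(1e-4,))
        assert summaries[0].pcp > 0.9

    def test_coverage_non_increasing_down_the_ladder(self, motifs,
                                                     planted_dataset):
        summaries = motif_only_evaluate(planted_dataset, motifs,
                                        E_VALUE_LADDER)
        cov = [s.coverage for s in summaries]
        assert all(a >= b for a, b in zip(cov, cov[1:]))

    def test_nothing_covered_reports_nan_pcp(self, motifs):
        d, _ = make_dataset(GeneratorConfig(n_pos=0, n_neg=10, seed=5))
        (s,) = motif_only_evaluate(d, motifs, e_thresholds=(1e-12,))
        assert s.covered == 0 and math.isnan(s.pcp)
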