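"""PWM construction, relative scoring, both-strand scanning, palindromes."""

import numpy as np
import pytest

from regcons.io import GenomicInterval, Peak, ValidationError
from regcons.motifs import (
    MotifHit,
    build_palindrome_pwm,
    build_pwm,
    iupac_match_count,
    iupac_match_positions,
    motif_peak_frequency,
    read_meme,
    relative_score,
    revcomp,
    scan_sequence,
    write_meme,
)

SOX = "AACAATG"  # one instance of the (A/T)(A/T)CAA(T/A)G consensus


def brute_force_hits(pwm, seq, threshold):
    """Independent oracle: score every offset on both strands by hand."""
    hits = []
    L = len(pwm)
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L].upper()
        if any(c not in "ACGT" for c in window):
            continue
        for strand, w in (("+", window), ("-", revcomp(window))):
            raw = sum(
                pwm.weights[i, "ACGT".index(c)] for i, c in enumerate(w)
            )
            score = 100.0 * raw / pwm.max_score
            if score > threshold:
                hits.append((off, strand, round(score, 9)))
    return sorted(hits)


class TestBuildPwm:
    def test_counts_per_position(self):
        pwm = build_pwm(["ACG", "ACG"])
        assert pwm.weights[0].tolist() == [2.0, 0.0, 0.0, 0.0]
        assert pwm.weights[1].tolist() == [0.0, 2.0, 0.0, 0.0]

    def test_degenerate_position_and_max_score(self):
        pwm = build_pwm(["AA", "AT"])
        assert pwm.weights[1].tolist() == [1.0, 0.0, 0.0, 1.0]
        assert pwm.max_score == 3.0

    def test_single_site_consensus_matrix(self):
        pwm = build_pwm([SOX])
        assert pwm.max_score == 7.0
        assert pwm.consensus == SOX

    def test_ragged_sites_rejected(self):
        with pytest.raises(ValidationError, match="unequal"):
            build_pwm(["ACG", "AC"])

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValidationError, match="non-ACGT"):
            build_pwm(["ANG"])


class TestRelativeScore:
    def test_consensus_scores_100(self):
        pwm = build_pwm([SOX, "TTCAAAG"])
        assert relative_score(pwm, pwm.consensus) == 100.0

    def test_degenerate_pwm_scores(self):
        pwm = build_pwm(["AA", "AT"])
        assert relative_score(pwm, "AA") == 100.0
        assert relative_score(pwm, "TT") == pytest.approx(100.0 / 3.0)

    def test_own_site_scores_100(self):
        pwm = build_pwm([SOX])
        assert relative_score(pwm, SOX.lower()) == 100.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            relative_score(build_pwm([SOX]), "ACGT")


class TestScanSequence:
    def test_planted_consensus_found_on_plus(self):
        pwm = build_pwm([SOX])
        seq = "C" * 10 + SOX + "C" * 10
        hits = scan_sequence(pwm, seq, threshold=75)
        assert MotifHit("", 10, "+", 100.0) in hits
        assert all(h.offset == 10 for h in hits if h.score == 100.0)

    def test_planted_revcomp_found_on_minus(self):
        pwm = build_pwm([SOX])
        seq = "C" * 10 + revcomp(SOX) + "C" * 10
        hits = scan_sequence(pwm, seq, threshold=75)
        assert [(h.offset, h.strand) for h in hits if h.score == 100.0] == [(10, "-")]

    def test_n_windows_skipped(self):
        pwm = build_pwm([SOX])
        seq = "N" * 10 + SOX + "N" * 10
        hits = scan_sequence(pwm, seq, threshold=0)
        # only the single fully-ACGT window can be reported
        assert {h.offset for h in hits} == {10}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        sites = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(3)]
        pwm = build_pwm(sites)
        seq = "".join(rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04], size=400))
        got = sorted((h.offset, h.strand, round(h.score, 9))
                     for h in scan_sequence(pwm, seq, threshold=70))
        assert got == brute_force_hits(pwm, seq, 70)

    @pytest.mark.parametrize("seed", range(3))
    def test_strand_symmetry(self, seed):
        """Scanning revcomp(seq) mirrors hits: strands flip, offsets reflect."""
        rng = np.random.default_rng(seed)
        pwm = build_pwm(["".join(rng.choice(list("ACGT"), 5)) for _ in range(2)])
        seq = "".join(rng.choice(list("ACGT"), 300))
        fwd = {(h.offset, h.strand) for h in scan_sequence(pwm, seq, threshold=70)}
        rev = scan_sequence(pwm, revcomp(seq), threshold=70)
        mirrored = {
            (len(seq) - h.offset - len(pwm), "+" if h.strand == "-" else "-") for h in rev
        }
        assert fwd == mirrored

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        pwm = build_pwm([SOX, "TTCAATG"])
        seq = "".join(rng.choice(list("ACGT"), 1000))
        n_prev = None
        for thr in (50, 60, 70, 80, 90):
            n = len(scan_sequence(pwm, seq, threshold=thr))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


class TestPalindrome:
    def test_composite_structure(self):
        mono = build_pwm([SOX])
        pal = build_palindrome_pwm(mono, spacer=4)
        assert len(pal.composite) == 2 * 7 + 4
        # first half = monomer, last half = reverse complement
        assert pal.composite.weights[:7].tolist() == mono.weights.tolist()
        assert pal.composite.weights[11:].tolist() == mono.weights[::-1, ::-1].tolist()

    @pytest.mark.parametrize("spacer_seq", ["ACGT", "acgt", "TTTT", "GGGG"])
    def test_consensus_with_any_spacer_scores_100(self, spacer_seq):
        pal = build_palindrome_pwm(build_pwm([SOX]), spacer=4)
        window = SOX + spacer_seq + revcomp(SOX)
        assert relative_score(pal.composite, window) == 100.0

    def test_monomer_only_sequence_scores_below_100(self):
        pal = build_palindrome_pwm(build_pwm([SOX]), spacer=4)
        window = SOX + "ACGT" + "GGGGGGG"  # no inverted copy
        assert relative_score(pal.composite, window) < 100.0

    def test_negative_spacer_rejected(self):
        with pytest.raises(ValidationError, match="spacer"):
            build_palindrome_pwm(build_pwm([SOX]), spacer=-1)


class TestPeakFrequency:
    def _peaks_on(self, genome, n, width=60):
        return [
            Peak(GenomicInterval("c", i * width, (i + 1) * width), f"p{i}", i * width + width // 2)
            for i in range(n)
        ]

    def test_planted_in_every_peak_gives_100(self):
        pwm = build_pwm([SOX])
        seq = "".join("C" * 26 + SOX + "C" * 27 for _ in range(10))
        genome = {"c": seq}
        assert motif_peak_frequency(self._peaks_on(genome, 10), genome, pwm) == 100.0

    def test_absent_motif_gives_0(self):
        pwm = build_pwm([SOX])
        genome = {"c": "C" * 600}
        assert motif_peak_frequency(self._peaks_on(genome, 10), genome, pwm) == 0.0

    def test_planted_in_two_of_ten_gives_20(self):
        blocks = []
        for i in range(10):
            if i in (2, 7):
                blocks.append("C" * 26 + SOX + "C" * 27)
            else:
                blocks.append("C" * 60)
        genome = {"c": "".join(blocks)}
        assert motif_peak_frequency(self._peaks_on(genome, 10), genome, build_pwm([SOX])) == 20.0

    def test_peak_beyond_chromosome_end_rejected(self):
        genome = {"c": "ACGT" * 10}
        peak = Peak(GenomicInterval("c", 20, 60), "p", 30)
        with pytest.raises(ValidationError, match="beyond"):
            motif_peak_frequency([peak], genome, build_pwm([SOX]))


class TestIupac:
    def test_consensus_matches_degenerate_pattern(self):
        assert iupac_match_count(SOX, "WWCAAWG") >= 1

    def test_overlapping_plus_strand_matches(self):
        assert iupac_match_count("CCAATCCAAT", "CCAAT") == 2

    def test_palindromic_pattern_counts_both_strands(self):
        assert iupac_match_count("ACGT", "ACGT") == 2

    def test_positions_report_both_strands(self):
        pos = iupac_match_positions("CCAATxxATTGG".replace("x", "C"), "CCAAT")
        assert (0, "+") in pos and (7, "-") in pos

    def test_invalid_code_rejected(self):
        with pytest.raises(ValidationError, match="IUPAC"):
            iupac_match_count("ACGT", "AXG")


class TestMemeRoundTrip:
    def test_scores_preserved(self, tmp_path):
        pwm = build_pwm([SOX, "TTCAATG", "ATCAAAG"], name="sox")
        path = tmp_path / "m.meme"
        write_meme([pwm], path)
        back = read_meme(path)["sox"]
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = "".join(rng.choice(list("ACGT"), len(pwm)))
            assert relative_score(back, w) == pytest.approx(relative_score(pwm, w), abs=1e-3)
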