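"""PWM construction/scanning, enrichment, transcript homology, deletion."""

import numpy as np
import pytest

from cistandem import motifs as mt
from cistandem.synth import ALU_CONSENSUS


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestPWM:
    def test_pure_counts_no_pseudocount(self):
        pwm = mt.pwm_from_counts([[10, 0, 0, 0], [0, 10, 0, 0]], pseudocount=0)
        assert pwm.consensus == "AC"
        assert pwm.matrix[0, 0] == 1.0

    def test_uniform_counts_zero_log_odds(self):
        pwm = mt.pwm_from_counts([[5, 5, 5, 5]] * 3, pseudocount=0)
        assert np.allclose(pwm.log_odds, 0.0)
        assert pwm.max_score == 0.0

    def test_pseudocount_normalisation(self):
        pwm = mt.pwm_from_counts([[8, 0, 0, 0]], pseudocount=1)
        # (8+1)/(8+4) = 0.75, (0+1)/12 for the rest
        assert pwm.matrix[0, 0] == pytest.approx(9 / 12)
        assert pwm.matrix[0, 1] == pytest.approx(1 / 12)

    def test_zero_column_without_pseudocount_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            mt.pwm_from_counts([[0, 0, 0, 0]], pseudocount=0)


class TestScan:
    def setup_method(self):
        self.rng = np.random.default_rng(5)
        self.pwm = mt.pwm_from_consensus("TTGACCAAGT")

    def test_planted_consensus_found_forward(self):
        bg = random_seq(self.rng, 300)
        seq = bg[:120] + self.pwm.consensus + bg[120:]
        hits = mt.scan_sequence(self.pwm, seq, score_min=0.9)
        assert any(h.offset == 120 and h.strand == "+" for h in hits)
        top = max(hits, key=lambda h: h.score)
        assert top.offset == 120 and top.score == pytest.approx(self.pwm.max_score)

    def test_planted_reverse_complement_found_on_minus(self):
        bg = random_seq(self.rng, 300)
        rc = mt.revcomp(self.pwm.consensus)
        seq = bg[:80] + rc + bg[80:]
        hits = mt.scan_sequence(self.pwm, seq, score_min=0.9)
        assert any(h.offset == 80 and h.strand == "-" for h in hits)

    def test_sequence_shorter_than_motif(self):
        assert mt.scan_sequence(self.pwm, "ACG") == []

    def test_matches_exhaustive_per_offset_rescoring(self):
        seq = random_seq(self.rng, 500)
        pwm = self.pwm
        hits = mt.scan_sequence(pwm, seq, score_min=0.3)
        lo = pwm.log_odds
        expected = {}
        L = len(pwm)
        for strand in "+-":
            s = seq if strand == "+" else mt.revcomp(seq)
            for off in range(len(s) - L + 1):
                window = s[off : off + L]
                score = sum(lo[i, "ACGT".index(b)] for i, b in enumerate(window))
                if score >= 0.3 * pwm.max_score - 1e-12:
                    fwd = off if strand == "+" else len(seq) - L - off
                    expected[(fwd, strand)] = score
        got = {(h.offset, h.strand): h.score for h in hits}
        assert set(got) == set(expected)
        for k in got:
            assert got[k] == pytest.approx(expected[k])

    def test_strand_involution(self):
        seq = random_seq(self.rng, 400)
        L = len(self.pwm)
        fwd = mt.scan_sequence(self.pwm, seq, score_min=0.5)
        rev = mt.scan_sequence(self.pwm, mt.revcomp(seq), score_min=0.5)
        mirrored = {
            (len(seq) - L - h.offset, "+-"[h.strand == "+"], round(h.score, 6))
            for h in rev
        }
        assert {(h.offset, h.strand, round(h.score, 6)) for h in fwd} == mirrored

    def test_n_bases_score_as_background(self):
        pwm = mt.pwm_from_consensus("ACGT")
        hits_n = mt.scan_sequence(pwm, "NNNN", score_min=-10, both_strands=False)
        assert hits_n[0].score == 0.0


class TestEnrichment:
    def test_full_vs_none_minimal_p(self):
        rng = np.random.default_rng(6)
        pwm = mt.pwm_from_consensus("TTGACCAAGT")
        import math

        sets = {f"s{i}": random_seq(rng, 60) + pwm.consensus for i in range(8)}
        bg = {f"b{i}": "".join(c for c in random_seq(rng, 70)) for i in range(12)}
        # keep background free of chance hits
        bg = {k: v for k, v in bg.items()
              if not mt.scan_sequence(pwm, v, score_min=0.9)}
        universe = {**sets, **bg}
        res = mt.motif_set_enrichment(pwm, sets, universe, score_min=0.9)
        n, N, K = len(sets), len(universe), len(sets)
        expected = math.comb(K, n) * math.comb(N - K, 0) / math.comb(N, n)
        assert res.p == pytest.approx(expected, rel=1e-9)

    def test_identical_fractions_not_significant(self):
        rng = np.random.default_rng(7)
        pwm = mt.pwm_from_consensus("TTGACCAAGT")
        bg = {f"b{i}": random_seq(rng, 80) for i in range(40)}
        subset = {k: bg[k] for k in list(bg)[:10]}
        res = mt.motif_set_enrichment(pwm, subset, bg, score_min=0.95)
        assert res.p >= 0.05  # no planted signal in a random subset

    def test_empty_collections_error(self):
        pwm = mt.pwm_from_consensus("ACGTACGT")
        with pytest.raises(ValueError, match="nonempty"):
            mt.motif_set_enrichment(pwm, {}, {"a": "ACGTACGT"})


class TestHomology:
    def test_exact_substring(self):
        rng = np.random.default_rng(8)
        t = random_seq(rng, 400)
        aln = mt.align_motif_to_transcript(t[200:230], t)
        assert aln.transcript_offset == 200
        assert aln.identity == 1.0
        assert aln.strand == "+"

    def test_motifs_from_planted_alu_fall_in_window(self):
        """Motifs sampled from the embedded repeat align inside its window."""
        rng = np.random.default_rng(9)
        t = random_seq(rng, 1200)
        off, L = 150, 300
        transcript = t[:off] + ALU_CONSENSUS + t[off + L:]
        for _ in range(5):
            s = int(rng.integers(0, L - 25))
            motif = ALU_CONSENSUS[s : s + 25]
            aln = mt.align_motif_to_transcript(motif, transcript)
            assert aln.identity == 1.0
            assert off <= aln.transcript_offset
            assert aln.transcript_offset + aln.length <= off + L

    def test_random_motif_identity_near_binomial_expectation(self):
        rng = np.random.default_rng(10)
        t = random_seq(rng, 1000)
        motif = random_seq(rng, 20)
        aln = mt.align_motif_to_transcript(motif, t)
        # best of ~2*981 windows of Bin(20, 1/4) matches: mean 5, sd ~1.94;
        # the maximum of that many draws sits several sds up but far from 20
        assert 5 <= aln.score <= 5 + 3 * np.sqrt(20 * 0.25 * 0.75) + 4
        assert aln.identity < 1.0

    def test_matches_exhaustive_offset_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            t = random_seq(rng, 200)
            motif = random_seq(rng, 12)
            aln = mt.align_motif_to_transcript(motif, t)
            best = -1
            for m in (motif, mt.revcomp(motif)):
                for off in range(len(t) - 12 + 1):
                    best = max(best, sum(a == b for a, b in zip(m, t[off : off + 12])))
            assert aln.score == best

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            mt.align_motif_to_transcript("", "ACGT")
        with pytest.raises(ValueError):
            mt.align_motif_to_transcript("ACGTT", "ACGT")


class TestDeletion:
    def test_deletion_covering_planted_segment_loses_motifs(self):
        rng = np.random.default_rng(12)
        t = random_seq(rng, 1200)
        transcript = t[:150] + ALU_CONSENSUS + t[450:]
        motifs_ = [ALU_CONSENSUS[i : i + 20] for i in (0, 100, 250)]
        deleted, lost = mt.apply_deletion(transcript, (150, 450), motifs_)
        assert len(deleted) == len(transcript) - 300
        assert all(lost.values())

    def test_zero_length_deletion_identity(self):
        deleted, lost = mt.apply_deletion("ACGTACGTACGT", (4, 4), ["ACGT"])
        assert deleted == "ACGTACGTACGT"
        assert not any(lost.values())

    def test_adjacent_deletion_retains_motif(self):
        rng = np.random.default_rng(13)
        t = random_seq(rng, 300)
        motif = t[100:120]
        _, lost = mt.apply_deletion(t, (120, 200), [motif])
        aln = mt.align_motif_to_transcript(motif, t)
        if aln.transcript_offset == 100:  # unique best placement
            assert not lost[motif]

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            mt.apply_deletion("ACGT", (2, 9), [])


class TestFormats:
    def test_jaspar_round_trip(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(
            ">MA0050.1 IRF1\n"
            "A  [ 0  3 20  1 ]\n"
            "C  [ 2  1  0  1 ]\n"
            "G  [ 1 16  0  1 ]\n"
            "T  [17  0  0 17 ]\n"
        )
        pwms = mt.read_jaspar(p)
        assert len(pwms) == 1
        assert pwms[0].name == "MA0050.1"
        assert pwms[0].consensus == "TGAT"

    def test_meme_minimal_reader(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF motif-1\n"
            "letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 1e-5\n"
            " 0.90 0.03 0.03 0.04\n"
            " 0.05 0.85 0.05 0.05\n"
            " 0.10 0.10 0.10 0.70\n"
        )
        pwms = mt.read_meme(p)
        assert len(pwms) == 1 and pwms[0].name == "motif-1"
        assert pwms[0].consensus == "ACT"
        assert len(pwms[0]) == 3
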