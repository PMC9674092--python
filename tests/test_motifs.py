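"""PWM scanning against a naive oracle, window orientation, enrichment."""

import numpy as np
import pytest
from scipy.stats import binom

from astrocilia import motifs as mo
from astrocilia import synthetic
from astrocilia.synthetic import reverse_complement

from conftest import CONSENSUS, consensus_counts

BASES = "ACGT"


def naive_scan(sequence, pwm, threshold):
    """Position-by-position rescan oracle: dict lookups, both strands."""
    hits = []
    lo = {(+1): pwm.log_odds, (-1): pwm.reverse_complement().log_odds}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    for strand, mat in (("+", lo[+1]), ("-", lo[-1])):
        for start in range(len(sequence) - pwm.width + 1):
            score = 0.0
            for j in range(pwm.width):
                score += mat[j, idx[sequence[start + j]]]
            if score >= threshold:
                hits.append((start + pwm.width // 2, strand, score))
    return sorted(hits)


def random_window(rng, length=150, half_width=None):
    seq = "".join(rng.choice(list(BASES), size=length))
    hw = half_width if half_width is not None else length // 2
    return mo.PromoterWindow("g", ".", 0, length, hw, "+", seq,
                             half_width=hw)


class TestPWM:
    def test_columns_sum_to_one(self):
        pwm = mo.PWM.from_counts("m", consensus_counts("ACGT"))
        np.testing.assert_allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_uniform_pwm_scores_exactly_zero(self):
        pwm = mo.PWM("u", np.full((4, 4), 0.25))
        rng = np.random.default_rng(0)
        w = random_window(rng, 60)
        hits = mo.scan_pwm(w, pwm)
        # log-odds identity: every position on both strands scores 0
        assert len(hits) == 2 * (60 - 4 + 1)
        assert all(h.score == 0.0 for h in hits)

    def test_consensus_and_max_score(self):
        pwm = mo.PWM.from_counts("m", consensus_counts("GATTACA"))
        assert pwm.consensus == "GATTACA"
        assert pwm.max_score > 0

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            mo.PWM("bad", np.ones((0, 4)))
        with pytest.raises(ValueError):
            mo.PWM("bad", np.ones((4, 3)))


class TestScan:
    def test_matches_naive_rescan_on_random_windows(self):
        pwm = mo.PWM.from_counts("soft", consensus_counts("TTGCCATG",
                                                          weight=6))
        threshold = 0.5 * pwm.max_score
        rng = np.random.default_rng(7)
        for _ in range(60):
            w = random_window(rng)
            got = sorted((h.offset + w.half_width, h.strand, h.score)
                         for h in mo.scan_pwm(w, pwm, threshold))
            expected = naive_scan(w.sequence, pwm, threshold)
            assert [(c, s) for c, s, _ in got] == \
                [(c, s) for c, s, _ in expected]
            np.testing.assert_allclose([x[2] for x in got],
                                       [x[2] for x in expected], atol=1e-9)

    def test_planted_consensus_at_minus_100_is_top_hit(self, small_genome,
                                                       strong_pwm):
        cfg = synthetic.PlantedSignalConfig(seed=13, motif_offset_mean=-100,
                                            motif_offset_sd=0.0)
        seqs, offsets = synthetic.make_promoters(small_genome, CONSENSUS, cfg)
        best = mo.best_hits(mo.scan_windows(
            mo.windows_from_sequences(seqs), strong_pwm))
        for gene, off in offsets.items():
            assert off == -100
            assert best[gene] is not None
            assert best[gene].offset == -100

    def test_all_n_window_has_no_hits(self, strong_pwm):
        w = mo.PromoterWindow("g", ".", 0, 100, 50, "+", "N" * 100,
                              half_width=50)
        assert mo.scan_pwm(w, strong_pwm) == []

    def test_n_bases_score_as_background(self):
        pwm = mo.PWM.from_counts("m", consensus_counts("ACG", weight=6))
        seq = "ANG" + "T" * 7
        w = mo.PromoterWindow("g", ".", 0, 10, 5, "+", seq, half_width=5)
        hits = mo.scan_pwm(w, pwm, score_threshold=-100.0)
        first = [h for h in hits if h.strand == "+" and
                 h.offset == 0 + pwm.width // 2 - 5][0]
        expected = pwm.log_odds[0, 0] + 0.0 + pwm.log_odds[2, 2]
        assert first.score == pytest.approx(expected)

    def test_strand_symmetry(self):
        # odd width so the hit center maps to the same physical base
        pwm = mo.PWM.from_counts("m", consensus_counts("TTGCC", weight=6))
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list(BASES), size=101))
        w_fwd = mo.PromoterWindow("g", ".", 0, 101, 50, "+", seq,
                                  half_width=50)
        w_rev = mo.PromoterWindow("g", ".", 0, 101, 50, "-",
                                  reverse_complement(seq), half_width=50)
        thr = 0.3 * pwm.max_score
        fwd = {(h.offset, h.strand, round(h.score, 9))
               for h in mo.scan_pwm(w_fwd, pwm, thr)}
        flip = {"+": "-", "-": "+"}
        rev = {(-h.offset, flip[h.strand], round(h.score, 9))
               for h in mo.scan_pwm(w_rev, pwm, thr)}
        assert fwd == rev

    def test_window_shorter_than_pwm_raises(self, strong_pwm):
        w = mo.PromoterWindow("g", ".", 0, 5, 2, "+", "ACGTA", half_width=2)
        with pytest.raises(ValueError):
            mo.scan_pwm(w, strong_pwm)


class TestExtractWindows:
    @pytest.fixture()
    def fasta(self, tmp_path):
        import pyfaidx
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list(BASES), size=20_000))
        path = tmp_path / "genome.fa"
        with open(path, "w") as fh:
            fh.write(">chr1\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
        return pyfaidx.Fasta(str(path)), seq

    def test_plus_strand_interval(self, fasta):
        import pandas as pd
        fa, seq = fasta
        genes = pd.DataFrame([("g", "chr1", 10_000, "+")],
                             columns=["gene_id", "chrom", "tss", "strand"])
        (w,) = mo.extract_promoter_windows(genes, fa)
        assert (w.start, w.end) == (9_500, 10_500)
        assert w.sequence == seq[9_500:10_500]
        assert not w.clipped
        assert w.offset_of_index(500) == 0

    def test_minus_strand_reverse_complemented(self, fasta):
        import pandas as pd
        fa, seq = fasta
        genes = pd.DataFrame([("g", "chr1", 10_000, "-")],
                             columns=["gene_id", "chrom", "tss", "strand"])
        (w,) = mo.extract_promoter_windows(genes, fa)
        assert (w.start, w.end) == (9_500, 10_500)
        assert w.sequence == reverse_complement(seq[9_500:10_500])
        # genomic 9,400 is outside the window; index 0 is the 3'-most base
        assert w.offset_of_index(0) == 10_000 - 10_499
        assert w.offset_of_index(len(w.sequence) - 1) == 500

    def test_edge_window_clipped_and_flagged(self, fasta):
        import pandas as pd
        fa, _ = fasta
        genes = pd.DataFrame([("g", "chr1", 200, "+")],
                             columns=["gene_id", "chrom", "tss", "strand"])
        (w,) = mo.extract_promoter_windows(genes, fa)
        assert w.clipped
        assert (w.start, w.end) == (0, 700)
        assert len(w.sequence) == 700

    def test_missing_chromosome_raises(self, fasta):
        import pandas as pd
        fa, _ = fasta
        genes = pd.DataFrame([("g", "chrX", 100, "+")],
                             columns=["gene_id", "chrom", "tss", "strand"])
        with pytest.raises(ValueError, match="chrX"):
            mo.extract_promoter_windows(genes, fa)


class TestCentralEnrichment:
    def _hit(self, gene, offset):
        return mo.MotifHit(gene, offset, "+", 10.0)

    def test_no_target_hits_gives_p_one(self):
        target = {"a": None, "b": None}
        negative = {f"n{i}": self._hit(f"n{i}", 0) for i in range(4)}
        res = mo.central_enrichment(target, negative, w_grid=(100,))
        assert res.pvalue == 1.0

    def test_tiny_instance_matches_hand_binomial(self):
        # 4 targets: 3 inside +/-50; negatives: 1 of 4 inside
        target = {"t1": self._hit("t1", 10), "t2": self._hit("t2", -40),
                  "t3": self._hit("t3", 45), "t4": self._hit("t4", 400)}
        negative = {"n1": self._hit("n1", 30), "n2": self._hit("n2", 300),
                    "n3": self._hit("n3", -200), "n4": self._hit("n4", 499)}
        res = mo.central_enrichment(target, negative, w_grid=(50,))
        expected = binom.sf(2, 4, 0.25)  # P(X >= 3), X ~ Bin(4, 1/4)
        hand = sum(
            __import__("math").comb(4, k) * 0.25 ** k * 0.75 ** (4 - k)
            for k in (3, 4))
        assert expected == pytest.approx(hand, rel=1e-12)
        assert res.pvalue == pytest.approx(hand, rel=1e-9)
        assert res.k_target == 3 and res.k_negative == 1

    def test_bonferroni_over_width_grid(self):
        target = {"t1": self._hit("t1", 10)}
        negative = {f"n{i}": self._hit(f"n{i}", 200) for i in range(10)}
        single = mo.central_enrichment(target, negative, w_grid=(50,))
        multi = mo.central_enrichment(target, negative, w_grid=(50, 100, 150))
        assert multi.n_widths_tested == 3
        assert multi.pvalue == pytest.approx(min(1.0, 3 * single.pvalue))

    def test_planted_central_signal_detected(self, small_genome, strong_pwm):
        cfg = synthetic.PlantedSignalConfig(seed=17, motif_offset_sd=50.0)
        planted = small_genome.genes["gene_id"].tolist()[:25]
        seqs, _ = synthetic.make_promoters(small_genome, CONSENSUS, cfg,
                                           plant_genes=planted)
        windows = {w.gene_id: w for w
                   in mo.windows_from_sequences(seqs)}
        t_best = mo.best_hits(mo.scan_windows(
            [windows[g] for g in planted], strong_pwm))
        others = [g for g in windows if g not in planted]
        n_best = mo.best_hits(mo.scan_windows(
            [windows[g] for g in others], strong_pwm))
        res = mo.central_enrichment(t_best, n_best)
        assert res.pvalue <= 0.01


class TestProbabilityCurve:
    def test_all_hits_central_bin(self):
        best = {f"g{i}": mo.MotifHit(f"g{i}", 0, "+", 5.0) for i in range(8)}
        curve = mo.motif_probability_curve(best, half_width=500, bin_width=50)
        assert curve["probability"].sum() == pytest.approx(1.0)
        peak = curve.loc[curve["probability"].idxmax()]
        assert peak["offset_left"] <= 0 < peak["offset_right"]

    def test_no_hits_gives_zero_curve(self):
        best = {"g1": None, "g2": None}
        curve = mo.motif_probability_curve(best, half_width=500, bin_width=50)
        assert (curve["probability"] == 0).all()

    def test_mass_bounded_by_one(self):
        best = {"g1": mo.MotifHit("g1", -10, "+", 5.0), "g2": None}
        curve = mo.motif_probability_curve(best, half_width=500, bin_width=50)
        assert curve["probability"].sum() <= 1.0

    def test_uneven_bins_rejected(self):
        with pytest.raises(ValueError):
            mo.motif_probability_curve({}, half_width=500, bin_width=33)


class TestMotifFormats:
    def test_jaspar_roundtrip(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(">MA0001.1 TEST\n"
                        "A [ 10  0  2 ]\n"
                        "C [  0 12  2 ]\n"
                        "G [  1  0  6 ]\n"
                        "T [  1  0  2 ]\n")
        (pwm,) = mo.load_jaspar(path)
        assert pwm.motif_id == "MA0001.1"
        assert pwm.width == 3
        assert pwm.consensus == "ACG"

    def test_meme_minimal_roundtrip(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF TEST1\n"
            "letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0\n"
            "0.900000 0.033333 0.033333 0.033334\n"
            "0.033333 0.900000 0.033333 0.033334\n"
            "0.100000 0.100000 0.700000 0.100000\n")
        (pwm,) = mo.load_meme_minimal(path)
        assert pwm.motif_id == "TEST1"
        assert pwm.consensus == "ACG"
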