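import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromcompare.io import GenomicInterval, Peak
from chromcompare.motif import (
    PWM,
    build_pwm,
    motif_occurrence_matrix,
    read_jaspar,
    scan_sequence,
    write_jaspar,
)

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(_COMP)[::-1]


def naive_scan(pwm, sequence, threshold):
    """Independent per-window enumeration oracle."""
    L = len(pwm)
    lo = pwm.log_odds
    idx = {b: i for i, b in enumerate("ACGT")}
    hits = []
    for start in range(len(sequence) - L + 1):
        window = sequence[start : start + L].upper()
        if any(b not in idx for b in window):
            continue
        fwd = sum(lo[i, idx[b]] for i, b in enumerate(window))
        if fwd >= threshold:
            hits.append((start, "+", fwd))
        rc = revcomp(window)
        rev = sum(lo[i, idx[b]] for i, b in enumerate(rc))
        if rev >= threshold:
            hits.append((start, "-", rev))
    return hits


class TestBuildPwm:
    def test_identical_sequences_no_pseudocount_are_point_masses(self):
        pwm = build_pwm(["ACGT"] * 10, pseudocount_weight=0)
        assert pwm.consensus == "ACGT"
        np.testing.assert_allclose(pwm.probs.max(axis=1), 1.0)

    def test_uniform_column_has_zero_information(self):
        pwm = build_pwm(
            ["AA", "CA", "GA", "TA"], pseudocount_weight=0, background=[0.25] * 4
        )
        np.testing.assert_allclose(pwm.probs[0], 0.25)
        assert pwm.information_content()[0] == pytest.approx(0.0, abs=1e-12)
        assert pwm.information_content()[1] == pytest.approx(2.0)

    def test_hand_computed_counts_with_pseudocount_one(self):
        seqs = ["ACGTAC", "ACGTAA", "ATGTAC", "GCGTAC"]
        bg = [0.25] * 4
        pwm = build_pwm(seqs, pseudocount_weight=1.0, background=bg)
        # position 0: A=3, G=1 -> (3 + 0.25)/5, (1 + 0.25)/5, others 0.25/5
        np.testing.assert_allclose(
            pwm.probs[0], [3.25 / 5, 0.25 / 5, 1.25 / 5, 0.25 / 5]
        )
        # position 5: C=3, A=1
        np.testing.assert_allclose(
            pwm.probs[5], [1.25 / 5, 3.25 / 5, 0.25 / 5, 0.25 / 5]
        )

    def test_n_bases_excluded_from_counts(self):
        pwm = build_pwm(["AN", "AN", "AC"], pseudocount_weight=0, background=[0.25] * 4)
        np.testing.assert_allclose(pwm.probs[1], [0, 1, 0, 0])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACG", "AC"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_pwm([])

    def test_columns_sum_to_one_and_ic_in_range(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(30)]
        pwm = build_pwm(seqs)
        np.testing.assert_allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)
        ic = pwm.information_content()
        assert (ic >= -1e-9).all() and (ic <= 2 + 1e-9).all()


class TestScanSequence:
    def mk_pwm(self):
        return build_pwm(
            ["ACGTAC", "ACGTAA", "ATGTAC", "GCGTAC"], background=[0.25] * 4
        )

    def test_consensus_scores_maximum(self):
        pwm = self.mk_pwm()
        hits = scan_sequence(pwm, pwm.consensus, threshold=pwm.max_score - 1e-9)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].score == pytest.approx(pwm.max_score)

    def test_reverse_complement_symmetry(self, rng):
        pwm = self.mk_pwm()
        seq = "".join(rng.choice(list("ACGT"), size=300))
        thr = 0.5 * pwm.max_score
        fwd_hits = scan_sequence(pwm, seq, threshold=thr)
        rc_hits = scan_sequence(pwm, revcomp(seq), threshold=thr)
        mapped = sorted(
            (len(seq) - (h.start + len(pwm)), "-" if h.strand == "+" else "+",
             round(h.score, 9))
            for h in rc_hits
        )
        assert mapped == sorted(
            (h.start, h.strand, round(h.score, 9)) for h in fwd_hits
        )

    def test_case_insensitive(self):
        pwm = self.mk_pwm()
        seq = "tt" + pwm.consensus.lower() + "gg"
        hits = scan_sequence(pwm, seq, threshold=0.9 * pwm.max_score)
        assert any(h.start == 2 and h.strand == "+" for h in hits)

    def test_windows_with_n_skipped(self):
        pwm = self.mk_pwm()
        seq = pwm.consensus[:3] + "N" + pwm.consensus[4:]
        assert scan_sequence(pwm, seq, threshold=-100.0) == []

    def test_threshold_above_max_warns_and_returns_empty(self):
        pwm = self.mk_pwm()
        with pytest.warns(UserWarning, match="maximum"):
            hits = scan_sequence(pwm, pwm.consensus, threshold=pwm.max_score + 1)
        assert hits == []

    def test_matches_naive_enumeration_oracle(self, rng):
        for _ in range(100):
            seqs = ["".join(rng.choice(list("ACGT"), size=6)) for _ in range(5)]
            pwm = build_pwm(seqs, background=[0.25] * 4)
            seq = "".join(rng.choice(list("ACGTN"), size=200, p=[0.24] * 4 + [0.04]))
            thr = float(rng.uniform(0.2, 0.8)) * pwm.max_score
            got = sorted(
                (h.start, h.strand, round(h.score, 9))
                for h in scan_sequence(pwm, seq, threshold=thr)
            )
            expected = sorted(
                (s, st_, round(sc, 9)) for s, st_, sc in naive_scan(pwm, seq, thr)
            )
            assert got == expected


class TestOccurrenceMatrix:
    def mk_sites(self, centers):
        return [
            Peak(GenomicInterval("chr1", c - 150, c + 150), summit=c) for c in centers
        ]

    def test_no_hits_zero_matrix(self):
        m = motif_occurrence_matrix([], self.mk_sites([10_000, 20_000]))
        assert m.values.sum() == 0

    def test_hit_at_each_center_fills_central_bin(self):
        from chromcompare.motif import MotifHit

        centers = [10_000, 20_000, 30_000]
        hits = [MotifHit("chr1", c, "+", 5.0) for c in centers]
        m = motif_occurrence_matrix(hits, self.mk_sites(centers))
        central = np.flatnonzero(m.bin_edges[:-1] == 0)[0]
        np.testing.assert_array_equal(m.values[:, central], 1.0)
        assert m.values.sum() == 3

    def test_matches_independent_binning_oracle(self, rng):
        from chromcompare.motif import MotifHit

        centers = [int(c) for c in rng.integers(5_000, 95_000, size=20)]
        sites = self.mk_sites(centers)
        hits = [
            MotifHit("chr1", int(p), "+", 1.0)
            for p in rng.integers(0, 100_000, size=500)
        ]
        m = motif_occurrence_matrix(hits, sites, flank=2_000, bin_size=50)
        expected = np.zeros((20, 80))
        for h in hits:
            for i, c in enumerate(centers):
                off = h.start - c
                if -2_000 <= off < 2_000:
                    expected[i, (off + 2_000) // 50] += 1
        np.testing.assert_array_equal(m.values, expected)


class TestJaspar:
    def test_round_trip(self, tmp_path, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(20)]
        pwm = build_pwm(seqs, background=[0.25] * 4, name="TEST")
        path = tmp_path / "m.jaspar"
        write_jaspar(pwm, path, scale=10_000)
        again = read_jaspar(path)
        assert again.name == "TEST"
        assert len(again) == len(pwm)
        np.testing.assert_allclose(again.probs, pwm.probs, atol=2e-3)

    def test_missing_row_rejected(self, tmp_path):
        path = tmp_path / "bad.jaspar"
        path.write_text(">X\nA [ 1 2 ]\nC [ 1 2 ]\nG [ 1 2 ]\n")
        with pytest.raises(ValueError):
            read_jaspar(path)


class TestPlantedMotifRecovery:
    def test_planted_instances_recovered_and_false_rate_bounded(self, truth):
        """>=95% of planted (mutated) motif instances found at the default
        threshold, and the genome-wide false-hit rate is within a factor of
        two of the analytic expectation from the score distribution."""
        from chromcompare.motif import scan_genome

        pwm = truth.truth_pwm
        hits = scan_genome(pwm, truth.genome, threshold_frac=0.6)
        hit_pos = {(h.chrom, h.start) for h in hits}
        planted = truth.planted_motifs
        recovered = sum((c, s) in hit_pos for c, s, _ in planted)
        assert recovered / len(planted) >= 0.95

        # exact score distribution of a background window by convolution
        threshold = 0.6 * pwm.max_score
        lo = pwm.log_odds
        bg = pwm.background
        dist = {0.0: 1.0}
        for i in range(len(pwm)):
            new = {}
            for s, p in dist.items():
                for b in range(4):
                    key = round(s + lo[i, b], 6)
                    new[key] = new.get(key, 0.0) + p * bg[b]
            dist = new
        p_hit = sum(p for s, p in dist.items() if s >= threshold)
        genome_size = sum(len(s) for s in truth.genome.values())
        expected_false = 2 * genome_size * p_hit  # both strands
        planted_hits = sum((c, s) in {(c2, s2) for c2, s2, _ in planted} for c, s in hit_pos)
        observed_false = len(hits) - planted_hits
        assert observed_false <= max(2.0, 2 * expected_false) + 5
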