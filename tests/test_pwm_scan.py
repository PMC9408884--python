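"""PWM construction, window scoring, FPR calibration and peak scanning."""

import itertools
import math

import numpy as np
import pytest

from mcotce import (
    FrequencyMatrix,
    PeakSet,
    build_pwm,
    calibrate,
    demo_motif,
    make_calibration,
    scan_peaks,
    score_window,
)
from mcotce.pwm_scan import (
    CalibrationError,
    all_window_scores,
    reverse_complement,
)

UNIFORM = np.full(4, 0.25)


def naive_score(pwm, window):
    """Independent per-position table-lookup oracle."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    return sum(pwm.weights[i, idx[b]] for i, b in enumerate(window))


class TestBuildPwm:
    def test_uniform_column_scores_zero(self):
        fm = FrequencyMatrix("u", np.full((4, 4), 25.0))
        pwm = build_pwm(fm, UNIFORM, pseudocount=3.7)
        assert np.allclose(pwm.weights, 0.0)

    def test_hand_computed_strong_column(self):
        # counts (100,0,0,0), uniform bg, pseudocount 1:
        # w_A = log2((100 + 0.25)/101) - log2(0.25)
        fm = FrequencyMatrix("s", np.array([[100, 0, 0, 0]] * 4, float))
        pwm = build_pwm(fm, UNIFORM, pseudocount=1.0)
        expected = math.log2(100.25 / 101) - math.log2(0.25)
        assert pwm.weights[0, 0] == pytest.approx(expected, abs=1e-12)
        assert pwm.weights[0, 0] == pytest.approx(1.9893, abs=1e-4)

    def test_probability_matrix_scaled_to_depth_100(self):
        probs = np.array([[0.7, 0.1, 0.1, 0.1]] * 4)
        fm_p = FrequencyMatrix("p", probs, is_counts=False)
        fm_c = FrequencyMatrix("c", probs * 100, is_counts=True)
        assert np.allclose(
            build_pwm(fm_p, UNIFORM).weights, build_pwm(fm_c, UNIFORM).weights
        )

    def test_zero_background_entry_rejected(self):
        fm = demo_motif("m", "ACGT")
        with pytest.raises(ValueError):
            build_pwm(fm, np.array([0.5, 0.5, 0.0, 0.0]))

    def test_min_below_max(self):
        pwm = build_pwm(demo_motif("m", "ACGTA"), UNIFORM)
        assert pwm.min_score < pwm.max_score


class TestScoreWindow:
    def test_uniform_pwm_scores_zero(self):
        pwm = build_pwm(FrequencyMatrix("u", np.full((5, 4), 10.0)), UNIFORM)
        assert score_window(pwm, "ACGTA") == pytest.approx(0.0)

    def test_consensus_achieves_max(self):
        pwm = build_pwm(demo_motif("m", "ACGT"), UNIFORM)
        assert score_window(pwm, "ACGT") == pytest.approx(pwm.max_score)

    def test_all_windows_match_lookup_oracle(self):
        # toy motif, exhaustive enumeration of all 4^4 windows
        fm = FrequencyMatrix(
            "toy", np.array([[90, 4, 3, 3], [2, 2, 94, 2],
                             [25, 25, 25, 25], [10, 20, 30, 40]], float)
        )
        pwm = build_pwm(fm, np.array([0.3, 0.2, 0.2, 0.3]))
        for w in itertools.product("ACGT", repeat=4):
            w = "".join(w)
            assert score_window(pwm, w) == pytest.approx(
                naive_score(pwm, w), abs=1e-12
            )

    def test_length_mismatch_and_n(self):
        pwm = build_pwm(demo_motif("m", "ACGT"), UNIFORM)
        with pytest.raises(ValueError):
            score_window(pwm, "ACGTA")
        with pytest.raises(ValueError):
            score_window(pwm, "ACNT")

    def test_random_pairs_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            L = int(rng.integers(4, 13))
            fm = FrequencyMatrix(
                "r", rng.integers(1, 100, size=(L, 4)).astype(float)
            )
            bg = rng.dirichlet(np.ones(4) * 5)
            bg = np.maximum(bg, 1e-3)
            bg /= bg.sum()
            pwm = build_pwm(fm, bg)
            w = "".join(rng.choice(list("ACGT"), size=L))
            assert score_window(pwm, w) == pytest.approx(
                naive_score(pwm, w), abs=1e-12
            )


class TestCalibrate:
    def test_edge_zero_gives_min_achievable(self, calibration_small):
        pwm = build_pwm(demo_motif("m", "ACGTA"), UNIFORM)
        cm = calibrate(pwm, calibration_small, cl_edges=(0.0, 1.0, 2.0, 2.5, 3.0),
                       cl_min=0.0)
        # FPR <= 1 holds everywhere: threshold is the minimum achievable score
        assert cm.cl_thresholds[0] == pytest.approx(cm.score_grid.min())

    def test_fpr_at_thresholds_matches_enumeration(self):
        cal = make_calibration(10_000, seed=9)
        pwm = build_pwm(demo_motif("toy", "ACGTAC"), cal.base_frequencies())
        cm = calibrate(pwm, cal, cl_edges=(1.0, 1.5, 2.0, 2.5, 3.0), cl_min=1.0)
        scores = all_window_scores(pwm, cal.sequences())
        for t, edge in zip(cm.cl_thresholds, cm.cl_edges):
            if np.isfinite(t):
                direct_fpr = float((scores >= t).mean())
                assert direct_fpr <= 10 ** (-edge)
                assert direct_fpr == pytest.approx(float(cm.fpr(t)), abs=1e-15)

    def test_calibration_too_small(self):
        cal = make_calibration(1_000, seed=1)
        pwm = build_pwm(demo_motif("m", "ACGTA"), UNIFORM)
        with pytest.raises(CalibrationError, match="larger"):
            calibrate(pwm, cal, cl_edges=(3.5, 4.0, 4.5, 5.0, 5.5))

    def test_motif_longer_than_calibration(self):
        cal = PeakSet(records=[("c1", "ACGT")])
        pwm = build_pwm(demo_motif("m", "ACGTACGTAC"), UNIFORM)
        with pytest.raises(CalibrationError):
            calibrate(pwm, cal, cl_edges=(0.0, 0.1, 0.2, 0.3, 0.4))

    def test_fpr_monotone_and_cl_nondecreasing(self, anchor_calibrated):
        cm = anchor_calibrated
        assert np.all(np.diff(cm.fpr_grid) >= 0)  # descending scores
        s = np.linspace(cm.score_grid.min(), cm.score_grid.max(), 200)
        cl = cm.cl(s)
        assert np.all(np.diff(cl) >= -1e-12)


class TestScanPeaks:
    def test_peak_shorter_than_motif(self, anchor_calibrated):
        peaks = PeakSet(records=[("p1", "ACGT")])
        hits = scan_peaks(anchor_calibrated, peaks)
        assert hits["p1"] == []

    def test_exact_consensus_single_hit(self, anchor_motif, anchor_calibrated):
        cons = anchor_motif.consensus()
        peaks = PeakSet(records=[("p1", cons)])
        hits = scan_peaks(anchor_calibrated, peaks)["p1"]
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1 and fwd[0].start == 0
        if cons != reverse_complement(cons):
            rev = [h for h in hits if h.strand == "-"]
            # the reverse strand may or may not pass threshold, but never
            # reports the consensus itself as a second forward hit
            assert all(h.start == 0 for h in rev)

    def test_planted_consensus_found(self, anchor_motif, anchor_calibrated):
        rng = np.random.default_rng(37)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        cons = anchor_motif.consensus()
        seq = seq[:37] + cons + seq[37 + len(cons):]
        hits = scan_peaks(anchor_calibrated, PeakSet(records=[("p", seq)]))["p"]
        assert any(h.start == 37 and h.strand == "+" for h in hits)

    def test_n_windows_skipped(self, anchor_motif, anchor_calibrated):
        cons = anchor_motif.consensus()
        seq = cons[:4] + "N" + cons[5:]
        hits = scan_peaks(anchor_calibrated, PeakSet(records=[("p", seq)]))["p"]
        assert hits == []

    def test_strand_symmetry(self, anchor_calibrated):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        # ensure at least one hit by planting the consensus
        seq = "TGTTTACTTA" + seq[10:]
        peaks = PeakSet(records=[("p", seq)])
        mirrored = PeakSet(records=[("p", reverse_complement(seq))])
        hits = scan_peaks(anchor_calibrated, peaks)["p"]
        mhits = scan_peaks(anchor_calibrated, mirrored)["p"]
        n = len(seq)
        remapped = sorted(
            (n - h.end, n - h.start, "-" if h.strand == "+" else "+",
             round(h.score, 9))
            for h in hits
        )
        got = sorted(
            (h.start, h.end, h.strand, round(h.score, 9)) for h in mhits
        )
        assert remapped == got

    def test_cl_min_monotonicity(self, anchor_motif, calibration_small):
        rng = np.random.default_rng(13)
        seqs = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(30)]
        cons = anchor_motif.consensus()
        seqs = [cons + s[len(cons):] for s in seqs]
        peaks = PeakSet(records=[(f"p{i}", s) for i, s in enumerate(seqs)])
        pwm = build_pwm(anchor_motif, calibration_small.base_frequencies())
        loose = calibrate(pwm, calibration_small, cl_min=2.0)
        tight = calibrate(pwm, calibration_small, cl_min=4.0)
        h_loose = scan_peaks(loose, peaks)
        h_tight = scan_peaks(tight, peaks)
        for pid in peaks.ids:
            expected = [h for h in h_loose[pid] if h.cl >= 4.0]
            assert [(h.start, h.strand) for h in expected] == [
                (h.start, h.strand) for h in h_tight[pid]
            ]
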