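"""Shuffles, background generation, and the CE classification taxonomy."""

from collections import Counter

import numpy as np
import pytest

from mcotce import (
    PeakSet,
    classify_location,
    classify_orientation,
    enumerate_ces,
    generate_background,
    shuffle_sequence,
)
from mcotce.pwm_scan import MotifHit


def hit(start, end, strand="+", peak="p", score=0.0, cl=3.0):
    return MotifHit(peak, start, end, strand, score, cl)


def dinucleotide_counts(s):
    return Counter(zip(s, s[1:]))


class TestShuffle:
    @pytest.mark.parametrize("mode", ["mono", "di"])
    def test_single_letter_fixed_point(self, mode):
        assert shuffle_sequence("AAAA", mode, seed=1) == "AAAA"

    def test_mono_preserves_composition(self):
        out = shuffle_sequence("ACGTACGT", "mono", seed=2)
        assert Counter(out) == Counter("ACGTACGT")

    def test_di_preserves_dinucleotides_exhaustively(self):
        rng = np.random.default_rng(7)
        for i in range(300):
            n = int(rng.integers(2, 101))
            s = "".join(rng.choice(list("ACGT"), size=n))
            t = shuffle_sequence(s, "di", seed=i)
            assert dinucleotide_counts(t) == dinucleotide_counts(s)
            assert t[0] == s[0] and t[-1] == s[-1]

    def test_determinism(self):
        s = "ACGTTGCAACGTGGCA"
        assert shuffle_sequence(s, "di", 5) == shuffle_sequence(s, "di", 5)
        assert shuffle_sequence(s, "mono", 5) == shuffle_sequence(s, "mono", 5)


class TestBackground:
    def test_counts_and_ids(self):
        peaks = PeakSet(records=[(f"p{i}", "ACGTACGTAC") for i in range(10)])
        bg = generate_background(peaks, reps=1, mode="mono", seed=3)
        assert len(bg.peaks) == 10
        assert bg.peaks.ids[0] == "p0#1"

    def test_byte_identical_with_same_seed(self):
        peaks = PeakSet(records=[("a", "ACGTTGCA"), ("b", "GGGTTTAA")])
        b1 = generate_background(peaks, reps=3, mode="di", seed=9)
        b2 = generate_background(peaks, reps=3, mode="di", seed=9)
        assert b1.peaks.records == b2.peaks.records

    def test_reps_and_composition(self):
        rng = np.random.default_rng(1)
        peaks = PeakSet(
            records=[
                (f"p{i}", "".join(rng.choice(list("ACGT"), size=60)))
                for i in range(5)
            ]
        )
        bg = generate_background(peaks, reps=10, mode="di", seed=4)
        assert len(bg.peaks) == 50
        src = dict(peaks.records)
        for bid, seq in bg.peaks:
            origin = src[bid.rsplit("#", 1)[0]]
            assert dinucleotide_counts(seq) == dinucleotide_counts(origin)


class TestOrientation:
    @pytest.mark.parametrize(
        "a,p,expected",
        [
            (hit(10, 18, "+"), hit(20, 26, "+"), "DirectAP"),
            (hit(20, 26, "+"), hit(10, 18, "+"), "DirectPA"),
            (hit(10, 18, "-"), hit(20, 26, "-"), "DirectPA"),
            (hit(20, 26, "-"), hit(10, 18, "-"), "DirectAP"),
            (hit(10, 18, "+"), hit(20, 26, "-"), "Inverted"),
            (hit(10, 18, "-"), hit(20, 26, "+"), "Everted"),
            (hit(20, 26, "-"), hit(10, 18, "+"), "Inverted"),
        ],
    )
    def test_convention(self, a, p, expected):
        assert classify_orientation(a, p) == expected

    def test_different_peaks_rejected(self):
        with pytest.raises(ValueError):
            classify_orientation(hit(0, 8, peak="x"), hit(10, 18, peak="y"))


class TestLocation:
    def test_full_containment(self):
        c = classify_location(hit(10, 18), hit(12, 16))
        assert c.location == "Full" and c.overlap_len == 4
        assert c.border_distance == 2
        # containment is symmetric in the interval sense
        c2 = classify_location(hit(12, 16), hit(10, 18))
        assert c2.location == "Full" and c2.overlap_len == 4

    def test_partial_overlap(self):
        c = classify_location(hit(10, 18), hit(14, 22))
        assert c.location == "Partial" and c.overlap_len == 4

    def test_spacer_boundaries(self):
        c = classify_location(hit(10, 18), hit(18, 24), 0, 29)
        assert c.location == "Spacer" and c.spacer_len == 0
        assert classify_location(hit(10, 18), hit(50, 56), 0, 29) is None
        c = classify_location(hit(10, 18), hit(47, 53), 0, 29)
        assert c.location == "Spacer" and c.spacer_len == 29

    def test_taxonomy_total_and_exclusive(self):
        rng = np.random.default_rng(21)
        n_full = n_partial = n_intersecting = 0
        for _ in range(10_000):
            s1, s2 = rng.integers(0, 80, size=2)
            l1, l2 = rng.integers(4, 13, size=2)
            a = hit(int(s1), int(s1 + l1), str(rng.choice(["+", "-"])))
            p = hit(int(s2), int(s2 + l2), str(rng.choice(["+", "-"])))
            assert classify_orientation(a, p) in (
                "DirectAP", "DirectPA", "Inverted", "Everted",
            )
            c = classify_location(a, p, 0, 29)
            assert c is None or c.location in ("Full", "Partial", "Spacer")
            inter = min(a.end, p.end) - max(a.start, p.start)
            if inter > 0:
                n_intersecting += 1
                n_full += c.location == "Full"
                n_partial += c.location == "Partial"
        assert n_full + n_partial == n_intersecting

    def test_mirror_invariance(self):
        rng = np.random.default_rng(22)
        L = 120
        for _ in range(5_000):
            s1, s2 = rng.integers(0, 100, size=2)
            l1, l2 = rng.integers(4, 13, size=2)
            a = hit(int(s1), int(s1 + l1), str(rng.choice(["+", "-"])))
            p = hit(int(s2), int(s2 + l2), str(rng.choice(["+", "-"])))
            flip = lambda h: MotifHit(
                h.peak_id, L - h.end, L - h.start,
                "+" if h.strand == "-" else "-", h.score, h.cl,
            )
            assert classify_orientation(a, p) == classify_orientation(
                flip(a), flip(p)
            )
            c1 = classify_location(a, p, 0, 29)
            c2 = classify_location(flip(a), flip(p), 0, 29)
            assert (c1 is None) == (c2 is None)
            if c1 is not None:
                assert c1 == c2


class TestEnumerate:
    def test_single_heterotypic_pair(self):
        ces = enumerate_ces(
            {"p": [hit(10, 18)]}, {"p": [hit(23, 29)]}, 0, 29
        )
        assert len(ces) == 1
        assert ces[0].location == "Spacer" and ces[0].spacer_len == 5

    def test_homotypic_unordered(self):
        a1, a2 = hit(10, 18, "+", score=5.0), hit(30, 38, "+", score=3.0)
        ces = enumerate_ces({"p": [a1, a2]}, None, 0, 29)
        assert len(ces) == 1
        assert ces[0].anchor == a1  # higher score takes the anchor role

    def test_homotypic_identical_coordinates_excluded(self):
        a1 = hit(10, 18, "+", score=5.0)
        ces = enumerate_ces({"p": [a1, a1]}, None, 0, 29)
        assert ces == []

    def test_exhaustive_pairing(self):
        ahits = [hit(0, 8), hit(20, 28)]
        phits = [hit(5, 11), hit(30, 36), hit(50, 56)]
        ces = enumerate_ces({"p": ahits}, {"p": phits}, 0, 50)
        # oracle: all 6 ordered pairs classify within limits
        assert len(ces) == 6

    def test_flow_nesting(self):
        rng = np.random.default_rng(30)
        ahits = [
            hit(int(s), int(s) + 8, str(rng.choice(["+", "-"])), cl=4.0)
            for s in rng.integers(0, 250, size=15)
        ]
        phits = [
            hit(int(s), int(s) + 6, str(rng.choice(["+", "-"])), cl=3.5)
            for s in rng.integers(0, 250, size=15)
        ]
        ces = enumerate_ces({"p": ahits}, {"p": phits}, 0, 29)
        n = {f: sum(ce.in_flow(f) for ce in ces)
             for f in ("Full", "Partial", "Overlap", "Spacer", "Any")}
        assert n["Overlap"] == n["Full"] + n["Partial"]
        assert n["Any"] == n["Overlap"] + n["Spacer"]

    def test_conservation_relation(self):
        ces = enumerate_ces(
            {"p": [hit(10, 18, cl=5.0)]}, {"p": [hit(20, 26, cl=3.2)]}, 0, 29
        )
        assert ces[0].conservation_relation == "anchor_more"
        ces = enumerate_ces(
            {"p": [hit(10, 18, cl=3.0)]}, {"p": [hit(20, 26, cl=3.0)]}, 0, 29
        )
        assert ces[0].conservation_relation == "tie"

    def test_geometry_labels(self):
        full = enumerate_ces({"p": [hit(10, 20)]}, {"p": [hit(13, 19)]}, 0, 29)[0]
        assert full.geometry_label() == "1F"  # border distance min(3, 1)
        partial = enumerate_ces({"p": [hit(10, 18)]}, {"p": [hit(14, 22)]}, 0, 29)[0]
        assert partial.geometry_label() == "4P"
        spacer = enumerate_ces({"p": [hit(10, 18)]}, {"p": [hit(23, 29)]}, 0, 29)[0]
        assert spacer.geometry_label() == "5S"
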