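"""Calibrate a motif against a background set and map its hits in peaks.

Builds a position weight matrix from a count matrix, calibrates score
thresholds so each hit carries a conservation level CL = -log10 of its
empirical false-positive rate, and scans a few sequences on both strands.
"""

from mcotce import (
    PeakSet, build_pwm, calibrate, demo_motif, make_calibration, scan_peaks,
)

anchor = demo_motif("FoxLike", "TGTTTACTTA")
print(f"motif {anchor.motif_id}: consensus {anchor.consensus()}")

# surrogate for a genome-scale promoter set: 400 kb of Markov-0 background
calibration = make_calibration(400_000, seed=11)
pwm = build_pwm(anchor, background=calibration.base_frequencies())
cm = calibrate(pwm, calibration)
print(f"calibrated on {cm.n_calibration_windows} windows; "
      f"score thresholds for CL ranges {cm.cl_edges}:")
print("  ", [round(float(t), 2) for t in cm.cl_thresholds])

# one peak carries the consensus at position 20, one is pure background
peaks = PeakSet(records=[
    ("peak_with_site", "ACGT" * 5 + "TGTTTACTTA" + "ACGT" * 5),
    ("peak_without", "ACGTACGTACGTACGTACGTACGTACGTACGT"),
])
hits = scan_peaks(cm, peaks)
for pid, hs in hits.items():
    print(f"{pid}: {len(hs)} hit(s)")
    for h in hs:
        print(f"  [{h.start},{h.end}) strand {h.strand} "
              f"score {h.score:.2f} CL {h.cl:.2f}")
# The consensus hit scores the PWM maximum, so its CL is the deepest
# level the calibration set can resolve; the background peak is empty.
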