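"""Plant composite elements with known geometry and recover them.

Half of 300 synthetic peaks receive an Anchor site and a Partner site in
DirectAP orientation separated by a 5 bp spacer; the full pipeline then
tests every location flow against a dinucleotide-shuffled background.
"""

from mcotce import (
    PlantSpec, RunConfig, demo_motif, make_calibration, plant, random_peaks,
    run_pair,
)

anchor = demo_motif("Anchor", "TGTTTACTTA")
partner = demo_motif("Partner", "GTTAATGATT")

peaks = random_peaks(300, 300, seed=1)
spec = PlantSpec(
    anchor, partner, orientation="DirectAP", location="Spacer", geometry=5,
    fraction_of_peaks=0.5, seed=2,
)
planted, truth = plant(peaks, spec)
print(f"planted {len(truth)} CEs in {len(planted)} peaks")

calibration = make_calibration(400_000, seed=3)
result = run_pair(planted, anchor, partner, RunConfig(seed=4),
                  calibration=calibration)

mr = result.motif("Partner")
print("\nCE enrichment, -log10 p per flow (foreground vs background):")
for flow in ("Full", "Partial", "Overlap", "Spacer", "Any"):
    print(f"  {flow:8s} {mr.flow_neg_log10_p(flow):8.2f}")
print(f"\nmost common variant: {mr.histogram.top_variant()}")
print(f"motif similarity p = {mr.similarity.p_value:.3f} "
      f"(flagged similar: {mr.similarity.similar})")
# The Spacer flow dominates (the planted geometry), the modal histogram
# variant is (DirectAP, '5S'), and the two motifs are not similar, so the
# co-occurrence is not a self-match artefact.
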