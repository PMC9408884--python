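"""Seeded synthetic data: random peaks, calibration sequences, and peaks
with planted composite elements of known geometry and conservation.

The generators make the whole pipeline testable without any external
download: ``make_calibration`` stands in for a genome-scale promoter set
(a Markov-0 background of the same base composition), and ``plant``
writes Anchor/Partner site pairs realising an exact orientation /
location / geometry into a controlled fraction of peaks, together with a
BED-like truth table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ce_core import ORIENTATIONS, LOCATIONS
from .motif_io import ALPHABET, FrequencyMatrix, PeakSet
from .pwm_scan import reverse_complement

UNIFORM = (0.25, 0.25, 0.25, 0.25)


def _random_seq(n: int, freqs: np.ndarray, rng: np.random.Generator) -> str:
    codes = rng.choice(4, size=n, p=freqs)
    lut = np.array(list(ALPHABET))
    return "".join(lut[codes])


def random_peaks(
    n: int, length: int, base_freqs=UNIFORM, seed: int = 0
) -> PeakSet:
    """n i.i.d. Markov-0 sequences of the given length; deterministic per
    seed.  Ids are ``peak1..peakN``."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    freqs = np.asarray(base_freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("base_freqs must sum to 1")
    rng = np.random.default_rng(seed)
    records = [(f"peak{i+1}", _random_seq(length, freqs, rng)) for i in range(n)]
    return PeakSet(records=records, source_path=f"<random:seed={seed}>")


def make_calibration(
    length_total: int, base_freqs=UNIFORM, seed: int = 0, chunk: int = 10_000
) -> PeakSet:
    """Markov-0 calibration sequences totalling ``length_total`` bases,
    chunked for convenience; a surrogate for a genome-wide promoter set."""
    rng = np.random.default_rng(seed)
    freqs = np.asarray(base_freqs, dtype=float)
    records = []
    i = 0
    remaining = length_total
    while remaining > 0:
        n = min(chunk, remaining)
        i += 1
        records.append((f"cal{i}", _random_seq(n, freqs, rng)))
        remaining -= n
    return PeakSet(records=records, source_path=f"<calibration:seed={seed}>")


@dataclass
class PlantSpec:
    """Recipe for planting Anchor/Partner site pairs into peaks.

    ``geometry`` is the spacer length for Spacer plants, the overlap
    length for Partial plants, and the offset of the shorter motif inside
    the longer one for Full plants.  ``anchor_strength`` /
    ``partner_strength`` set, per column, the probability of emitting the
    consensus letter instead of a background letter, so they control the
    conservation level of the planted sites monotonically.
    """

    anchor_matrix: FrequencyMatrix
    partner_matrix: FrequencyMatrix
    orientation: str = "DirectAP"
    location: str = "Spacer"
    geometry: int = 5
    fraction_of_peaks: float = 0.5
    anchor_strength: float = 1.0
    partner_strength: float = 1.0
    base_freqs: tuple = UNIFORM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        la, lp = len(self.anchor_matrix), len(self.partner_matrix)
        if self.location == "Partial" and not (1 <= self.geometry < min(la, lp)):
            raise ValueError("partial overlap must be in [1, min motif length)")
        if self.location == "Full" and not (
            0 <= self.geometry <= abs(la - lp)
        ):
            raise ValueError("full-overlap offset must be in [0, |La - Lp|]")
        if self.location == "Spacer" and self.geometry < 0:
            raise ValueError("spacer length must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth coordinates of one planted CE (0-based half-open)."""

    peak_id: str
    anchor_start: int
    anchor_end: int
    anchor_strand: str
    partner_start: int
    partner_end: int
    partner_strand: str
    orientation: str
    location: str
    geometry: int


def _emit_site(
    fm: FrequencyMatrix, strength: float, freqs: np.ndarray,
    rng: np.random.Generator,
) -> str:
    """Sample a site: consensus letter with probability ``strength`` per
    column, otherwise a background letter."""
    consensus = fm.consensus()
    out = []
    for c in consensus:
        if rng.random() < strength:
            out.append(c)
        else:
            out.append(ALPHABET[rng.choice(4, p=freqs)])
    return "".join(out)


def _layout(spec: PlantSpec) -> tuple[int, int, int, str, str]:
    """Relative coordinates and strands realising the spec.

    Returns (anchor_offset, partner_offset, span, anchor_strand,
    partner_strand) with offsets from the left edge of the construct.
    The anchor is the left motif except for DirectPA plants and Full
    overlaps with a longer partner (containment forces the longer motif
    left).  Combinations the left/right classification convention cannot
    realise (e.g. a DirectAP Full overlap with a longer partner) are
    rejected.
    """
    la, lp = len(spec.anchor_matrix), len(spec.partner_matrix)
    if spec.location == "Full":
        if la == lp:
            raise ValueError("Full overlap requires motifs of different length")
        anchor_left = la > lp
    else:
        anchor_left = spec.orientation != "DirectPA"

    if spec.location == "Spacer":
        left_len = la if anchor_left else lp
        off_left, off_right = 0, left_len + spec.geometry
        span = la + lp + spec.geometry
    elif spec.location == "Partial":
        left_len = la if anchor_left else lp
        off_left, off_right = 0, left_len - spec.geometry
        span = la + lp - spec.geometry
    else:  # Full: shorter motif inside the longer, geometry = start offset
        off_left, off_right = 0, spec.geometry
        span = max(la, lp)
    a_off, p_off = (off_left, off_right) if anchor_left else (off_right, off_left)

    if spec.orientation in ("DirectAP", "DirectPA"):
        sa = sp = "+"
    elif spec.orientation == "Inverted":  # heads facing: left '+', right '-'
        sa, sp = ("+", "-") if anchor_left else ("-", "+")
    else:  # Everted: heads apart: left '-', right '+'
        sa, sp = ("-", "+") if anchor_left else ("+", "-")

    # confirm the layout classifies back to the requested labels
    from .ce_core import classify_location, classify_orientation
    from .pwm_scan import MotifHit

    a = MotifHit("_", a_off, a_off + la, sa, 0.0, 0.0)
    p = MotifHit("_", p_off, p_off + lp, sp, 0.0, 0.0)
    got = classify_orientation(a, p)
    call = classify_location(a, p, 0, max(spec.geometry, 0))
    if got != spec.orientation or call is None or call.location != spec.location:
        raise ValueError(
            f"orientation {spec.orientation} with location {spec.location} and "
            f"motif lengths ({la}, {lp}) is not realisable under the "
            "left/right classification convention"
        )
    return a_off, p_off, span, sa, sp


def plant(peaks: PeakSet, spec: PlantSpec) -> tuple[PeakSet, list[TruthRecord]]:
    """Write sampled Anchor+Partner sites realising ``spec`` into a seeded
    random subset of ceil(fraction * n) peaks, at a uniform random
    admissible position; returns the modified peaks and the truth table."""
    rng = np.random.default_rng(spec.seed)
    freqs = np.asarray(spec.base_freqs, dtype=float)
    a_off, p_off, span, sa, sp = _layout(spec)
    n = len(peaks)
    n_plant = int(np.ceil(spec.fraction_of_peaks * n))
    chosen = set(rng.choice(n, size=n_plant, replace=False)) if n_plant else set()

    records: list[tuple[str, str]] = []
    truth: list[TruthRecord] = []
    for i, (pid, seq) in enumerate(peaks):
        if i not in chosen:
            records.append((pid, seq))
            continue
        if span > len(seq):
            raise ValueError(
                f"planted construct ({span} bp) longer than peak {pid!r}"
            )
        pos = int(rng.integers(0, len(seq) - span + 1))
        anchor_site = _emit_site(spec.anchor_matrix, spec.anchor_strength, freqs, rng)
        partner_site = _emit_site(
            spec.partner_matrix, spec.partner_strength, freqs, rng
        )
        if sa == "-":
            anchor_site = reverse_complement(anchor_site)
        if sp == "-":
            partner_site = reverse_complement(partner_site)
        s = list(seq)
        # partner written first so an overlapping anchor wins shared columns;
        # for Full overlaps the inner motif is written last to stay intact
        la, lp = len(spec.anchor_matrix), len(spec.partner_matrix)
        writes = [(p_off, partner_site), (a_off, anchor_site)]
        if spec.location == "Full" and lp < la:
            writes = [(a_off, anchor_site), (p_off, partner_site)]
        for off, site in writes:
            s[pos + off : pos + off + len(site)] = site
        records.append((pid, "".join(s)))
        truth.append(
            TruthRecord(
                peak_id=pid,
                anchor_start=pos + a_off,
                anchor_end=pos + a_off + la,
                anchor_strand=sa,
                partner_start=pos + p_off,
                partner_end=pos + p_off + lp,
                partner_strand=sp,
                orientation=spec.orientation,
                location=spec.location,
                geometry=spec.geometry,
            )
        )
    return PeakSet(records=records, source_path=peaks.source_path), truth


def write_truth_table(truth: list[TruthRecord], path) -> None:
    """BED-like TSV of planted CE coordinates (0-based half-open)."""
    cols = [
        "peak_id", "anchor_start", "anchor_end", "anchor_strand",
        "partner_start", "partner_end", "partner_strand",
        "orientation", "location", "geometry",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truth:
            fh.write("\t".join(str(getattr(t, c)) for c in cols) + "\n")


def demo_motif(motif_id: str, consensus: str, depth: int = 100) -> FrequencyMatrix:
    """A strong count matrix with the given consensus (depth-1 consensus
    counts, 1/3 elsewhere is rounded to integers: depth-3 vs 1)."""
    cols = []
    for c in consensus.upper():
        col = [1.0] * 4
        col[ALPHABET.index(c)] = float(depth - 3)
        cols.append(col)
    return FrequencyMatrix(motif_id=motif_id, columns=np.array(cols), is_counts=True)
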