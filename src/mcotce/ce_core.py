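"""Composite-element core: permuted background datasets, Anchor/Partner
pair enumeration, and classification by orientation, location, geometry
and conservation relation.

Orientation follows the usual repeat taxonomy: Direct (both motifs on the
same strand, in AP or PA order), Inverted (heads facing each other) and
Everted (heads pointing apart).  Location distinguishes Full overlap (one
motif entirely inside the other), Partial overlap, and Spacer (disjoint
motifs separated by a gap within configured limits).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .motif_io import PeakSet
from .pwm_scan import MotifHit

ORIENTATIONS = ("DirectAP", "DirectPA", "Inverted", "Everted")
LOCATIONS = ("Full", "Partial", "Spacer")

DEFAULT_SPACER_MIN = 0
DEFAULT_SPACER_MAX = 29


# ---------------------------------------------------------------------------
# Sequence shuffles

def _mono_shuffle(seq: str, rng: np.random.Generator) -> str:
    letters = np.array(list(seq))
    return "".join(rng.permutation(letters))


def _di_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (random Eulerian walk).

    Builds the multigraph whose edges are the adjacent-letter pairs of
    ``seq`` and samples a uniform random Eulerian path from the first to
    the last letter: for every vertex except the final one a random "last
    exit" edge is chosen so that last-exit edges form a tree rooted at the
    final vertex (Altschul–Erickson construction); the remaining out-edges
    are permuted freely.
    """
    if len(set(seq)) == 1:
        return seq
    vertices = sorted(set(seq))
    vidx = {v: i for i, v in enumerate(vertices)}
    nv = len(vertices)
    out_edges: list[list[int]] = [[] for _ in range(nv)]
    for a, b in zip(seq, seq[1:]):
        out_edges[vidx[a]].append(vidx[b])
    start, end = vidx[seq[0]], vidx[seq[-1]]

    while True:
        # propose a random last-exit edge per vertex (except `end`)
        last_exit = [-1] * nv
        for v in range(nv):
            if v != end and out_edges[v]:
                last_exit[v] = out_edges[v][rng.integers(len(out_edges[v]))]
        # accept iff every vertex with out-edges reaches `end` via last exits
        ok = True
        for v in range(nv):
            if v == end or not out_edges[v]:
                continue
            seen = {v}
            u = v
            while u != end:
                u = last_exit[u]
                if u == -1 or u in seen:
                    ok = False
                    break
                seen.add(u)
            if not ok:
                break
        if ok:
            break

    walk_lists: list[list[int]] = []
    for v in range(nv):
        rest = list(out_edges[v])
        if last_exit[v] != -1:
            rest.remove(last_exit[v])
        perm = [rest[i] for i in rng.permutation(len(rest))] if rest else []
        if last_exit[v] != -1:
            perm.append(last_exit[v])
        walk_lists.append(perm)

    pos = [0] * nv
    out = [vertices[start]]
    u = start
    for _ in range(len(seq) - 1):
        nxt = walk_lists[u][pos[u]]
        pos[u] += 1
        out.append(vertices[nxt])
        u = nxt
    return "".join(out)


def shuffle_sequence(seq: str, mode: str = "di", seed: int = 0) -> str:
    """Shuffle a DNA sequence preserving its mono- or di-nucleotide counts.

    ``mode='mono'`` returns a uniform random permutation of the letters;
    ``mode='di'`` a random Eulerian-walk shuffle preserving all 16
    dinucleotide counts exactly.  Deterministic per (seq, mode, seed).
    """
    rng = np.random.default_rng(seed)
    if mode == "mono":
        return _mono_shuffle(seq, rng)
    if mode == "di":
        return _di_shuffle(seq, rng)
    raise ValueError(f"unknown shuffle mode {mode!r}")


@dataclass
class BackgroundSet:
    """Permuted copies of a foreground peak set."""

    peaks: PeakSet
    reps: int
    shuffle_mode: str
    seed: int


def generate_background(
    peaks: PeakSet, reps: int = 10, mode: str = "di", seed: int = 0
) -> BackgroundSet:
    """Generate ``reps`` composition-preserving shuffles of every peak.

    Background ids are ``"<peak_id>#k"`` for k = 1..reps; the per-peak
    sub-seed is derived deterministically from (seed, peak index, k).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    records: list[tuple[str, str]] = []
    for i, (pid, seq) in enumerate(peaks):
        for k in range(1, reps + 1):
            sub = np.random.SeedSequence([seed, i, k]).generate_state(1)[0]
            records.append((f"{pid}#{k}", shuffle_sequence(seq, mode, int(sub))))
    return BackgroundSet(
        peaks=PeakSet(records=records, source_path=f"<shuffled:{mode}>"),
        reps=reps,
        shuffle_mode=mode,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Pair classification

def classify_orientation(anchor: MotifHit, partner: MotifHit) -> str:
    """Mutual orientation of an Anchor/Partner hit pair.

    Same strand: DirectAP when the anchor comes first in the reading
    order of that strand (ties break toward the anchor), DirectPA
    otherwise.  Opposite strands: Inverted when the two motifs' heads
    face each other — the '+' hit upstream of the '-' hit — and Everted
    when they point apart.  Positions are compared by interval centre,
    which coincides with left/right order whenever neither motif
    contains the other and stays invariant under reverse complement of
    the peak (a containment pair has no meaningful left/right order).
    """
    if anchor.peak_id != partner.peak_id:
        raise ValueError("hits are on different peaks")
    ca = anchor.start + anchor.end  # 2x centre; exact in int
    cp = partner.start + partner.end
    if anchor.strand == partner.strand:
        anchor_first = ca <= cp if anchor.strand == "+" else ca >= cp
        return "DirectAP" if anchor_first else "DirectPA"
    c_plus, c_minus = (ca, cp) if anchor.strand == "+" else (cp, ca)
    return "Inverted" if c_plus <= c_minus else "Everted"


@dataclass(frozen=True)
class LocationCall:
    location: str  # Full | Partial | Spacer
    overlap_len: int = 0
    spacer_len: Optional[int] = None
    border_distance: int = 0


def classify_location(
    anchor: MotifHit,
    partner: MotifHit,
    spacer_min: int = DEFAULT_SPACER_MIN,
    spacer_max: int = DEFAULT_SPACER_MAX,
) -> Optional[LocationCall]:
    """Mutual location of two hits, or ``None`` for out-of-limits spacing.

    Full: one interval contains the other (overlap = shorter length,
    border distance = the smaller of the two start/end offsets).
    Partial: the intervals intersect but neither contains the other.
    Spacer: disjoint with a gap g, spacer_min <= g <= spacer_max.
    """
    a0, a1 = anchor.start, anchor.end
    p0, p1 = partner.start, partner.end
    inter = min(a1, p1) - max(a0, p0)
    if inter > 0:
        contains = (a0 <= p0 and p1 <= a1) or (p0 <= a0 and a1 <= p1)
        if contains:
            return LocationCall(
                "Full",
                overlap_len=min(a1 - a0, p1 - p0),
                border_distance=min(abs(a0 - p0), abs(a1 - p1)),
            )
        return LocationCall("Partial", overlap_len=inter)
    gap = max(a0, p0) - min(a1, p1)
    if spacer_min <= gap <= spacer_max:
        return LocationCall("Spacer", spacer_len=gap)
    return None


@dataclass(frozen=True)
class CEInstance:
    """One Anchor/Partner hit pair classified as a candidate CE."""

    peak_id: str
    anchor: MotifHit
    partner: MotifHit
    orientation: str
    location: str
    overlap_len: int
    spacer_len: Optional[int]
    border_distance: int
    conservation_relation: str  # anchor_more | partner_more | tie

    def geometry_label(self) -> str:
        """Histogram label: '<d>F' (border distance), '<v>P' (overlap
        length) or '<g>S' (spacer length)."""
        if self.location == "Full":
            return f"{self.border_distance}F"
        if self.location == "Partial":
            return f"{self.overlap_len}P"
        return f"{self.spacer_len}S"

    def in_flow(self, flow: str) -> bool:
        if flow == "Any":
            return True
        if flow == "Overlap":
            return self.location in ("Full", "Partial")
        return self.location == flow


def _conservation_relation(anchor: MotifHit, partner: MotifHit) -> str:
    if anchor.cl > partner.cl:
        return "anchor_more"
    if anchor.cl < partner.cl:
        return "partner_more"
    return "tie"


def _make_ce(
    anchor: MotifHit, partner: MotifHit, call: LocationCall
) -> CEInstance:
    return CEInstance(
        peak_id=anchor.peak_id,
        anchor=anchor,
        partner=partner,
        orientation=classify_orientation(anchor, partner),
        location=call.location,
        overlap_len=call.overlap_len,
        spacer_len=call.spacer_len,
        border_distance=call.border_distance,
        conservation_relation=_conservation_relation(anchor, partner),
    )


def enumerate_ces(
    anchor_hits: dict[str, list[MotifHit]],
    partner_hits: dict[str, list[MotifHit]] | None,
    spacer_min: int = DEFAULT_SPACER_MIN,
    spacer_max: int = DEFAULT_SPACER_MAX,
) -> list[CEInstance]:
    """Enumerate candidate CEs from per-peak hit lists.

    Heterotypic (``partner_hits`` given): every ordered (anchor, partner)
    pair within a peak whose location classifies.  Homotypic
    (``partner_hits=None``): every unordered pair of distinct anchor hits,
    excluding identical-coordinate pairs, counted once with the
    higher-scoring hit in the anchor role.
    """
    ces: list[CEInstance] = []
    if partner_hits is not None:
        for pid, ahits in anchor_hits.items():
            phits = partner_hits.get(pid, [])
            for a in ahits:
                for p in phits:
                    call = classify_location(a, p, spacer_min, spacer_max)
                    if call is not None:
                        ces.append(_make_ce(a, p, call))
    else:
        for pid, ahits in anchor_hits.items():
            for i in range(len(ahits)):
                for j in range(i + 1, len(ahits)):
                    h1, h2 = ahits[i], ahits[j]
                    if (h1.start, h1.end, h1.strand) == (h2.start, h2.end, h2.strand):
                        continue
                    if h1.score >= h2.score:
                        a, p = h1, h2
                    else:
                        a, p = h2, h1
                    call = classify_location(a, p, spacer_min, spacer_max)
                    if call is not None:
                        ces.append(_make_ce(a, p, call))
    return ces
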