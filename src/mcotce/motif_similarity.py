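"""Anchor/Partner matrix similarity with a column-permutation null.

A composite element between two motifs that essentially recognise the
same sequence is suspect: the co-occurrence may just be one motif found
twice.  This module scores matrix similarity as the maximum Pearson
correlation over all relative offsets (>= 4 overlapping columns) and
both orientations (partner as-is or reverse-complemented), and attaches
a permutation p-value from partner matrices with their column order
shuffled.  Pairs with p < 0.05 are flagged as potentially self-matching;
the flag annotates results but never suppresses them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motif_io import FrequencyMatrix

MIN_OVERLAP = 4
SIMILARITY_ALPHA = 0.05


@dataclass
class SimilarityResult:
    best_correlation: float
    best_offset: int
    best_orientation: str  # same | reverse_complement
    p_value: float
    n_shuffles: int
    seed: int

    @property
    def similar(self) -> bool:
        return self.p_value < SIMILARITY_ALPHA


def _offsets(la: int, lp: int) -> list[int]:
    """Relative partner offsets with >= MIN_OVERLAP overlapping columns."""
    return [
        off
        for off in range(-(lp - MIN_OVERLAP), la - MIN_OVERLAP + 1)
        if min(la, off + lp) - max(0, off) >= MIN_OVERLAP
    ]


def _pearson_batch(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Pearson r of a flat vector x against each row of ys."""
    x = x - x.mean()
    ys = ys - ys.mean(axis=1, keepdims=True)
    num = ys @ x
    den = np.sqrt((x @ x) * (ys * ys).sum(axis=1))
    out = np.zeros(len(ys))
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return np.clip(out, -1.0, 1.0)


def _best_over_alignments(
    anchor_p: np.ndarray, partners: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Max correlation per partner matrix over offsets x orientations.

    ``partners`` is (n, L_p, 4).  Returns (best_r, best_offset,
    best_is_rc) arrays of length n.
    """
    la = anchor_p.shape[0]
    lp = partners.shape[1]
    n = partners.shape[0]
    best = np.full(n, -np.inf)
    best_off = np.zeros(n, dtype=int)
    best_rc = np.zeros(n, dtype=bool)
    variants = (
        (False, partners),
        (True, partners[:, ::-1, ::-1]),
    )
    for is_rc, mats in variants:
        for off in _offsets(la, lp):
            a0, a1 = max(0, off), min(la, off + lp)
            x = anchor_p[a0:a1].ravel()
            seg = mats[:, a0 - off : a1 - off, :].reshape(n, -1)
            r = _pearson_batch(x, seg)
            upd = r > best
            best[upd] = r[upd]
            best_off[upd] = off
            best_rc[upd] = is_rc
    return best, best_off, best_rc


def similarity(
    anchor: FrequencyMatrix,
    partner: FrequencyMatrix,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> SimilarityResult:
    """Similarity statistic and permutation p-value for two matrices.

    The p-value is ``(1 + #{shuffled >= observed}) / (1 + n_shuffles)``
    over partner matrices with independently permuted column order.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    la, lp = len(anchor), len(partner)
    if not _offsets(la, lp):
        raise ValueError(
            f"motifs too short for similarity (no offset with >= "
            f"{MIN_OVERLAP} overlapping columns)"
        )
    ap = anchor.probabilities()
    pp = partner.probabilities()
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(lp) for _ in range(n_shuffles)])
    stack = np.concatenate([pp[None, :, :], pp[perms]], axis=0)
    best, best_off, best_rc = _best_over_alignments(ap, stack)
    observed = best[0]
    null = best[1:]
    p = (1 + int((null >= observed).sum())) / (1 + n_shuffles)
    return SimilarityResult(
        best_correlation=float(observed),
        best_offset=int(best_off[0]),
        best_orientation="reverse_complement" if best_rc[0] else "same",
        p_value=p,
        n_shuffles=n_shuffles,
        seed=seed,
    )
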