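"""Position weight matrices, empirical FPR calibration, and motif scanning.

A motif hit's conservation level (CL) is the -log10 of the empirical
false-positive rate of its score on a calibration sequence set: the
fraction of calibration windows (both strands pooled) scoring at least as
high.  Five score thresholds mark the five conservation-level ranges used
downstream; a configurable ``cl_min`` sets the weakest reportable hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motif_io import ALPHABET, FrequencyMatrix, PeakSet

# effective read depth used to turn probability matrices into pseudo-counts
PROBABILITY_DEPTH = 100.0

DEFAULT_CL_EDGES = (3.5, 4.0, 4.5, 5.0, 5.5)
DEFAULT_CL_MIN = 3.0

_CODE = np.full(256, 4, dtype=np.int8)  # 4 == N / anything else
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes A=0 C=1 G=2 T=3, N (or other)=4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class CalibrationError(ValueError):
    """Raised when the calibration set cannot support the requested CLs."""


@dataclass
class PWM:
    """Log-odds position weight matrix.

    ``weights[i, b] = log2((counts[i, b] + pc * bg[b]) / (depth_i + pc))
    - log2(bg[b])`` where ``depth_i`` is the column count sum and ``pc``
    the pseudocount, distributed over letters by background frequency.
    """

    motif_id: str
    weights: np.ndarray  # (L, 4)
    background: np.ndarray
    pseudocount: float

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())


def build_pwm(
    fm: FrequencyMatrix,
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> PWM:
    """Build a log-odds PWM from a frequency matrix.

    Probability-dialect matrices are first scaled to pseudo-counts at an
    effective depth of 100.  The pseudocount is distributed over the four
    letters proportionally to the background.
    """
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or np.any(background <= 0):
        raise ValueError("background must be 4 strictly positive probabilities")
    if abs(background.sum() - 1.0) > 1e-6:
        raise ValueError("background must sum to 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")

    counts = fm.columns if fm.is_counts else fm.probabilities() * PROBABILITY_DEPTH
    depth = counts.sum(axis=1, keepdims=True)
    if np.any(depth == 0):
        raise ValueError(f"motif {fm.motif_id!r}: zero-depth column")
    probs = (counts + pseudocount * background) / (depth + pseudocount)
    weights = np.log2(probs) - np.log2(background)
    return PWM(
        motif_id=fm.motif_id,
        weights=weights,
        background=background,
        pseudocount=float(pseudocount),
    )


def score_window(pwm: PWM, window: str) -> float:
    """Score a single L-length window on the forward strand.

    Raises ``ValueError`` on a length mismatch or any non-ACGT letter
    (the caller treats the latter as "skip this window").  Reverse-strand
    scoring is ``score_window`` of the reverse complement.
    """
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} != motif length {pwm.length}"
        )
    codes = encode(window)
    if np.any(codes == 4):
        raise ValueError("window contains N")
    return float(pwm.weights[np.arange(pwm.length), codes].sum())


def _batch_scores(weights: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Scores for every window of every row of a padded code matrix.

    ``codes`` is (n_seqs, max_len) int8 with 4 for N/padding.  Returns an
    (n_seqs, max_len - L + 1) float array; windows touching an N or the
    padding score -inf.
    """
    L = weights.shape[0]
    n, m = codes.shape
    nwin = m - L + 1
    if nwin <= 0:
        return np.zeros((n, 0))
    waug = np.concatenate([weights, np.full((L, 1), -np.inf)], axis=1)
    scores = np.zeros((n, nwin))
    for i in range(L):
        scores += waug[i][codes[:, i : i + nwin]]
    return scores


def _pad_encode(seqs: list[str]) -> np.ndarray:
    m = max((len(s) for s in seqs), default=0)
    out = np.full((len(seqs), m), 4, dtype=np.int8)
    for r, s in enumerate(seqs):
        out[r, : len(s)] = encode(s)
    return out


def all_window_scores(pwm: PWM, seqs: list[str]) -> np.ndarray:
    """Pooled scores of every N-free window on both strands of ``seqs``."""
    if not seqs:
        return np.zeros(0)
    codes = _pad_encode(seqs)
    fwd = _batch_scores(pwm.weights, codes)
    rc = _pad_encode([reverse_complement(s) for s in seqs])
    rev = _batch_scores(pwm.weights, rc)
    pooled = np.concatenate([fwd.ravel(), rev.ravel()])
    return pooled[np.isfinite(pooled)]


@dataclass
class CalibratedMotif:
    """A PWM plus its empirical score -> FPR map and the five CL thresholds.

    ``score_grid`` holds the distinct achievable scores observed on the
    calibration set in descending order; ``fpr_grid[k]`` is the fraction of
    calibration windows scoring >= ``score_grid[k]``.  Scores between grid
    points take the FPR of the next grid point below them (the largest FPR
    among tied/bracketing scores, so CL is never overstated).
    """

    pwm: PWM
    score_grid: np.ndarray  # descending distinct scores
    fpr_grid: np.ndarray  # non-decreasing along score_grid
    cl_edges: tuple[float, ...]
    cl_thresholds: np.ndarray  # score threshold per cl_edge (may be +inf)
    cl_min: float
    n_calibration_windows: int

    def fpr(self, scores: np.ndarray | float) -> np.ndarray:
        """Empirical FPR(s) = P(calibration window score >= s).

        A score above every calibration score maps to the smallest
        resolvable rate, 1 / n_calibration_windows.
        """
        scores = np.asarray(scores, dtype=float)
        asc = self.score_grid[::-1]  # ascending
        fpr_asc = self.fpr_grid[::-1]
        idx = np.searchsorted(asc, scores, side="left")
        out = np.where(
            idx >= len(asc),
            1.0 / self.n_calibration_windows,
            fpr_asc[np.minimum(idx, len(asc) - 1)],
        )
        return out

    def cl(self, scores: np.ndarray | float) -> np.ndarray:
        return -np.log10(self.fpr(scores))

    @property
    def threshold_score(self) -> float:
        """Smallest score whose CL reaches ``cl_min``."""
        target = 10.0 ** (-self.cl_min)
        ok = self.fpr_grid <= target
        if not ok.any():
            return np.inf
        return float(self.score_grid[ok][-1])


def calibrate(
    pwm: PWM,
    calibration: PeakSet,
    cl_edges: tuple[float, ...] = DEFAULT_CL_EDGES,
    cl_min: float = DEFAULT_CL_MIN,
) -> CalibratedMotif:
    """Calibrate score thresholds against an empirical background set.

    The calibration set must provide at least ``10**cl_edges[-1]``
    scannable windows (both strands pooled) so the tightest CL range is
    resolvable.  ``t_k`` is the smallest achievable score with
    ``FPR <= 10**(-cl_edges[k])``.
    """
    if list(cl_edges) != sorted(cl_edges):
        raise ValueError("cl_edges must be ascending")
    scores = all_window_scores(pwm, calibration.sequences())
    n = scores.size
    if n == 0:
        raise CalibrationError(
            "motif is longer than every calibration sequence"
        )
    required = 10.0 ** cl_edges[-1]
    if n < required:
        raise CalibrationError(
            f"calibration set provides {n} windows but {required:.0f} are "
            f"needed to resolve CL {cl_edges[-1]}; supply a larger set"
        )
    desc = np.sort(scores)[::-1]
    grid, first_idx = np.unique(-desc, return_index=True)
    grid = -grid  # descending distinct scores
    # windows with score >= grid[k]: ranks of the last occurrence
    counts = np.searchsorted(-desc, -grid, side="right")
    fpr_grid = counts / n

    thresholds = np.full(len(cl_edges), np.inf)
    for k, edge in enumerate(cl_edges):
        ok = fpr_grid <= 10.0 ** (-edge)
        if ok.any():
            thresholds[k] = grid[ok][-1]  # smallest achievable passing score
    return CalibratedMotif(
        pwm=pwm,
        score_grid=grid,
        fpr_grid=fpr_grid,
        cl_edges=tuple(cl_edges),
        cl_thresholds=thresholds,
        cl_min=float(cl_min),
        n_calibration_windows=n,
    )


@dataclass(frozen=True)
class MotifHit:
    """A scored, stranded motif occurrence in a peak.

    Coordinates are 0-based half-open on the forward strand of the peak;
    ``strand`` '-' means the reverse complement of the window matched.
    """

    peak_id: str
    start: int
    end: int
    strand: str
    score: float
    cl: float


def scan_peaks(cm: CalibratedMotif, peaks: PeakSet) -> dict[str, list[MotifHit]]:
    """Map all motif occurrences with CL >= cl_min in every peak.

    Both strands are scanned; windows containing N are skipped.  Returns
    hits grouped by peak id (peaks without hits map to empty lists),
    ordered by (start, strand) within each peak.
    """
    out: dict[str, list[MotifHit]] = {pid: [] for pid in peaks.ids}
    if len(peaks) == 0:
        return out
    L = cm.pwm.length
    t = cm.threshold_score
    seqs = peaks.sequences()
    codes = _pad_encode(seqs)
    fwd = _batch_scores(cm.pwm.weights, codes)
    rc = _pad_encode([reverse_complement(s) for s in seqs])
    rev = _batch_scores(cm.pwm.weights, rc)
    ids = peaks.ids
    for r, (pid, seq) in enumerate(zip(ids, seqs)):
        n = len(seq)
        nwin = n - L + 1
        if nwin <= 0:
            continue
        hits = []
        frow = fwd[r, :nwin]
        for j in np.nonzero(frow >= t)[0]:
            hits.append((int(j), "+", float(frow[j])))
        rrow = rev[r, :nwin]
        for j in np.nonzero(rrow >= t)[0]:
            # reverse-strand window j corresponds to forward start n - L - j
            hits.append((n - L - int(j), "-", float(rrow[j])))
        hits.sort(key=lambda h: (h[0], h[1]))
        cls = cm.cl(np.array([h[2] for h in hits])) if hits else []
        out[pid] = [
            MotifHit(pid, s, s + L, st, sc, float(c))
            for (s, st, sc), c in zip(hits, cls)
        ]
    return out
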