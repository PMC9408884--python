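"""Significance machinery for composite elements.

Enrichment is tested per computation flow (Full, Partial, Overlap,
Spacer, Any) at the sequence level — peaks with vs without a CE,
foreground vs permuted background — with a one-sided Fisher's exact
test.  Conservation asymmetry within CEs is tested at the CE level with
a two-sided Fisher's exact test whose -log10 p carries a sign: '+'
toward the Anchor motif, '-' toward the Partner.  A 12x12 per-mille
heatmap over conservation-level bins contrasts observed (foreground)
and expected (background) CE abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .ce_core import CEInstance

FLOWS = ("Full", "Partial", "Overlap", "Spacer", "Any")
CONSERVATION_CLASSES = ("any", "anchor_more", "partner_more")

HEATMAP_EDGES = (3.5, 3.7, 3.9, 4.1, 4.3, 4.5, 4.7, 4.9, 5.1, 5.3, 5.5)

P_FLOOR = 1e-320
MIN_CES_FOR_ASYMMETRY = 5


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table; row 1 = foreground, row 2 = background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative contingency counts")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")


def fisher_exact(table: ContingencyTable, alternative: str = "greater") -> float:
    """Fisher's exact test on a 2x2 table, via the hypergeometric law.

    ``greater`` returns P[X >= a] conditioning on the margins; ``two_sided``
    sums the probabilities of all outcomes no more likely than the observed
    one.  Degenerate tables (a zero margin) return 1 by convention.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1 = a + b
    k = a + c
    if r1 == 0 or k == 0 or r1 == n or k == n:
        return 1.0
    dist = hypergeom(n, r1, k)
    if alternative == "greater":
        return float(min(1.0, dist.sf(a - 1)))
    if alternative == "two_sided":
        support = np.arange(max(0, r1 + k - n), min(r1, k) + 1)
        pmf = dist.pmf(support)
        p_obs = dist.pmf(a)
        # relative tolerance guards against float noise on equal masses
        mask = pmf <= p_obs * (1 + 1e-12)
        if mask.all():
            return 1.0
        return float(min(1.0, pmf[mask].sum()))
    raise ValueError(f"unknown alternative {alternative!r}")


def neg_log10(p: float) -> float:
    return -math.log10(max(p, P_FLOOR)) + 0.0  # avoid -0.0 at p = 1


@dataclass
class FlowResult:
    """Enrichment of one flow x conservation class."""

    flow: str
    conservation_class: str
    table: ContingencyTable
    p_value: float

    @property
    def neg_log10_p(self) -> float:
        return neg_log10(self.p_value)


def flow_significance(
    fg_peaks_with_ce: int,
    n_fg: int,
    bg_peaks_with_ce: int,
    n_bg: int,
    flow: str = "Any",
    conservation_class: str = "any",
) -> FlowResult:
    """One-sided (greater) Fisher test of CE overrepresentation in the
    foreground, counting sequences with/without a CE."""
    if n_fg == 0:
        raise ValueError("empty foreground dataset")
    if fg_peaks_with_ce > n_fg or bg_peaks_with_ce > n_bg:
        raise ValueError("counts exceed dataset sizes")
    table = ContingencyTable(
        fg_peaks_with_ce,
        n_fg - fg_peaks_with_ce,
        bg_peaks_with_ce,
        n_bg - bg_peaks_with_ce,
    )
    return FlowResult(flow, conservation_class, table, fisher_exact(table, "greater"))


def _peaks_with(ces: Sequence[CEInstance], flow: str, cls: str) -> set[str]:
    out = set()
    for ce in ces:
        if not ce.in_flow(flow):
            continue
        if cls != "any" and ce.conservation_relation != cls:
            continue
        out.add(ce.peak_id)
    return out


def all_flow_significances(
    fg_ces: Sequence[CEInstance],
    bg_ces: Sequence[CEInstance],
    n_fg: int,
    n_bg: int,
) -> list[FlowResult]:
    """Enrichment for the 5 flows x 3 conservation classes (15 tests)."""
    results = []
    for flow in FLOWS:
        for cls in CONSERVATION_CLASSES:
            results.append(
                flow_significance(
                    len(_peaks_with(fg_ces, flow, cls)),
                    n_fg,
                    len(_peaks_with(bg_ces, flow, cls)),
                    n_bg,
                    flow=flow,
                    conservation_class=cls,
                )
            )
    return results


@dataclass
class AsymmetryResult:
    """Signed conservation-asymmetry test for one flow.

    ``signed_neg_log10_p`` is positive when the foreground is enriched in
    anchor-more-conserved CEs relative to the background, negative toward
    the partner.  Flows with fewer than 5 conservation-informative CEs in
    either dataset are reported as not assessed.
    """

    flow: str
    table: ContingencyTable
    p_value: float
    signed_neg_log10_p: Optional[float]
    assessed: bool


def asymmetry_significance(
    fg_ces: Sequence[CEInstance], bg_ces: Sequence[CEInstance]
) -> list[AsymmetryResult]:
    """Two-sided Fisher asymmetry test per flow, at the CE level.

    Ties in conservation are excluded; the sign compares anchor-more
    proportions between foreground and background.
    """
    out = []
    for flow in FLOWS:
        fa = sum(
            1 for ce in fg_ces
            if ce.in_flow(flow) and ce.conservation_relation == "anchor_more"
        )
        fp = sum(
            1 for ce in fg_ces
            if ce.in_flow(flow) and ce.conservation_relation == "partner_more"
        )
        ba = sum(
            1 for ce in bg_ces
            if ce.in_flow(flow) and ce.conservation_relation == "anchor_more"
        )
        bp = sum(
            1 for ce in bg_ces
            if ce.in_flow(flow) and ce.conservation_relation == "partner_more"
        )
        if fa + fp < MIN_CES_FOR_ASYMMETRY or ba + bp < MIN_CES_FOR_ASYMMETRY:
            table = ContingencyTable(fa, fp, ba, bp) if fa + fp + ba + bp else None
            out.append(
                AsymmetryResult(
                    flow=flow,
                    table=table if table is not None else ContingencyTable(0, 0, 0, 1),
                    p_value=1.0,
                    signed_neg_log10_p=None,
                    assessed=False,
                )
            )
            continue
        table = ContingencyTable(fa, fp, ba, bp)
        p = fisher_exact(table, "two_sided")
        fg_prop = fa / (fa + fp)
        bg_prop = ba / (ba + bp)
        sign = 1.0 if fg_prop > bg_prop else (-1.0 if fg_prop < bg_prop else 0.0)
        out.append(
            AsymmetryResult(
                flow=flow,
                table=table,
                p_value=p,
                signed_neg_log10_p=sign * neg_log10(p),
                assessed=True,
            )
        )
    return out


@dataclass
class HeatmapMatrix:
    """12x12 per-mille contrast of CE abundance over CL bins.

    ``values[i, j] = 1000*obs[i, j]/Obs - 1000*exp[i, j]/Exp`` with rows
    indexing the Anchor CL bin (i) and columns the Partner CL bin (j);
    bins are (-inf, 3.5), [3.5, 3.7), ..., [5.3, 5.5), [5.5, inf).
    """

    flow: str
    obs_counts: np.ndarray
    exp_counts: np.ndarray
    values: np.ndarray
    obs_total: int
    exp_total: int
    empty: bool = False

    @staticmethod
    def n_bins() -> int:
        return len(HEATMAP_EDGES) + 1

    @staticmethod
    def bin_labels() -> list[str]:
        e = HEATMAP_EDGES
        labels = [f"<{e[0]}"]
        labels += [f"[{lo},{hi})" for lo, hi in zip(e[:-1], e[1:])]
        labels.append(f">={e[-1]}")
        return labels


def _bin_cl(cl: float) -> int:
    return int(np.searchsorted(HEATMAP_EDGES, cl, side="right"))


def _count_grid(ces: Sequence[CEInstance], flow: str) -> np.ndarray:
    n = HeatmapMatrix.n_bins()
    grid = np.zeros((n, n), dtype=int)
    for ce in ces:
        if ce.in_flow(flow):
            grid[_bin_cl(ce.anchor.cl), _bin_cl(ce.partner.cl)] += 1
    return grid


def permille_matrix(obs_counts: np.ndarray, exp_counts: np.ndarray) -> np.ndarray:
    """Per-mille contrast 1000*obs/Obs - 1000*exp/Exp (zero if a side is
    empty)."""
    obs_counts = np.asarray(obs_counts, dtype=float)
    exp_counts = np.asarray(exp_counts, dtype=float)
    obs_t, exp_t = obs_counts.sum(), exp_counts.sum()
    if obs_t == 0 or exp_t == 0:
        return np.zeros_like(obs_counts)
    return 1000.0 * obs_counts / obs_t - 1000.0 * exp_counts / exp_t


def heatmap(
    fg_ces: Sequence[CEInstance], bg_ces: Sequence[CEInstance], flow: str
) -> HeatmapMatrix:
    """Bin CEs of one flow by (anchor CL, partner CL) and contrast
    foreground vs background abundance in per mille."""
    obs = _count_grid(fg_ces, flow)
    exp = _count_grid(bg_ces, flow)
    empty = obs.sum() == 0 or exp.sum() == 0
    return HeatmapMatrix(
        flow=flow,
        obs_counts=obs,
        exp_counts=exp,
        values=permille_matrix(obs, exp),
        obs_total=int(obs.sum()),
        exp_total=int(exp.sum()),
        empty=empty,
    )


@dataclass(frozen=True)
class HistogramRow:
    orientation: str
    geometry_label: str
    foreground_percent: float


@dataclass
class HistogramTable:
    rows: list[HistogramRow]

    def top_variant(self) -> Optional[tuple[str, str]]:
        if not self.rows:
            return None
        best = max(
            self.rows,
            key=lambda r: (r.foreground_percent, r.orientation, r.geometry_label),
        )
        return (best.orientation, best.geometry_label)


def histogram(fg_ces: Sequence[CEInstance], n_fg_peaks: int) -> HistogramTable:
    """Percentage of foreground peaks containing each (orientation,
    geometry) CE variant; a peak counts once per variant."""
    peaks_by_variant: dict[tuple[str, str], set[str]] = {}
    for ce in fg_ces:
        key = (ce.orientation, ce.geometry_label())
        peaks_by_variant.setdefault(key, set()).add(ce.peak_id)
    rows = [
        HistogramRow(o, g, 100.0 * len(pids) / n_fg_peaks)
        for (o, g), pids in sorted(peaks_by_variant.items())
    ]
    return HistogramTable(rows=rows)


def adjust_for_library(
    raw_p_by_motif: dict[str, dict[str, float]], method: str = "bonferroni"
) -> dict[str, dict[str, float]]:
    """Bonferroni adjustment of per-flow enrichment p-values across a
    partner library; returns adjusted -log10 p per motif and flow."""
    if method not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment method {method!r}")
    m = len(raw_p_by_motif)
    out: dict[str, dict[str, float]] = {}
    for motif, by_flow in raw_p_by_motif.items():
        out[motif] = {}
        for flow, p in by_flow.items():
            adj = p if method == "none" else min(1.0, p * m)
            out[motif][flow] = neg_log10(adj)
    return out
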