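"""End-to-end orchestration: calibrate, scan, enumerate, test, report.

``run_pair`` analyses one Anchor/Partner motif pair over a peak set;
``run_library`` repeats the partner-specific part for every motif of a
library, sharing the anchor calibration and the permuted background.
The homotypic Anchor/Anchor pair is always analysed alongside (reported
under the motif name "Anchor") unless disabled.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import ce_core, ce_stats, motif_io, motif_similarity, pwm_scan
from .ce_core import CEInstance
from .ce_stats import (
    FLOWS,
    AsymmetryResult,
    FlowResult,
    HeatmapMatrix,
    HistogramTable,
)
from .motif_io import FrequencyMatrix, PeakSet
from .motif_similarity import SimilarityResult
from .pwm_scan import CalibratedMotif, MotifHit
from .synth_fixtures import make_calibration

logger = logging.getLogger(__name__)

ProgressCallback = Callable[[float, str], None]


@dataclass
class RunConfig:
    """All knobs of a composite-element run.

    ``cl_edges`` are the five conservation-level range boundaries
    (-log10 FPR); ``cl_min`` the weakest reportable hit.  ``spacer_min``
    / ``spacer_max`` bound the admissible gap between spaced motifs.
    ``bg_reps`` permuted copies of every peak form the background.
    """

    spacer_min: int = ce_core.DEFAULT_SPACER_MIN
    spacer_max: int = ce_core.DEFAULT_SPACER_MAX
    cl_edges: tuple[float, ...] = pwm_scan.DEFAULT_CL_EDGES
    cl_min: float = pwm_scan.DEFAULT_CL_MIN
    bg_reps: int = 10
    shuffle_mode: str = "di"
    n_shuffles_similarity: int = 1000
    pseudocount: float = 1.0
    seed: int = 1
    anchor_best_only: bool = False
    include_homotypic: bool = True
    synth_calibration_length: int = 1_000_000
    sort_by: Optional[str] = None
    sort_ascending: bool = False

    def __post_init__(self) -> None:
        if self.spacer_min > self.spacer_max:
            raise ValueError("spacer_min must be <= spacer_max")
        if list(self.cl_edges) != sorted(set(self.cl_edges)):
            raise ValueError("cl_edges must be strictly ascending")


@dataclass
class CELogo:
    """Positional counts of the most common overlap CE variant, with the
    anchor normalised to the '+' strand of the frame."""

    counts: np.ndarray  # (width, 4)
    anchor_interval: tuple[int, int]
    anchor_strand: str  # always '+' in the normalised frame
    partner_interval: tuple[int, int]
    partner_strand: str
    variant_label: str
    n_instances: int


@dataclass
class MotifResult:
    """All statistics for one second motif (a partner, or 'Anchor')."""

    motif_id: str
    flow_results: list[FlowResult]
    asymmetry_results: list[AsymmetryResult]
    heatmaps: list[HeatmapMatrix]
    histogram: HistogramTable
    similarity: Optional[SimilarityResult]
    fg_ces: list[CEInstance]
    n_fg_ces: int = 0
    n_bg_ces: int = 0
    logo: Optional[CELogo] = None

    def flow_neg_log10_p(self, flow: str, conservation_class: str = "any") -> float:
        for fr in self.flow_results:
            if fr.flow == flow and fr.conservation_class == conservation_class:
                return fr.neg_log10_p
        raise KeyError(flow)

    def flow_p(self, flow: str, conservation_class: str = "any") -> float:
        for fr in self.flow_results:
            if fr.flow == flow and fr.conservation_class == conservation_class:
                return fr.p_value
        raise KeyError(flow)

    def asymmetry_signed(self, flow: str) -> Optional[float]:
        for ar in self.asymmetry_results:
            if ar.flow == flow:
                return ar.signed_neg_log10_p
        raise KeyError(flow)


@dataclass
class RunResult:
    config: RunConfig
    anchor_id: str
    n_fg_peaks: int
    n_bg_peaks: int
    motif_results: list[MotifResult]
    adjusted: Optional[dict[str, dict[str, float]]] = None
    sort_by: Optional[str] = None
    sort_ascending: bool = False

    def motif(self, motif_id: str) -> MotifResult:
        for mr in self.motif_results:
            if mr.motif_id == motif_id:
                return mr
        raise KeyError(motif_id)


def _variant_key(ce: CEInstance) -> tuple:
    """Structural identity of an overlap CE in the anchor-normalised frame:
    orientation, location, overlap length, signed partner offset."""
    if ce.anchor.strand == "+":
        off = ce.partner.start - ce.anchor.start
    else:
        off = ce.anchor.end - ce.partner.end
    return (ce.orientation, ce.location, ce.overlap_len, off)


def _variant_label(key: tuple) -> str:
    o, loc, ov, off = key
    return f"{o}|{loc}|ov{ov}|off{off:+d}"


def ce_logo(peaks: PeakSet, ces: Sequence[CEInstance]) -> Optional[CELogo]:
    """Build the CE logo for the most common overlap-class variant.

    Groups overlap CEs by (orientation, location, overlap length, signed
    offset), picks the modal variant (ties: more distinct peaks, then
    lexicographically smaller label), stacks the union-interval
    subsequences of its foreground instances — reverse-complemented when
    the anchor is on '-' so all anchors share one frame — into positional
    nucleotide counts.  Returns ``None`` when there is no overlap CE.
    """
    overlap = [ce for ce in ces if ce.location in ("Full", "Partial")]
    if not overlap:
        return None
    groups: dict[tuple, list[CEInstance]] = {}
    for ce in overlap:
        groups.setdefault(_variant_key(ce), []).append(ce)
    modal_key = min(
        groups,
        key=lambda k: (
            -len(groups[k]),
            -len({ce.peak_id for ce in groups[k]}),
            _variant_label(k),
        ),
    )
    instances = groups[modal_key]
    seq_by_id = dict(peaks.records)
    width = None
    counts = None
    a_iv = p_iv = None
    p_strand = None
    for ce in instances:
        u0 = min(ce.anchor.start, ce.partner.start)
        u1 = max(ce.anchor.end, ce.partner.end)
        sub = seq_by_id[ce.peak_id][u0:u1]
        if ce.anchor.strand == "-":
            sub = pwm_scan.reverse_complement(sub)
            a0, a1 = u1 - ce.anchor.end, u1 - ce.anchor.start
            p0, p1 = u1 - ce.partner.end, u1 - ce.partner.start
            ps = "+" if ce.partner.strand == "-" else "-"
        else:
            a0, a1 = ce.anchor.start - u0, ce.anchor.end - u0
            p0, p1 = ce.partner.start - u0, ce.partner.end - u0
            ps = ce.partner.strand
        if counts is None:
            width = u1 - u0
            counts = np.zeros((width, 4), dtype=int)
            a_iv, p_iv, p_strand = (a0, a1), (p0, p1), ps
        codes = pwm_scan.encode(sub)
        for i, c in enumerate(codes):
            if c < 4:
                counts[i, c] += 1
    return CELogo(
        counts=counts,
        anchor_interval=a_iv,
        anchor_strand="+",
        partner_interval=p_iv,
        partner_strand=p_strand,
        variant_label=_variant_label(modal_key),
        n_instances=len(instances),
    )


def _filter_best_anchor(hits: dict[str, list[MotifHit]]) -> dict[str, list[MotifHit]]:
    out = {}
    for pid, hs in hits.items():
        if hs:
            best = max(hs, key=lambda h: (h.score, -h.start, h.strand))
            out[pid] = [best]
        else:
            out[pid] = []
    return out


def _null_progress(fraction: float, stage: str) -> None:
    pass


def _analyse_motif(
    motif_id: str,
    fg_ces: list[CEInstance],
    bg_ces: list[CEInstance],
    n_fg: int,
    n_bg: int,
    fg_peaks: PeakSet,
    sim: Optional[SimilarityResult],
) -> MotifResult:
    mr = MotifResult(
        motif_id=motif_id,
        flow_results=ce_stats.all_flow_significances(fg_ces, bg_ces, n_fg, n_bg),
        asymmetry_results=ce_stats.asymmetry_significance(fg_ces, bg_ces),
        heatmaps=[ce_stats.heatmap(fg_ces, bg_ces, f) for f in FLOWS],
        histogram=ce_stats.histogram(fg_ces, n_fg),
        similarity=sim,
        fg_ces=fg_ces,
        n_fg_ces=len(fg_ces),
        n_bg_ces=len(bg_ces),
    )
    mr.logo = ce_logo(fg_peaks, fg_ces)
    return mr


def run_library(
    peaks: PeakSet,
    anchor: FrequencyMatrix,
    partners: Sequence[FrequencyMatrix],
    config: RunConfig = RunConfig(),
    calibration: Optional[PeakSet] = None,
    progress: ProgressCallback = _null_progress,
) -> RunResult:
    """Analyse the anchor against every partner of a library.

    The anchor calibration, its foreground/background hit maps and the
    permuted background set are computed once and shared across partners.
    With no partners and ``include_homotypic`` enabled, only the
    homotypic Anchor/Anchor analysis is run.
    """
    progress(0.0, "start")
    if calibration is None:
        calibration = make_calibration(
            config.synth_calibration_length,
            seed=int(np.random.SeedSequence([config.seed, 101]).generate_state(1)[0]),
        )
    background_freqs = calibration.base_frequencies()
    anchor_pwm = pwm_scan.build_pwm(anchor, background_freqs, config.pseudocount)
    anchor_cm = pwm_scan.calibrate(
        anchor_pwm, calibration, config.cl_edges, config.cl_min
    )
    progress(0.05, "anchor calibrated")

    bg = ce_core.generate_background(
        peaks, config.bg_reps, config.shuffle_mode,
        int(np.random.SeedSequence([config.seed, 11]).generate_state(1)[0]),
    )
    n_fg, n_bg = len(peaks), len(bg.peaks)
    progress(0.15, "background generated")

    fg_anchor_hits = pwm_scan.scan_peaks(anchor_cm, peaks)
    bg_anchor_hits = pwm_scan.scan_peaks(anchor_cm, bg.peaks)
    if config.anchor_best_only:
        fg_anchor_hits = _filter_best_anchor(fg_anchor_hits)
        bg_anchor_hits = _filter_best_anchor(bg_anchor_hits)
    progress(0.25, "anchor scanned")

    motif_results: list[MotifResult] = []
    if config.include_homotypic:
        fg_ces = ce_core.enumerate_ces(
            fg_anchor_hits, None, config.spacer_min, config.spacer_max
        )
        bg_ces = ce_core.enumerate_ces(
            bg_anchor_hits, None, config.spacer_min, config.spacer_max
        )
        motif_results.append(
            _analyse_motif("Anchor", fg_ces, bg_ces, n_fg, n_bg, peaks, None)
        )
    progress(0.3, "homotypic done")

    n_partners = len(partners)
    for i, partner in enumerate(partners):
        try:
            sim = motif_similarity.similarity(
                anchor, partner, config.n_shuffles_similarity,
                seed=int(
                    np.random.SeedSequence([config.seed, 7, i]).generate_state(1)[0]
                ),
            )
            partner_pwm = pwm_scan.build_pwm(
                partner, background_freqs, config.pseudocount
            )
            partner_cm = pwm_scan.calibrate(
                partner_pwm, calibration, config.cl_edges, config.cl_min
            )
            fg_partner_hits = pwm_scan.scan_peaks(partner_cm, peaks)
            bg_partner_hits = pwm_scan.scan_peaks(partner_cm, bg.peaks)
            fg_ces = ce_core.enumerate_ces(
                fg_anchor_hits, fg_partner_hits,
                config.spacer_min, config.spacer_max,
            )
            bg_ces = ce_core.enumerate_ces(
                bg_anchor_hits, bg_partner_hits,
                config.spacer_min, config.spacer_max,
            )
            motif_results.append(
                _analyse_motif(
                    partner.motif_id, fg_ces, bg_ces, n_fg, n_bg, peaks, sim
                )
            )
        except (ValueError, pwm_scan.CalibrationError) as exc:
            logger.warning("skipping partner %r: %s", partner.motif_id, exc)
        progress(0.3 + 0.65 * (i + 1) / max(n_partners, 1), f"partner {i + 1}")

    adjusted = None
    if n_partners > 1:
        raw = {
            mr.motif_id: {f: mr.flow_p(f) for f in FLOWS}
            for mr in motif_results
            if mr.motif_id != "Anchor"
        }
        adjusted = ce_stats.adjust_for_library(raw)
    progress(1.0, "done")
    return RunResult(
        config=config,
        anchor_id=anchor.motif_id,
        n_fg_peaks=n_fg,
        n_bg_peaks=n_bg,
        motif_results=motif_results,
        adjusted=adjusted,
        sort_by=config.sort_by,
        sort_ascending=config.sort_ascending,
    )


def run_pair(
    peaks: PeakSet,
    anchor: FrequencyMatrix,
    partner: Optional[FrequencyMatrix],
    config: RunConfig = RunConfig(),
    calibration: Optional[PeakSet] = None,
    progress: ProgressCallback = _null_progress,
) -> RunResult:
    """Analyse one Anchor/Partner pair (or anchor-only homotypic run)."""
    partners = [partner] if partner is not None else []
    return run_library(peaks, anchor, partners, config, calibration, progress)


def run_and_write(
    peaks: PeakSet,
    anchor: FrequencyMatrix,
    partners: Sequence[FrequencyMatrix],
    outdir: str,
    config: RunConfig = RunConfig(),
    calibration: Optional[PeakSet] = None,
    progress: ProgressCallback = _null_progress,
) -> RunResult:
    """Run and write every output table under ``outdir``."""
    result = run_library(peaks, anchor, partners, config, calibration, progress)
    motif_io.write_output_tables(result, outdir)
    return result
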