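"""Input/output: peak FASTA files, nucleotide frequency matrices, motif
libraries, and the tab-separated result tables.

All frequency matrices are held internally in a single alphabet order
(A, C, G, T); dialect readers permute their native order into it.
Coordinates in every output table are 0-based, half-open.
"""

from __future__ import annotations

import io
import logging
import math
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_VALID_CHARS = frozenset("ACGTN")

DIALECTS = ("plain", "hocomoco_pcm", "jaspar", "meme_minimal")


class MotifIOError(ValueError):
    """Raised for malformed peak or motif input files."""


@dataclass
class PeakSet:
    """An ordered collection of named DNA sequences (ChIP-seq peaks).

    Sequences are uppercase over the alphabet {A, C, G, T, N}; ids are
    unique within a set.
    """

    records: list[tuple[str, str]]
    source_path: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        cleaned: list[tuple[str, str]] = []
        for pid, seq in self.records:
            if pid in seen:
                raise MotifIOError(f"duplicate peak id {pid!r}")
            seen.add(pid)
            s = seq.upper()
            bad = set(s) - _VALID_CHARS
            if bad:
                raise MotifIOError(
                    f"peak {pid!r} contains illegal characters {sorted(bad)!r}"
                )
            if not s:
                raise MotifIOError(f"peak {pid!r} has empty sequence")
            cleaned.append((pid, s))
        self.records = cleaned

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [pid for pid, _ in self.records]

    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.records)

    def base_frequencies(self) -> np.ndarray:
        """Empirical (A, C, G, T) frequencies; N is ignored."""
        counts = np.zeros(4)
        for _, seq in self.records:
            for i, b in enumerate(ALPHABET):
                counts[i] += seq.count(b)
        total = counts.sum()
        if total == 0:
            raise MotifIOError("peak set contains no A/C/G/T letters")
        return counts / total


@dataclass
class FrequencyMatrix:
    """Positional nucleotide counts or probabilities for a motif.

    ``columns`` has shape (L, 4) in (A, C, G, T) order: one row per motif
    position.  ``is_counts`` distinguishes raw counts from probability
    columns (each summing to 1).
    """

    motif_id: str
    columns: np.ndarray
    is_counts: bool = True
    dialect: str = "plain"

    MIN_LENGTH = 4

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=float)
        if cols.ndim != 2 or cols.shape[1] != 4:
            raise MotifIOError(
                f"motif {self.motif_id!r}: matrix must be L x 4, got {cols.shape}"
            )
        if cols.shape[0] < self.MIN_LENGTH:
            raise MotifIOError(
                f"motif {self.motif_id!r}: length {cols.shape[0]} < "
                f"{self.MIN_LENGTH} is degenerate"
            )
        if np.any(cols < 0):
            raise MotifIOError(f"motif {self.motif_id!r}: negative entries")
        sums = cols.sum(axis=1)
        if np.any(sums == 0):
            raise MotifIOError(f"motif {self.motif_id!r}: all-zero column")
        if not self.is_counts and np.any(np.abs(sums - 1.0) > 1e-6):
            raise MotifIOError(
                f"motif {self.motif_id!r}: probability columns must sum to 1"
            )
        self.columns = cols

    def __len__(self) -> int:
        return self.columns.shape[0]

    def probabilities(self) -> np.ndarray:
        """Column-normalised (L, 4) probability matrix."""
        return self.columns / self.columns.sum(axis=1, keepdims=True)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.columns.argmax(axis=1))

    def reverse_complement(self) -> "FrequencyMatrix":
        return FrequencyMatrix(
            motif_id=self.motif_id + "_rc",
            columns=self.columns[::-1, ::-1].copy(),
            is_counts=self.is_counts,
            dialect=self.dialect,
        )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> PeakSet:
    """Read a peak FASTA file into a :class:`PeakSet`.

    Lowercase letters are uppercased; duplicate ids, characters outside
    {A, C, G, T, N} and empty files are rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise MotifIOError(f"no such file: {path}")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise MotifIOError(f"no FASTA records in {path}")
    return PeakSet(records=records, source_path=path)


def write_fasta(peaks: PeakSet, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for pid, seq in peaks:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Frequency-matrix dialects

def _sniff_dialect(text: str) -> str:
    stripped = text.lstrip()
    if re.search(r"^MEME version", text, flags=re.M) or re.search(
        r"^letter-probability matrix", text, flags=re.M
    ):
        return "meme_minimal"
    if re.search(r"^[ACGT]\s*\[", text, flags=re.M):
        return "jaspar"
    if stripped.startswith(">"):
        return "hocomoco_pcm"
    return "plain"


def _looks_like_counts(cols: np.ndarray) -> bool:
    """Integer-valued matrices are counts; otherwise columns summing to 1
    are probabilities."""
    if np.allclose(cols, np.round(cols), atol=1e-9):
        return True
    return not np.allclose(cols.sum(axis=1), 1.0, atol=1e-6)


def _parse_four_column_blocks(text: str, path: str) -> list[FrequencyMatrix]:
    """Plain / Hocomoco PCM dialect: optional '>' id line, then L rows of
    4 whitespace-separated numbers in (A, C, G, T) order."""
    handle = io.StringIO(text if text.lstrip().startswith(">") else ">motif\n" + text)
    try:
        parsed = bio_motifs.parse(handle, "pfm-four-columns")
    except Exception as exc:  # Bio raises bare ValueError on ragged input
        raise MotifIOError(f"{path}: cannot parse 4-column matrix: {exc}") from exc
    if not parsed:
        raise MotifIOError(f"{path}: no parseable 4-column matrix block")
    out = []
    for m in parsed:
        cols = np.array(
            [[m.counts[b][i] for b in ALPHABET] for i in range(m.length)], dtype=float
        )
        out.append(
            FrequencyMatrix(
                motif_id=m.name or "motif",
                columns=cols,
                is_counts=_looks_like_counts(cols),
                dialect="hocomoco_pcm" if text.lstrip().startswith(">") else "plain",
            )
        )
    return out


def _parse_jaspar(text: str, path: str) -> list[FrequencyMatrix]:
    if not text.lstrip().startswith(">"):
        text = ">motif\n" + text
    try:
        parsed = bio_motifs.parse(io.StringIO(text), "jaspar")
    except Exception as exc:
        raise MotifIOError(f"{path}: cannot parse JASPAR matrix: {exc}") from exc
    out = []
    for m in parsed:
        cols = np.array(
            [[m.counts[b][i] for b in ALPHABET] for i in range(m.length)], dtype=float
        )
        is_counts = _looks_like_counts(cols)
        name = m.name if m.name else m.matrix_id
        out.append(
            FrequencyMatrix(
                motif_id=name or "motif", columns=cols, is_counts=is_counts,
                dialect="jaspar",
            )
        )
    return out


_MEME_MOTIF_RE = re.compile(r"^MOTIF\s+(\S+)", flags=re.M)


def _parse_meme_minimal(text: str, path: str) -> list[FrequencyMatrix]:
    """MEME minimal dialect, keeping the printed probabilities exact."""
    out: list[FrequencyMatrix] = []
    blocks = _MEME_MOTIF_RE.split(text)
    # blocks = [preamble, id1, body1, id2, body2, ...]
    for motif_id, body in zip(blocks[1::2], blocks[2::2]):
        lines = body.splitlines()
        rows: list[list[float]] = []
        in_matrix = False
        for line in lines:
            if line.lstrip().startswith("letter-probability matrix"):
                in_matrix = True
                continue
            if in_matrix:
                fields = line.split()
                if len(fields) == 4:
                    try:
                        rows.append([float(x) for x in fields])
                    except ValueError:
                        break
                elif rows:
                    break
        if not rows:
            raise MotifIOError(
                f"{path}: motif {motif_id!r} has no letter-probability matrix"
            )
        out.append(
            FrequencyMatrix(
                motif_id=motif_id,
                columns=np.array(rows),
                is_counts=False,
                dialect="meme_minimal",
            )
        )
    if not out:
        raise MotifIOError(f"{path}: no MOTIF blocks found")
    return out


def _parse_matrices(text: str, dialect: str, path: str) -> list[FrequencyMatrix]:
    if dialect == "auto":
        dialect = _sniff_dialect(text)
    if dialect in ("plain", "hocomoco_pcm"):
        return _parse_four_column_blocks(text, path)
    if dialect == "jaspar":
        return _parse_jaspar(text, path)
    if dialect == "meme_minimal":
        return _parse_meme_minimal(text, path)
    raise MotifIOError(f"unknown matrix dialect {dialect!r}")


def read_frequency_matrix(
    path: str | os.PathLike, dialect: str = "auto"
) -> FrequencyMatrix:
    """Read a single motif frequency matrix.

    ``dialect`` is one of ``plain``, ``hocomoco_pcm``, ``jaspar``,
    ``meme_minimal`` or ``auto`` (sniffed from header tokens).  Columns are
    returned in (A, C, G, T) order regardless of the dialect's native layout.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise MotifIOError(f"no such file: {path}")
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise MotifIOError(f"empty matrix file: {path}")
    mats = _parse_matrices(text, dialect, path)
    if len(mats) != 1:
        raise MotifIOError(
            f"{path}: expected one motif, found {len(mats)} "
            "(use read_motif_library for multi-motif files)"
        )
    return mats[0]


def read_motif_library(
    path: str | os.PathLike, dialect: str = "auto"
) -> list[FrequencyMatrix]:
    """Read a multi-motif file (MEME minimal or concatenated PCM blocks).

    Duplicate ids are deduplicated by suffixing ``.2``, ``.3``, ...;
    block order is preserved.  Blocks that fail to parse as a valid motif
    are skipped with a warning; zero parseable motifs is an error.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise MotifIOError(f"no such file: {path}")
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise MotifIOError(f"empty motif library: {path}")
    sniffed = _sniff_dialect(text) if dialect == "auto" else dialect
    mats: list[FrequencyMatrix] = []
    if sniffed == "meme_minimal":
        blocks = _MEME_MOTIF_RE.split(text)
        for motif_id, body in zip(blocks[1::2], blocks[2::2]):
            try:
                mats.extend(_parse_meme_minimal(f"MOTIF {motif_id}\n{body}", path))
            except MotifIOError as exc:
                logger.warning("skipping malformed library entry %r: %s", motif_id, exc)
    else:
        # split on '>' headers so one bad block does not kill the file
        chunks = re.split(r"(?m)^(?=>)", text)
        for chunk in chunks:
            if not chunk.strip():
                continue
            try:
                mats.extend(_parse_matrices(chunk, sniffed, path))
            except MotifIOError as exc:
                header = chunk.splitlines()[0][:40]
                logger.warning("skipping malformed library entry %r: %s", header, exc)
    if not mats:
        raise MotifIOError(f"{path}: no motifs could be parsed")
    seen: dict[str, int] = {}
    for m in mats:
        n = seen.get(m.motif_id, 0) + 1
        seen[m.motif_id] = n
        if n > 1:
            m.motif_id = f"{m.motif_id}.{n}"
    return mats


def write_frequency_matrix(fm: FrequencyMatrix, path: str | os.PathLike) -> None:
    """Write a matrix in the plain/PCM 4-column dialect (A C G T)."""
    with open(path, "w") as fh:
        fh.write(f">{fm.motif_id}\n")
        for row in fm.columns:
            if fm.is_counts and np.allclose(row, np.round(row)):
                fh.write("\t".join(str(int(round(x))) for x in row) + "\n")
            else:
                fh.write("\t".join(repr(float(x)) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Result tables

FLOWS = ("Full", "Partial", "Overlap", "Spacer", "Any")

_FLOAT_FMT = "%.6g"


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        if math.isnan(x):
            return "NA"
        return _FLOAT_FMT % x
    return str(x)


def _write_tsv(path: str, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


def _safe_name(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", name)


def write_output_tables(results, outdir: str | os.PathLike) -> list[str]:
    """Write all result tables for a completed run.

    ``results`` is a :class:`mcotce.pipeline.RunResult`.  Produces, under
    ``outdir``: ``results.tsv`` (one row per second motif), ``pvalues.tsv``
    (all contingency counts and raw p-values), and per-motif subdirectories
    with ``histogram.tsv``, five ``heatmap_<flow>.tsv``, ``ce_list.tsv``,
    ``logo_counts.tsv`` and ``logo_annotation.tsv``.  Returns the list of
    files written.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []

    header = (
        ["Motif name"]
        + [f"CE {f} -log10(P)" for f in FLOWS]
        + ["Similarity -log10(P)", "Similar flag"]
        + [f"Asymmetry {f} signed -log10(P)" for f in FLOWS]
    )
    if results.adjusted is not None:
        header += [f"CE {f} -log10(P) Bonferroni" for f in FLOWS]
    rows = []
    for mr in results.motif_results:
        row: list = [mr.motif_id]
        row += [mr.flow_neg_log10_p(f) for f in FLOWS]
        if mr.similarity is None:
            row += [None, None]
        else:
            row += [
                -math.log10(max(mr.similarity.p_value, 1e-320)),
                int(mr.similarity.p_value < 0.05),
            ]
        row += [mr.asymmetry_signed(f) for f in FLOWS]
        if results.adjusted is not None:
            adj = results.adjusted.get(mr.motif_id, {})
            row += [adj.get(f) for f in FLOWS]
        rows.append(row)
    if results.sort_by is not None:
        col = results.sort_by
        try:
            idx = header.index(col)
        except ValueError:
            raise MotifIOError(f"--sort-by column {col!r} not in results table")
        def key(row):
            v = row[idx]
            missing = v is None or (isinstance(v, float) and math.isnan(v))
            return (missing, v if not missing else 0, row[0])
        rows.sort(key=key, reverse=not results.sort_ascending)
    p = os.path.join(outdir, "results.tsv")
    _write_tsv(p, header, rows)
    written.append(p)

    prows = []
    for mr in results.motif_results:
        for fr in mr.flow_results:
            t = fr.table
            prows.append(
                [mr.motif_id, "enrichment", fr.flow, fr.conservation_class,
                 t.a, t.b, t.c, t.d, fr.p_value]
            )
        for ar in mr.asymmetry_results:
            t = ar.table
            prows.append(
                [mr.motif_id, "asymmetry", ar.flow, "",
                 t.a, t.b, t.c, t.d,
                 ar.p_value if ar.assessed else None]
            )
        if mr.similarity is not None:
            prows.append(
                [mr.motif_id, "similarity", "", "", "", "", "", "",
                 mr.similarity.p_value]
            )
    p = os.path.join(outdir, "pvalues.tsv")
    _write_tsv(
        p,
        ["motif", "test", "flow", "conservation_class", "a", "b", "c", "d",
         "p_value"],
        prows,
    )
    written.append(p)

    for mr in results.motif_results:
        mdir = os.path.join(outdir, _safe_name(mr.motif_id))
        os.makedirs(mdir, exist_ok=True)

        p = os.path.join(mdir, "histogram.tsv")
        _write_tsv(
            p,
            ["orientation", "geometry", "foreground_percent"],
            [(r.orientation, r.geometry_label, r.foreground_percent)
             for r in mr.histogram.rows],
        )
        written.append(p)

        for hm in mr.heatmaps:
            p = os.path.join(mdir, f"heatmap_{hm.flow}.tsv")
            edges = hm.bin_labels()
            with open(p, "w") as fh:
                fh.write("anchor_cl\\partner_cl\t" + "\t".join(edges) + "\n")
                for i, lab in enumerate(edges):
                    fh.write(
                        lab + "\t"
                        + "\t".join(_FLOAT_FMT % v for v in hm.values[i]) + "\n"
                    )
            written.append(p)

        p = os.path.join(mdir, "ce_list.tsv")
        _write_tsv(
            p,
            ["peak_id",
             "anchor_start", "anchor_end", "anchor_strand", "anchor_score",
             "anchor_cl",
             "partner_start", "partner_end", "partner_strand", "partner_score",
             "partner_cl",
             "orientation", "location", "geometry"],
            [(ce.peak_id,
              ce.anchor.start, ce.anchor.end, ce.anchor.strand,
              ce.anchor.score, ce.anchor.cl,
              ce.partner.start, ce.partner.end, ce.partner.strand,
              ce.partner.score, ce.partner.cl,
              ce.orientation, ce.location, ce.geometry_label())
             for ce in mr.fg_ces],
        )
        written.append(p)

        p = os.path.join(mdir, "logo_counts.tsv")
        if mr.logo is not None:
            _write_tsv(
                p,
                ["position", "A", "C", "G", "T"],
                [(i, *row) for i, row in enumerate(mr.logo.counts)],
            )
            pa = os.path.join(mdir, "logo_annotation.tsv")
            _write_tsv(
                pa,
                ["role", "start", "end", "strand", "variant", "n_instances"],
                [("anchor", *mr.logo.anchor_interval, mr.logo.anchor_strand,
                  mr.logo.variant_label, mr.logo.n_instances),
                 ("partner", *mr.logo.partner_interval, mr.logo.partner_strand,
                  mr.logo.variant_label, mr.logo.n_instances)],
            )
        else:
            _write_tsv(p, ["position", "A", "C", "G", "T"], [])
            pa = os.path.join(mdir, "logo_annotation.tsv")
            _write_tsv(
                pa, ["role", "start", "end", "strand", "variant", "n_instances"], []
            )
        written.append(p)
        written.append(pa)

    return written


def write_calibration_cache(cm, path: str | os.PathLike) -> None:
    """Two-column TSV (score cutpoint, empirical FPR) for reproducibility."""
    _write_tsv(
        path,
        ["score", "fpr"],
        [(float(s), float(f)) for s, f in zip(cm.score_grid, cm.fpr_grid)],
    )
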