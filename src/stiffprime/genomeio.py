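"""Readers/writers for the genomic formats the pipeline touches, plus the
interval algebra every other module builds on.

Conventions
-----------
All coordinates are 0-based, half-open (BED convention). Peaks/regions are
unstranded (``.``); only gene models and motif hits carry strand. A region's
midpoint is ``(start + end) // 2``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "SignalTrack",
    "StateSegmentation",
    "PWM",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "read_counts",
    "write_counts",
    "read_gene_models",
    "write_gene_models",
    "merge_intervals",
    "overlap_bases",
    "total_bases",
    "midpoint",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."
    extra: tuple = ()

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def midpoint(iv: GenomicInterval) -> int:
    return iv.midpoint


@dataclass(frozen=True)
class GeneModel:
    """A gene with TSS, span and exon structure.

    For ``+`` genes the TSS is ``gene_start``; for ``-`` genes it is
    ``gene_end - 1`` (the last covered base under the half-open convention).
    """

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    exons: tuple = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not (0 <= self.gene_start < self.gene_end):
            raise ValueError(f"invalid gene span for {self.gene_id}")
        prev_end = self.gene_start
        for s, e in self.exons:
            if s < prev_end or e > self.gene_end or s >= e:
                raise ValueError(
                    f"exons of {self.gene_id} must be sorted, non-overlapping "
                    "and within the gene span"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        return self.gene_start if self.strand == "+" else self.gene_end - 1

    @property
    def tts(self) -> int:
        """Transcription termination site (last base on the gene strand)."""
        return self.gene_end - 1 if self.strand == "+" else self.gene_start


class SignalTrack:
    """Piecewise-constant, non-negative coverage, per chromosome.

    Stored as parallel arrays of (start, end, value) segments, sorted and
    non-overlapping within a chromosome. Bases not covered by any segment
    read as 0.
    """

    def __init__(self, segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None):
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        if segments:
            for chrom, (starts, ends, values) in segments.items():
                self.set_chrom(chrom, starts, ends, values)

    def set_chrom(self, chrom: str, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if not (len(starts) == len(ends) == len(values)):
            raise ValueError("segment arrays must have equal length")
        if len(starts):
            if np.any(ends <= starts):
                raise ValueError("segments must have end > start")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"segments on {chrom} overlap or are unsorted")
            if np.any(~np.isfinite(values)) or np.any(values < 0):
                raise ValueError("segment values must be finite and >= 0")
        # cumulative integral up to the start of each segment, for O(log n) lookups
        cum = np.concatenate([[0.0], np.cumsum((ends - starts) * values)])
        self._chroms[chrom] = (starts, ends, values, cum)

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    def segments(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        s, e, v, _ = self._chroms[chrom]
        return s, e, v

    @property
    def n_segments(self) -> int:
        return sum(len(self._chroms[c][0]) for c in self._chroms)

    @property
    def total_signal(self) -> float:
        return float(sum(self._chroms[c][3][-1] for c in self._chroms))

    @property
    def covered_bases(self) -> int:
        return int(
            sum((self._chroms[c][1] - self._chroms[c][0]).sum() for c in self._chroms)
        )

    def _cum_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of the track over [0, pos) for an array of positions."""
        starts, ends, values, cum = self._chroms[chrom]
        idx = np.searchsorted(ends, pos, side="right")
        base = cum[idx]
        # partial segment: pos falls inside segment idx
        inside = (idx < len(starts)) & (pos > starts[np.minimum(idx, len(starts) - 1)])
        safe = np.minimum(idx, len(starts) - 1)
        partial = np.where(
            inside, (pos - starts[safe]).clip(min=0) * values[safe], 0.0
        )
        return base + partial

    def integrate(self, chrom: str, starts, ends) -> np.ndarray:
        """Vectorized integral of the signal over [start, end) windows."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._chroms:
            return np.zeros(len(starts))
        return self._cum_at(chrom, ends) - self._cum_at(chrom, starts)

    def window_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); uncovered bases are 0."""
        out = np.zeros(end - start)
        if chrom not in self._chroms:
            return out
        starts, ends, values, _ = self._chroms[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            a, b = max(s, start), min(e, end)
            if a < b:
                out[a - start : b - start] = v
        return out

    def scaled(self, factor: float) -> "SignalTrack":
        out = SignalTrack()
        for chrom in self._chroms:
            s, e, v = self.segments(chrom)
            out.set_chrom(chrom, s, e, v * factor)
        return out


@dataclass
class StateSegmentation:
    """A chromatin-state partition: labeled intervals plus the genome size."""

    intervals: list
    genome_size: int
    state_labels: tuple = ()

    def __post_init__(self):
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")
        labels = sorted({iv.name for iv in self.intervals})
        if not self.state_labels:
            self.state_labels = tuple(labels)
        else:
            unknown = set(labels) - set(self.state_labels)
            if unknown:
                raise ValueError(f"intervals carry undeclared state labels: {unknown}")
        by_chrom: dict[str, list] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs, key=lambda x: x.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(f"segmentation intervals overlap on {chrom}")

    def state_intervals(self, label: str) -> list:
        return [iv for iv in self.intervals if iv.name == label]


@dataclass
class PWM:
    """A position weight matrix: probabilities over A,C,G,T per column.

    Built from raw count matrices by adding ``pseudocount`` to every cell and
    normalizing each column to sum to 1.
    """

    motif_id: str
    probs: np.ndarray  # (4, L), rows A,C,G,T
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.25

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 4:
            raise ValueError("PWM needs a 4 x L matrix with L >= 4")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @classmethod
    def from_counts(cls, motif_id: str, counts, background=None, pseudocount: float = 0.25) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4:
            raise FormatError(f"PFM {motif_id}: expected 4 rows, got {counts.shape[0]}")
        if np.any(counts < 0):
            raise FormatError(f"PFM {motif_id}: negative counts")
        probs = counts + pseudocount
        probs /= probs.sum(axis=0, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(motif_id, probs, bg, pseudocount)

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """(4, L) log2(p / background) scoring matrix."""
        return np.log2(self.probs / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))


# ---------------------------------------------------------------------------
# BED / narrowPeak


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3-6 or narrowPeak; extra columns are preserved in ``extra``."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else f"iv_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
            extra = tuple(fields[4:5] + fields[6:]) if len(fields) > 4 else ()
            intervals.append(GenomicInterval(chrom, start, end, name, strand, extra))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name]
            if iv.extra or iv.strand != ".":
                fields.append(iv.extra[0] if iv.extra else "0")
                fields.append(iv.strand)
                fields.extend(iv.extra[1:])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA into an in-memory dict of uppercase sequences."""
    fa = Fasta(str(path), sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path) -> SignalTrack:
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad bedGraph record") from exc
            per_chrom.setdefault(fields[0], []).append((start, end, value))
    track = SignalTrack()
    for chrom, segs in per_chrom.items():
        segs.sort()
        arr = np.array(segs, dtype=float)
        track.set_chrom(chrom, arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
    return track


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.segments(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# JASPAR PFM

_JASPAR_ROW = re.compile(r"^(?:([ACGT])\s*\[)?\s*([0-9eE+.\s-]+?)\s*\]?\s*$")


def read_jaspar_pfm(path, pseudocount: float = 0.25, background=None) -> list[PWM]:
    """Read JASPAR-format PFMs: a ``>motif_id`` header then 4 count rows.

    Both the bare-number dialect and the ``A [ 8 0 ... ]`` row-label dialect
    are accepted.
    """
    motifs: list[PWM] = []
    motif_id = None
    rows: list[list[float]] = []

    def flush():
        if motif_id is None:
            return
        if len(rows) != 4:
            raise FormatError(f"PFM {motif_id}: expected 4 count rows, got {len(rows)}")
        motifs.append(PWM.from_counts(motif_id, np.array(rows), background, pseudocount))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                rows = []
            else:
                m = _JASPAR_ROW.match(line)
                if m is None:
                    raise FormatError(f"{path}: unparseable PFM row: {line!r}")
                try:
                    rows.append([float(x) for x in m.group(2).split()])
                except ValueError as exc:
                    raise FormatError(f"{path}: bad number in PFM row {line!r}") from exc
    flush()
    return motifs


def write_jaspar_pfm(counts_by_motif: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for motif_id, counts in counts_by_motif.items():
            fh.write(f">{motif_id}\n")
            for base, row in zip(BASES, np.asarray(counts)):
                fh.write(f"{base} [ " + " ".join(f"{x:g}" for x in row) + " ]\n")


# ---------------------------------------------------------------------------
# count matrices + sample sheets


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "assay", "stiffness", "day", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise FormatError(f"sample sheet {path} missing columns: {sorted(missing)}")
    sheet["day"] = sheet["day"].astype(int)
    return sheet.set_index("sample_id", drop=False)


def read_counts(path, sample_sheet: pd.DataFrame):
    """Read a features x samples TSV into a CountMatrix.

    The header row carries sample ids; the first column carries feature ids.
    Sample order is rearranged to match the sample sheet.
    """
    from .difftest import CountMatrix  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = set(df.columns) - set(sample_sheet.index)
    if unknown:
        raise FormatError(f"{path}: samples not in sample sheet: {sorted(unknown)}")
    meta = sample_sheet.loc[list(df.columns)]
    df = df[list(meta.index)]
    if not all(np.issubdtype(dt, np.integer) for dt in df.dtypes):
        raise FormatError(f"{path}: non-integer counts")
    return CountMatrix(df, meta)


def write_counts(counts, path) -> None:
    counts.table.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# gene models (refFlat-like TSV)

_GENE_COLUMNS = ["gene_id", "chrom", "strand", "gene_start", "gene_end", "exon_starts", "exon_ends"]


def read_gene_models(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_GENE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path} missing columns: {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        ex_s = [int(x) for x in str(row.exon_starts).split(",") if x]
        ex_e = [int(x) for x in str(row.exon_ends).split(",") if x]
        genes.append(
            GeneModel(
                row.gene_id,
                row.chrom,
                row.strand,
                int(row.gene_start),
                int(row.gene_end),
                tuple(zip(ex_s, ex_e)),
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "gene_start": g.gene_start,
                "gene_end": g.gene_end,
                "exon_starts": ",".join(str(s) for s, _ in g.exons),
                "exon_ends": ",".join(str(e) for _, e in g.exons),
            }
        )
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval algebra


def merge_intervals(intervals: Sequence[GenomicInterval], min_gap: int = 0) -> list[GenomicInterval]:
    """Merge intervals closer than ``min_gap`` bases (0 merges book-ended ones).

    The output is sorted by (chrom, start); a merged interval's name joins the
    member names with ``|``.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    out: list[GenomicInterval] = []
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    cur = None
    names: list[str] = []
    for iv in by_pos:
        if cur is not None and iv.chrom == cur.chrom and iv.start <= cur.end + min_gap:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end, cur.name)
            names.append(iv.name)
        else:
            if cur is not None:
                out.append(GenomicInterval(cur.chrom, cur.start, cur.end, "|".join(names)))
            cur = iv
            names = [iv.name]
    if cur is not None:
        out.append(GenomicInterval(cur.chrom, cur.start, cur.end, "|".join(names)))
    return out


def total_bases(intervals: Sequence[GenomicInterval]) -> int:
    """Total bases covered (after self-merging)."""
    return sum(iv.width for iv in merge_intervals(intervals))


def overlap_bases(set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]) -> int:
    """Total bases in the intersection of two interval sets (each self-merged)."""
    a = merge_intervals(set_a)
    b = merge_intervals(set_b)
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    total = 0
    for chrom, ivs_b in by_chrom_b.items():
        ivs_a = [iv for iv in a if iv.chrom == chrom]
        i = j = 0
        while i < len(ivs_a) and j < len(ivs_b):
            lo = max(ivs_a[i].start, ivs_b[j].start)
            hi = min(ivs_a[i].end, ivs_b[j].end)
            if lo < hi:
                total += hi - lo
            if ivs_a[i].end < ivs_b[j].end:
                i += 1
            else:
                j += 1
    return total
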