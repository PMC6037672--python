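"""Genomic interval substrate: peaks, genes, BED/peak-table I/O, overlap machinery.

All coordinates are 0-based half-open internally. BED input is taken as-is;
MACS-style tab tables (1-based inclusive, header line) are converted on
ingest. Interval overlap uses the half-open convention throughout: two
intervals overlap iff max(start_a, start_b) < min(end_a, end_b).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneAnnotation",
    "PeakOrigin",
    "BiasClass",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_peaks",
    "write_peaks_bed",
    "read_gene_annotation",
    "write_gene_annotation",
    "overlap_peaks",
    "count_reads_in_peak",
    "count_reads_for_peaks",
    "promoter_window",
    "assign_to_promoters",
    "active_promoter_genes",
    "peaks_to_dataframe",
    "write_peak_table",
    "read_peak_table",
]


class BedParseError(ValueError):
    """Raised for malformed interval lines; carries the 1-based line number."""


class PeakOrigin(str, enum.Enum):
    SAMPLE1_UNIQUE = "sample1-unique"
    SAMPLE2_UNIQUE = "sample2-unique"
    COMMON = "common"
    UNSET = "unset"


class BiasClass(str, enum.Enum):
    SAMPLE1 = "sample1-biased"
    SAMPLE2 = "sample2-biased"
    UNBIASED = "unbiased"
    UNSET = "unset"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and max(self.start, other.start) < min(
            self.end, other.end
        )


@dataclass
class Peak:
    """A ChIP-seq peak with its comparison annotations.

    ``m_value``/``a_value`` hold the log2 intensity ratio and average log2
    intensity of the two samples; ``m_normalized`` the trend-corrected M;
    ``p_value`` the per-peak differential-binding significance.
    Unset numeric annotations are ``None``.
    """

    interval: GenomicInterval
    summit: int | None = None
    read_count_1: int | None = None
    read_count_2: int | None = None
    m_value: float | None = None
    a_value: float | None = None
    m_normalized: float | None = None
    p_value: float | None = None
    bias_class: BiasClass = BiasClass.UNSET
    origin: PeakOrigin = PeakOrigin.UNSET
    name: str | None = None

    def __post_init__(self) -> None:
        if self.summit is not None and not (0 <= self.summit < self.interval.length):
            raise ValueError(
                f"summit offset {self.summit} outside peak of length "
                f"{self.interval.length}"
            )
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def key(self) -> str:
        """Stable peak identity used to index hit matrices."""
        return f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene symbol with its width-1 TSS interval and strand."""

    gene_id: str
    tss: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.tss.length != 1:
            raise ValueError("tss interval must have width exactly 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def _iter_data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+/BED6 file into intervals (0-based half-open).

    Comment (#), track and browser lines are skipped. Malformed coordinates
    raise :class:`BedParseError` naming the offending line.
    """
    intervals: list[GenomicInterval] = []
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise BedParseError(f"{path}: line {lineno}: expected >=3 columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(
                f"{path}: line {lineno}: non-integer coordinate"
            ) from exc
        strand = "."
        if len(fields) >= 6 and fields[5] in ("+", "-"):
            strand = fields[5]
        try:
            intervals.append(GenomicInterval(chrom, start, end, strand))
        except ValueError as exc:
            raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_peaks(path: str | Path, dialect: str = "bed") -> list[Peak]:
    """Read a peak file into :class:`Peak` records.

    ``dialect="bed"`` reads BED3+ (0-based half-open, no summit).
    ``dialect="macs-xls"`` reads a tab table with a header line and 1-based
    inclusive ``start``/``end``; the ``summit`` column is the 0-based offset
    of the summit from the peak start.
    """
    if dialect == "bed":
        return [Peak(interval=iv) for iv in read_bed(path)]
    if dialect != "macs-xls":
        raise ValueError(f"unknown peak dialect {dialect!r}")

    peaks: list[Peak] = []
    header: list[str] | None = None
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = [f.strip().lower() for f in fields]
            continue
        row = dict(zip(header, fields))
        try:
            chrom = row.get("chr") or row["chrom"]
            start1 = int(row["start"])
            end1 = int(row["end"])
        except (KeyError, ValueError) as exc:
            raise BedParseError(f"{path}: line {lineno}: bad row ({exc})") from exc
        start0 = start1 - 1
        if start0 < 0:
            raise BedParseError(
                f"{path}: line {lineno}: 1-based start {start1} converts to "
                "negative coordinate"
            )
        summit = None
        if "summit" in row and row["summit"] != "":
            summit = int(row["summit"])
        try:
            peak = Peak(interval=GenomicInterval(chrom, start0, end1), summit=summit)
        except ValueError as exc:
            raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
        peaks.append(peak)
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    write_bed((p.interval for p in peaks), path)


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a tab-delimited TSS table: gene_id, chrom, tss (0-based), strand."""
    genes: list[GeneAnnotation] = []
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if fields[0].lower() == "gene_id":  # optional header
            continue
        if len(fields) < 4:
            raise BedParseError(f"{path}: line {lineno}: expected 4 columns")
        gene_id, chrom, tss_s, strand = fields[:4]
        try:
            tss = int(tss_s)
            genes.append(
                GeneAnnotation(gene_id, GenomicInterval(chrom, tss, tss + 1), strand)
            )
        except ValueError as exc:
            raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return genes


def write_gene_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.tss.chrom}\t{g.tss.start}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Overlap machinery
# ---------------------------------------------------------------------------


def _mark_overlapping(queries: Sequence[Peak], targets: Sequence[Peak]) -> list[bool]:
    """For each query peak, does any target peak overlap it (>=1 bp)?

    Sort-and-sweep per chromosome: targets sorted by start with a running
    prefix-max of ends; a query overlaps some target iff among targets with
    start < query.end the maximal end exceeds query.start. O((n+m) log m).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in targets:
        by_chrom.setdefault(t.interval.chrom, []).append(
            (t.interval.start, t.interval.end)
        )
    prepared: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.fromiter((s for s, _ in ivs), dtype=np.int64)
        ends = np.maximum.accumulate(np.fromiter((e for _, e in ivs), dtype=np.int64))
        prepared[chrom] = (starts, ends)

    flags: list[bool] = []
    for q in queries:
        got = prepared.get(q.interval.chrom)
        if got is None:
            flags.append(False)
            continue
        starts, maxends = got
        k = int(np.searchsorted(starts, q.interval.end, side="left"))
        flags.append(k > 0 and int(maxends[k - 1]) > q.interval.start)
    return flags


def overlap_peaks(
    peaks_1: Sequence[Peak], peaks_2: Sequence[Peak]
) -> tuple[list[Peak], list[Peak]]:
    """Label every peak common or sample-unique by cross-sample overlap.

    A peak is ``common`` iff it shares >=1 bp (half-open) with any peak of
    the other sample; otherwise it is unique to its own sample. Labels are
    written onto the input peaks, which are also returned.
    """
    for p, is_common in zip(peaks_1, _mark_overlapping(peaks_1, peaks_2)):
        p.origin = PeakOrigin.COMMON if is_common else PeakOrigin.SAMPLE1_UNIQUE
    for p, is_common in zip(peaks_2, _mark_overlapping(peaks_2, peaks_1)):
        p.origin = PeakOrigin.COMMON if is_common else PeakOrigin.SAMPLE2_UNIQUE
    return list(peaks_1), list(peaks_2)


def _read_midpoints(reads: Sequence[GenomicInterval], extension: int) -> dict[str, np.ndarray]:
    """Sorted extension-shifted midpoints per chromosome.

    A read is treated as the 5' end of a fragment of length ``extension``:
    + strand reads contribute start + extension/2, - strand reads
    end - extension/2, unstranded reads their geometric midpoint.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    half = extension / 2.0
    mids: dict[str, list[float]] = {}
    for r in reads:
        if r.strand == "+":
            m = r.start + half
        elif r.strand == "-":
            m = r.end - half
        else:
            m = (r.start + r.end) / 2.0
        mids.setdefault(r.chrom, []).append(m)
    return {c: np.sort(np.asarray(v, dtype=float)) for c, v in mids.items()}


def count_reads_in_peak(
    peak: Peak, reads: Sequence[GenomicInterval], extension: int = 100
) -> int:
    """Number of reads whose shifted midpoint falls in [start, end)."""
    return count_reads_for_peaks([peak], reads, extension)[0]


def count_reads_for_peaks(
    peaks: Sequence[Peak], reads: Sequence[GenomicInterval], extension: int = 100
) -> np.ndarray:
    """Vectorized midpoint-in-interval read counting over many peaks."""
    mids = _read_midpoints(reads, extension)
    counts = np.zeros(len(peaks), dtype=np.int64)
    for i, p in enumerate(peaks):
        arr = mids.get(p.interval.chrom)
        if arr is None:
            continue
        lo = np.searchsorted(arr, p.interval.start, side="left")
        hi = np.searchsorted(arr, p.interval.end, side="left")
        counts[i] = hi - lo
    return counts


# ---------------------------------------------------------------------------
# Promoter assignment
# ---------------------------------------------------------------------------


def promoter_window(
    gene: GeneAnnotation, upstream: int, downstream: int
) -> GenomicInterval:
    """Strand-oriented promoter window around the TSS, clipped at 0.

    On the + strand the window is [tss - upstream, tss + downstream); on the
    - strand it is mirrored so that "upstream" extends toward larger
    coordinates: [tss + 1 - downstream, tss + 1 + upstream).
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    t = gene.tss.start
    if gene.strand == "+":
        lo, hi = t - upstream, t + downstream
    else:
        lo, hi = t + 1 - downstream, t + 1 + upstream
    lo = max(lo, 0)
    hi = max(hi, lo + 1)
    return GenomicInterval(gene.tss.chrom, lo, hi, gene.strand)


def assign_to_promoters(
    peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    upstream: int = 2000,
    downstream: int = 2000,
) -> dict[str, list[Peak]]:
    """Map each gene to the peaks overlapping its promoter window.

    A peak may be assigned to several genes; genes without any overlapping
    peak are absent from the result.
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end, i)
        )
    prepared: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
        idx = np.array([i for _, _, i in ivs], dtype=np.int64)
        prepared[chrom] = (starts, ends, idx)

    out: dict[str, list[Peak]] = {}
    for g in genes:
        got = prepared.get(g.tss.chrom)
        if got is None:
            continue
        win = promoter_window(g, upstream, downstream)
        starts, ends, idx = got
        k = int(np.searchsorted(starts, win.end, side="left"))
        hit = idx[:k][ends[:k] > win.start]
        if hit.size:
            out[g.gene_id] = [peaks[int(i)] for i in np.sort(hit)]
    return out


def active_promoter_genes(
    h3k4me3_assigned: set[str], h3k27me3_assigned: set[str]
) -> set[str]:
    """Genes marked by the active mark and not by the repressive mark."""
    return set(h3k4me3_assigned) - set(h3k27me3_assigned)


# ---------------------------------------------------------------------------
# Peak tables (the normalization stage's tabular output)
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "summit",
    "read_count_1",
    "read_count_2",
    "m_value",
    "a_value",
    "m_normalized",
    "p_value",
    "bias_class",
    "origin",
]


def peaks_to_dataframe(peaks: Sequence[Peak]) -> pd.DataFrame:
    rows = []
    for p in peaks:
        rows.append(
            {
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "summit": p.summit if p.summit is not None else -1,
                "read_count_1": p.read_count_1,
                "read_count_2": p.read_count_2,
                "m_value": p.m_value,
                "a_value": p.a_value,
                "m_normalized": p.m_normalized,
                "p_value": p.p_value,
                "bias_class": p.bias_class.value,
                "origin": p.origin.value,
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_peak_table(peaks: Sequence[Peak], path: str | Path) -> None:
    df = peaks_to_dataframe(peaks)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_peak_table(path: str | Path) -> list[Peak]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: peak table missing column(s): {missing}")
    peaks = []
    for row in df.itertuples(index=False):
        summit = None if row.summit is None or int(row.summit) < 0 else int(row.summit)
        peaks.append(
            Peak(
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                summit=summit,
                read_count_1=None if pd.isna(row.read_count_1) else int(row.read_count_1),
                read_count_2=None if pd.isna(row.read_count_2) else int(row.read_count_2),
                m_value=None if pd.isna(row.m_value) else float(row.m_value),
                a_value=None if pd.isna(row.a_value) else float(row.a_value),
                m_normalized=None if pd.isna(row.m_normalized) else float(row.m_normalized),
                p_value=None if pd.isna(row.p_value) else float(row.p_value),
                bias_class=BiasClass(row.bias_class),
                origin=PeakOrigin(row.origin),
            )
        )
    return peaks
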