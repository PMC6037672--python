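"""PWM motif scanning with exact null-distribution score thresholds.

Position frequency matrices (JASPAR text format) are turned into log-odds
scoring matrices against a 0-order background. Per-position log-odds are
quantized to a fixed lattice (granularity 0.001 bit, rounding up), and the
exact distribution of the total score of a random background word is
computed by dynamic programming (iterated convolution of the per-position
score distributions on the integer lattice). The hit threshold is the
smallest lattice score whose null tail probability does not exceed the
requested per-window P-value; because scanning scores with the same
quantized matrix, P(hit | background) <= threshold_pvalue holds exactly.
Rounding up is the conservative direction: the quantized score of any word
is >= its unquantized score, so the guarantee transfers to raw scores too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .genomic import GenomicInterval, Peak

logger = logging.getLogger(__name__)

__all__ = [
    "MotifModel",
    "HitMatrix",
    "MotifParseError",
    "GRANULARITY",
    "read_jaspar",
    "write_jaspar",
    "estimate_background",
    "build_scoring",
    "score_distribution",
    "scan_sequence",
    "build_hit_matrix",
    "hits_from_intervals",
]

ALPHABET = "ACGT"
#: Score lattice granularity in bits.
GRANULARITY = 1e-3
UNIFORM_BACKGROUND = np.full(4, 0.25)


class MotifParseError(ValueError):
    """Raised for malformed motif records; names the offending record."""


@dataclass
class MotifModel:
    """A named PFM with (optionally) its derived scoring model.

    ``pfm`` is a width x 4 matrix of base counts over (A, C, G, T).
    After :func:`build_scoring`, ``log_odds`` holds the lattice-quantized
    log2-odds matrix (bits), ``threshold`` the minimal hit score and
    ``threshold_pvalue`` the null tail probability it was derived from.
    """

    motif_id: str
    name: str
    pfm: np.ndarray
    background: np.ndarray | None = None
    log_odds: np.ndarray | None = None
    threshold: float | None = None
    threshold_pvalue: float | None = None

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.ndim != 2 or self.pfm.shape[1] != 4:
            raise ValueError(f"motif {self.motif_id}: pfm must be width x 4")
        if self.pfm.shape[0] == 0:
            raise ValueError(f"motif {self.motif_id}: zero-width motif")
        if np.any(self.pfm < 0):
            raise ValueError(f"motif {self.motif_id}: negative pfm entries")

    @property
    def width(self) -> int:
        return int(self.pfm.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.pfm, axis=1))

    @property
    def is_scored(self) -> bool:
        return self.log_odds is not None and self.threshold is not None


# ---------------------------------------------------------------------------
# JASPAR I/O (Bio.motifs behind a per-record wrapper for precise errors)
# ---------------------------------------------------------------------------


def _split_records(text: str) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    header: str | None = None
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if header is not None:
                records.append((header, "\n".join(body)))
            header, body = line, []
        elif line.strip():
            body.append(line)
    if header is not None:
        records.append((header, "\n".join(body)))
    return records


def read_jaspar(path: str | Path) -> list[MotifModel]:
    """Parse a JASPAR-format PFM file (possibly multi-record).

    Each record is '>ID NAME' followed by four rows 'A [ counts... ]' etc.
    Records with missing base rows or rows of unequal width raise
    :class:`MotifParseError` naming the record ID; counts are preserved
    exactly. Scoring fields are left unset.
    """
    text = Path(path).read_text()
    models: list[MotifModel] = []
    for header, body in _split_records(text):
        parts = header[1:].split(None, 1)
        motif_id = parts[0] if parts else ""
        name = parts[1].strip() if len(parts) > 1 else motif_id
        present = {ln.strip()[:1].upper() for ln in body.splitlines() if ln.strip()}
        missing = [b for b in ALPHABET if b not in present]
        if missing:
            raise MotifParseError(
                f"motif record {motif_id!r}: missing base row(s) {missing}"
            )
        try:
            m = bio_motifs.read(StringIO(header + "\n" + body + "\n"), "jaspar")
        except Exception as exc:
            raise MotifParseError(f"motif record {motif_id!r}: {exc}") from exc
        pfm = np.array([[m.counts[b][i] for b in ALPHABET] for i in range(m.length)])
        models.append(MotifModel(motif_id=motif_id, name=name, pfm=pfm))
    return models


def write_jaspar(models: Iterable[MotifModel], path: str | Path) -> None:
    def fmt(x: float) -> str:
        return str(int(x)) if float(x).is_integer() else repr(float(x))

    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.motif_id} {m.name}\n")
            for j, base in enumerate(ALPHABET):
                row = " ".join(fmt(v) for v in m.pfm[:, j])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Scoring model
# ---------------------------------------------------------------------------


def estimate_background(sequences: Iterable[str], floor: float = 1e-3) -> np.ndarray:
    """0-order background from sequences, N ignored, entries floored.

    The floor keeps log-odds finite when a base is absent from small
    fixture sequences; the vector is renormalized after flooring.
    """
    counts = np.zeros(4)
    table = _code_table()
    for seq in sequences:
        codes = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        counts += np.bincount(codes[codes < 4], minlength=4)
    total = counts.sum()
    bg = counts / total if total > 0 else UNIFORM_BACKGROUND.copy()
    bg = np.maximum(bg, floor)
    return bg / bg.sum()


def _validate_background(background: np.ndarray) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 4 positive probabilities summing to 1")
    return bg


def build_scoring(
    model: MotifModel,
    background: np.ndarray | Sequence[float] = UNIFORM_BACKGROUND,
    pseudocount_fraction: float = 0.01,
    threshold_pvalue: float = 1e-4,
) -> MotifModel:
    """Derive the quantized log-odds matrix and exact-null hit threshold.

    Position probabilities use a background-proportional pseudocount:
    p(i,n) = (count(i,n) + f*bg(n)) / (rowsum(i) + f). The log2-odds matrix
    is quantized up to the 0.001-bit lattice; the threshold is the minimal
    lattice score t with P(S >= t | background) <= threshold_pvalue, where
    S is the quantized score of an i.i.d. background word (exact DP).
    Returns a new scored MotifModel; the input is not modified.
    """
    if pseudocount_fraction <= 0:
        raise ValueError("pseudocount_fraction must be > 0")
    if not (0.0 < threshold_pvalue <= 1.0):
        raise ValueError("threshold_pvalue must be in (0, 1]")
    bg = _validate_background(background)
    rowsum = model.pfm.sum(axis=1, keepdims=True)
    if np.any(rowsum == 0):
        raise ValueError(f"motif {model.motif_id}: empty pfm row")
    probs = (model.pfm + pseudocount_fraction * bg) / (rowsum + pseudocount_fraction)
    raw_lo = np.log2(probs / bg)
    units = np.ceil(raw_lo / GRANULARITY - 1e-9).astype(np.int64)
    log_odds = units * GRANULARITY

    scores, tail = score_distribution(log_odds, bg)
    # minimal lattice t with tail(t) <= p: one unit above the largest support
    # score still exceeding p (or the minimum support score if none does)
    above = np.nonzero(tail > threshold_pvalue)[0]
    if above.size == 0:
        thr_units = int(round(scores[0] / GRANULARITY))
    else:
        thr_units = int(round(scores[above[-1]] / GRANULARITY)) + 1
    return replace(
        model,
        background=bg,
        log_odds=log_odds,
        threshold=thr_units * GRANULARITY,
        threshold_pvalue=threshold_pvalue,
    )


def score_distribution(
    log_odds: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the total quantized score.

    Returns (support_scores ascending in bits, tail) with
    tail[i] = P(S >= support_scores[i]) for a word drawn i.i.d. from the
    background. Computed by convolving per-position score distributions on
    the integer lattice; exact up to float summation error.
    """
    bg = _validate_background(background)
    units = np.rint(np.asarray(log_odds) / GRANULARITY).astype(np.int64)
    dist = np.array([1.0])
    offset = 0  # lattice value of dist[0]
    for i in range(units.shape[0]):
        row = units[i]
        lo, hi = int(row.min()), int(row.max())
        pos = np.zeros(hi - lo + 1)
        for n in range(4):
            pos[row[n] - lo] += bg[n]
        dist = np.convolve(dist, pos)
        offset += lo
    support = (offset + np.arange(dist.size)) * GRANULARITY
    keep = dist > 0
    probs = dist[keep]
    support = support[keep]
    tail = np.cumsum(probs[::-1])[::-1]
    return support, tail


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

_CODE_TABLE: np.ndarray | None = None


def _code_table() -> np.ndarray:
    global _CODE_TABLE
    if _CODE_TABLE is None:
        t = np.full(256, 4, dtype=np.uint8)
        for i, b in enumerate(ALPHABET):
            t[ord(b)] = i
            t[ord(b.lower())] = i
        _CODE_TABLE = t
    return _CODE_TABLE


def scan_sequence(seq: str, model: MotifModel) -> list[tuple[int, str, float]]:
    """All hits of a scored motif on both strands of a sequence.

    Every window of the motif's width is scored on the forward strand and as
    its reverse complement; windows scoring >= threshold are emitted as
    (offset, strand, score) with offsets 0-based on the forward strand for
    both strands. Windows containing non-ACGT characters never hit.
    Sequences shorter than the motif yield an empty list.
    """
    if not model.is_scored:
        raise ValueError(f"motif {model.motif_id} has no scoring model")
    w = model.width
    if len(seq) < w:
        return []
    codes = _code_table()[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)

    lo5 = np.full((w, 5), -np.inf)
    lo5[:, :4] = model.log_odds
    # reverse-complement view: position j reads the complement of base j
    # against motif column w-1-j
    lo5_rc = np.full((w, 5), -np.inf)
    lo5_rc[:, :4] = model.log_odds[::-1, ::-1]

    pos_idx = np.arange(w)[None, :]
    fwd = lo5[pos_idx, windows].sum(axis=1)
    rev = lo5_rc[pos_idx, windows].sum(axis=1)

    tol = 1e-9
    hits: list[tuple[int, str, float]] = []
    thr = model.threshold - tol
    for o in np.nonzero(fwd >= thr)[0]:
        hits.append((int(o), "+", float(fwd[o])))
    for o in np.nonzero(rev >= thr)[0]:
        hits.append((int(o), "-", float(rev[o])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


# ---------------------------------------------------------------------------
# Hit matrices
# ---------------------------------------------------------------------------


@dataclass
class HitMatrix:
    """Peaks x motifs occupancy: hit counts, with a binary presence view."""

    peak_index: list[str]
    motif_index: list[str]
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=np.int64)
        if self.occupancy.shape != (len(self.peak_index), len(self.motif_index)):
            raise ValueError("occupancy shape does not match index lengths")
        if np.any(self.occupancy < 0):
            raise ValueError("occupancy entries must be >= 0")

    @property
    def binary(self) -> np.ndarray:
        return self.occupancy > 0

    def column(self, motif_id: str) -> np.ndarray:
        return self.occupancy[:, self.motif_index.index(motif_id)]

    def rows_for(self, peak_keys: Sequence[str]) -> np.ndarray:
        pos = {k: i for i, k in enumerate(self.peak_index)}
        missing = [k for k in peak_keys if k not in pos]
        if missing:
            raise KeyError(f"peaks absent from hit matrix: {missing[:3]}...")
        return self.occupancy[[pos[k] for k in peak_keys], :]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.occupancy, index=self.peak_index, columns=self.motif_index
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "peak"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "HitMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            peak_index=[str(i) for i in df.index],
            motif_index=[str(c) for c in df.columns],
            occupancy=df.to_numpy(dtype=np.int64),
        )


def _fetch_sequence(genome, chrom: str, start: int, end: int) -> str | None:
    """Sequence accessor over a pyfaidx.Fasta or a plain chrom->str mapping."""
    if isinstance(genome, Mapping):
        seq = genome.get(chrom)
        if seq is None:
            return None
        return seq[max(start, 0) : min(end, len(seq))]
    if chrom not in genome:
        return None
    contig = genome[chrom]
    return str(contig[max(start, 0) : min(end, len(contig))])


def _open_genome(genome):
    if isinstance(genome, (str, Path)):
        import pyfaidx

        return pyfaidx.Fasta(str(genome))
    return genome


def build_hit_matrix(
    peaks: Sequence[Peak],
    genome,
    motif_models: Sequence[MotifModel],
    window: str = "whole-peak",
    summit_radius: int = 100,
    background: np.ndarray | None = None,
    pseudocount_fraction: float = 0.01,
    threshold_pvalue: float = 1e-4,
    collect_hits: list | None = None,
) -> HitMatrix:
    """Scan every peak window with every motif into an occupancy matrix.

    ``window`` is "whole-peak" or "summit" (summit +- summit_radius, clipped
    to the peak and to chromosome ends; peaks without a summit fall back to
    the interval midpoint). Motifs without a scoring model are scored here,
    against ``background`` if given and otherwise against a 0-order
    background estimated from the scanned sequences themselves. Peaks on
    chromosomes absent from the genome are dropped with a warning. If
    ``collect_hits`` is a list, (peak_key, motif_id, offset, strand, score)
    tuples are appended to it; offsets are genome coordinates.
    """
    if window not in ("whole-peak", "summit"):
        raise ValueError(f"unknown window mode {window!r}")
    fa = _open_genome(genome)

    kept: list[Peak] = []
    seqs: list[str] = []
    starts: list[int] = []
    for p in peaks:
        iv = p.interval
        if window == "summit":
            center = iv.start + (p.summit if p.summit is not None else iv.length // 2)
            lo = max(iv.start, center - summit_radius)
            hi = min(iv.end, center + summit_radius)
        else:
            lo, hi = iv.start, iv.end
        seq = _fetch_sequence(fa, iv.chrom, lo, hi)
        if seq is None:
            logger.warning("dropping peak %s: chromosome not in genome", p.key)
            continue
        kept.append(p)
        seqs.append(seq)
        starts.append(lo)

    scored: list[MotifModel] = []
    bg = None
    for m in motif_models:
        if m.is_scored:
            scored.append(m)
            continue
        if bg is None:
            bg = (
                _validate_background(background)
                if background is not None
                else estimate_background(seqs)
            )
        scored.append(
            build_scoring(
                m,
                background=bg,
                pseudocount_fraction=pseudocount_fraction,
                threshold_pvalue=threshold_pvalue,
            )
        )

    occ = np.zeros((len(kept), len(scored)), dtype=np.int64)
    for j, m in enumerate(scored):
        for i, (p, seq) in enumerate(zip(kept, seqs)):
            hits = scan_sequence(seq, m)
            occ[i, j] = len(hits)
            if collect_hits is not None:
                for o, strand, score in hits:
                    collect_hits.append(
                        (p.key, m.motif_id, starts[i] + o, strand, score)
                    )
    return HitMatrix(
        peak_index=[p.key for p in kept],
        motif_index=[m.motif_id for m in scored],
        occupancy=occ,
    )


def hits_from_intervals(
    peaks: Sequence[Peak], sites: Sequence[GenomicInterval], label: str
) -> HitMatrix:
    """Single-column hit matrix from externally supplied binding sites.

    occupancy(p) counts the site intervals overlapping peak p by >=1 bp
    (half-open). Used to plug in e.g. a TF's own ChIP-seq peaks in place of
    motif scanning.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
    prepared: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        starts = np.sort(np.array([s for s, _ in ivs], dtype=np.int64))
        ends = np.sort(np.array([e for _, e in ivs], dtype=np.int64))
        prepared[chrom] = (starts, ends)

    occ = np.zeros((len(peaks), 1), dtype=np.int64)
    for i, p in enumerate(peaks):
        got = prepared.get(p.interval.chrom)
        if got is None:
            continue
        starts, ends = got
        # sites with start < peak.end, minus sites with end <= peak.start
        n_start = np.searchsorted(starts, p.interval.end, side="left")
        n_gone = np.searchsorted(ends, p.interval.start, side="right")
        occ[i, 0] = n_start - n_gone
    return HitMatrix(
        peak_index=[p.key for p in peaks], motif_index=[label], occupancy=occ
    )
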