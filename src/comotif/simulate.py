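"""Synthetic genomes, peaks, reads and motifs for end-to-end testing.

The generator is the inverse model of the pipeline's assumptions: two
samples share a set of common peaks whose underlying binding intensity is
identical up to a global depth ratio; a chosen fraction of common peaks
("carriers") additionally get their sample-1 intensity multiplied by
2**planted_m_shift, and a planted motif's consensus is written into the
genome at their centers. Read counts are Poisson (or negative-binomial)
around the per-peak intensity, and reads are placed so that the counting
convention (extension-shifted midpoint, default 100 bp fragments) recovers
them. Every draw flows from a single integer seed; identical configs
produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .genomic import (
    GeneAnnotation,
    GenomicInterval,
    write_bed,
    write_gene_annotation,
)
from .motifs import ALPHABET, HitMatrix, MotifModel, write_jaspar

__all__ = [
    "SimConfig",
    "SimulatedData",
    "simulate_genome",
    "write_genome_fasta",
    "simulate_peaks_and_reads",
    "end_to_end_fixture",
    "make_planted_motif",
    "make_decoy_motif",
    "planted_association_instance",
]

READ_LENGTH = 36
FRAGMENT_SIZE = 100  # matches the default counting extension
PEAK_MARGIN = 500  # keep peaks away from chromosome ends
INTENSITY_SIGMA_LOG2 = 0.5  # log-normal spread of per-peak binding strength


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study; defaults are the standard conditions.

    ``depth_ratio`` multiplies sample 2's intensity globally (pure
    technical bias the normalization must remove); ``planted_m_shift`` is a
    genuine biological log2 effect confined to carrier peaks.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 200_000
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_common: int = 500
    n_unique_1: int = 50
    n_unique_2: int = 50
    peak_width: int = 300
    depth_ratio: float = 1.0
    mean_reads: float = 100.0
    planted_fraction: float = 0.2
    planted_m_shift: float = 0.8
    count_noise: str = "poisson"  # or "negative-binomial"
    nb_dispersion: float = 0.1
    background_read_fraction: float = 0.1
    n_decoy_motifs: int = 20
    tss_in_peak_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.planted_fraction <= 1.0):
            raise ValueError("planted_fraction must be in [0, 1]")
        if self.depth_ratio <= 0:
            raise ValueError("depth_ratio must be > 0")
        if min(self.n_common, self.n_unique_1, self.n_unique_2) < 0:
            raise ValueError("peak counts must be >= 0")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ValueError("background must be 4 probabilities summing to 1")
        if self.count_noise not in ("poisson", "negative-binomial"):
            raise ValueError(f"unknown count_noise {self.count_noise!r}")


@dataclass
class SimulatedData:
    """In-memory bundle produced by :func:`simulate_peaks_and_reads`."""

    genome: dict[str, np.ndarray]  # chrom -> uint8 base codes (mutated by planting)
    peaks_1: list[GenomicInterval]
    peaks_2: list[GenomicInterval]
    reads_1: list[GenomicInterval]
    reads_2: list[GenomicInterval]
    truth: pd.DataFrame
    planted_motif: MotifModel | None


def _decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def simulate_genome(config: SimConfig) -> dict[str, np.ndarray]:
    """i.i.d. background-composition chromosomes as uint8 code arrays."""
    rng = np.random.default_rng(config.seed)
    return {
        f"chr{i + 1}": rng.choice(
            4, size=config.chromosome_length, p=np.asarray(config.background)
        ).astype(np.uint8)
        for i in range(config.n_chromosomes)
    }


def write_genome_fasta(genome: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = _decode(genome[chrom])
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def make_planted_motif(
    rng: np.random.Generator, width: int = 12, motif_id: str = "PLANTED.1"
) -> MotifModel:
    """A strongly informative motif (consensus base count 85/100)."""
    consensus = rng.integers(0, 4, size=width)
    pfm = np.full((width, 4), 5.0)
    pfm[np.arange(width), consensus] = 85.0
    return MotifModel(motif_id=motif_id, name="planted", pfm=pfm)


def make_decoy_motif(rng: np.random.Generator, index: int, width: int = 8) -> MotifModel:
    """A random decoy PFM with roughly 1 bit of information per position."""
    dominant = rng.integers(0, 4, size=width)
    pfm = np.full((width, 4), 100.0 * 0.2 / 3.0)
    pfm[np.arange(width), dominant] = 80.0
    return MotifModel(motif_id=f"DECOY.{index}", name=f"decoy{index}", pfm=pfm)


def _draw_counts(
    rng: np.random.Generator, lam: np.ndarray, config: SimConfig
) -> np.ndarray:
    if config.count_noise == "poisson":
        return rng.poisson(lam)
    # NB with Var = mu + dispersion * mu^2, parameterized via gamma-Poisson
    r = 1.0 / config.nb_dispersion
    return rng.poisson(rng.gamma(shape=r, scale=lam / r))


def _place_reads(
    rng: np.random.Generator,
    chrom: str,
    start: int,
    end: int,
    n: int,
    chrom_len: int,
) -> list[GenomicInterval]:
    """Reads whose FRAGMENT_SIZE-extended midpoints are uniform in [start, end)."""
    reads = []
    centers = rng.integers(start, end, size=n)
    strands = rng.integers(0, 2, size=n)
    half = FRAGMENT_SIZE // 2
    for c, s in zip(centers, strands):
        if s == 0:
            lo = int(c) - half
            reads.append(
                GenomicInterval(chrom, max(lo, 0), max(lo, 0) + READ_LENGTH, "+")
            )
        else:
            hi = min(int(c) + half, chrom_len)
            hi = max(hi, READ_LENGTH)
            reads.append(GenomicInterval(chrom, hi - READ_LENGTH, hi, "-"))
    return reads


def simulate_peaks_and_reads(
    config: SimConfig, genome: dict[str, np.ndarray]
) -> SimulatedData:
    """Place peaks, plant the motif in carriers, and draw reads for both samples.

    Peaks are non-overlapping fixed-width intervals on a shuffled slot grid.
    Sample-1 intensity of a carrier peak is its baseline times
    2**planted_m_shift; sample 2 sees baseline times depth_ratio for every
    peak it covers. Unique peaks receive only background reads in the other
    sample. The truth table records origin, carrier status and the true M
    (log2 intensity ratio; defined for common peaks).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_total = config.n_common + config.n_unique_1 + config.n_unique_2

    slots: list[tuple[str, int]] = []
    step = config.peak_width + 50
    for chrom, arr in genome.items():
        for s in range(PEAK_MARGIN, len(arr) - PEAK_MARGIN - config.peak_width, step):
            slots.append((chrom, s))
    if n_total > len(slots):
        raise ValueError(
            f"requested {n_total} peaks exceed genome capacity of {len(slots)} slots"
        )
    order = rng.permutation(len(slots))[:n_total]
    chosen = [slots[i] for i in order]
    origins = (
        ["common"] * config.n_common
        + ["sample1-unique"] * config.n_unique_1
        + ["sample2-unique"] * config.n_unique_2
    )

    # carriers are drawn from every peak bound in sample 1 (common and
    # sample-1-unique): a co-factor of sample-1-biased binding co-occurs with
    # both fine-tuned and unique sample-1 peaks
    sample1_idx = np.arange(config.n_common + config.n_unique_1)
    n_carriers = int(round(config.planted_fraction * len(sample1_idx)))
    carrier_idx = set(
        rng.choice(sample1_idx, size=n_carriers, replace=False).tolist()
        if n_carriers
        else []
    )

    planted = make_planted_motif(rng) if n_carriers else None
    if planted is not None:
        cons = np.argmax(planted.pfm, axis=1).astype(np.uint8)
        for i in sorted(carrier_idx):
            chrom, s = chosen[i]
            mid = s + config.peak_width // 2 - planted.width // 2
            genome[chrom][mid : mid + planted.width] = cons

    lam_base = config.mean_reads * 2.0 ** rng.normal(
        0.0, INTENSITY_SIGMA_LOG2, size=n_total
    )
    peaks_1, peaks_2 = [], []
    reads_1, reads_2 = [], []
    rows = []
    lam1 = np.zeros(n_total)
    lam2 = np.zeros(n_total)
    for i, ((chrom, s), origin) in enumerate(zip(chosen, origins)):
        carrier = i in carrier_idx and origin != "sample2-unique"
        shift = 2.0**config.planted_m_shift if carrier else 1.0
        if origin in ("common", "sample1-unique"):
            lam1[i] = lam_base[i] * shift
        if origin in ("common", "sample2-unique"):
            lam2[i] = lam_base[i] * config.depth_ratio
        iv = GenomicInterval(chrom, s, s + config.peak_width)
        if origin in ("common", "sample1-unique"):
            peaks_1.append(iv)
        if origin in ("common", "sample2-unique"):
            peaks_2.append(iv)
        true_m = (
            np.log2(lam1[i] / lam2[i]) if origin == "common" else np.nan
        )
        rows.append(
            {
                "chrom": chrom,
                "start": s,
                "end": s + config.peak_width,
                "origin": origin,
                "carrier": carrier,
                "true_m": true_m,
            }
        )

    counts_1 = _draw_counts(rng, lam1, config)
    counts_2 = _draw_counts(rng, lam2, config)
    for i, (chrom, s) in enumerate(chosen):
        chrom_len = len(genome[chrom])
        if counts_1[i]:
            reads_1 += _place_reads(
                rng, chrom, s, s + config.peak_width, int(counts_1[i]), chrom_len
            )
        if counts_2[i]:
            reads_2 += _place_reads(
                rng, chrom, s, s + config.peak_width, int(counts_2[i]), chrom_len
            )

    # genome-wide background reads, depth-scaled in sample 2
    bg_rate = config.background_read_fraction * config.mean_reads / config.peak_width
    for chrom, arr in genome.items():
        n_bg1 = rng.poisson(bg_rate * len(arr))
        n_bg2 = rng.poisson(bg_rate * len(arr) * config.depth_ratio)
        reads_1 += _place_reads(rng, chrom, PEAK_MARGIN, len(arr) - PEAK_MARGIN, n_bg1, len(arr))
        reads_2 += _place_reads(rng, chrom, PEAK_MARGIN, len(arr) - PEAK_MARGIN, n_bg2, len(arr))

    truth = pd.DataFrame(rows).sort_values(["chrom", "start"], ignore_index=True)
    key = lambda iv: (iv.chrom, iv.start)
    return SimulatedData(
        genome=genome,
        peaks_1=sorted(peaks_1, key=key),
        peaks_2=sorted(peaks_2, key=key),
        reads_1=sorted(reads_1, key=key),
        reads_2=sorted(reads_2, key=key),
        truth=truth,
        planted_motif=planted,
    )


def end_to_end_fixture(config: SimConfig, outdir: str | Path) -> dict:
    """Write a complete input bundle and its expectation manifest.

    Files: genome.fa, peaks_1.bed / peaks_2.bed, reads_1.bed / reads_2.bed,
    motifs.jaspar (planted motif first, then decoys), genes.tsv (TSSs inside
    a fraction of sample-1 peaks plus intergenic ones), truth.tsv and
    manifest.json. Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    data = simulate_peaks_and_reads(config, genome)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    write_genome_fasta(data.genome, outdir / "genome.fa")
    write_bed(data.peaks_1, outdir / "peaks_1.bed")
    write_bed(data.peaks_2, outdir / "peaks_2.bed")
    write_bed(data.reads_1, outdir / "reads_1.bed")
    write_bed(data.reads_2, outdir / "reads_2.bed")

    motif_models = []
    if data.planted_motif is not None:
        motif_models.append(data.planted_motif)
    motif_models += [
        make_decoy_motif(rng, i) for i in range(config.n_decoy_motifs)
    ]
    write_jaspar(motif_models, outdir / "motifs.jaspar")

    genes: list[GeneAnnotation] = []
    gid = 0
    for iv in data.peaks_1:
        if rng.random() < config.tss_in_peak_fraction:
            gid += 1
            pos = iv.start + iv.length // 2 + 10
            genes.append(
                GeneAnnotation(
                    f"G{gid:05d}",
                    GenomicInterval(iv.chrom, pos, pos + 1),
                    "+" if rng.random() < 0.5 else "-",
                )
            )
    for chrom, arr in data.genome.items():
        for _ in range(25):
            gid += 1
            pos = int(rng.integers(PEAK_MARGIN, len(arr) - PEAK_MARGIN))
            genes.append(
                GeneAnnotation(
                    f"G{gid:05d}",
                    GenomicInterval(chrom, pos, pos + 1),
                    "+" if rng.random() < 0.5 else "-",
                )
            )
    write_gene_annotation(genes, outdir / "genes.tsv")
    data.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.6g")

    manifest = {
        "config": dataclasses.asdict(config),
        "planted_motif_id": (
            data.planted_motif.motif_id if data.planted_motif else None
        ),
        "expected_top_motif": (
            data.planted_motif.motif_id
            if data.planted_motif is not None and config.planted_m_shift != 0
            else None
        ),
        "n_genes": len(genes),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def planted_association_instance(
    seed: int,
    n_peaks: int = 2000,
    n_decoys: int = 100,
    planted_fraction: float = 0.2,
    m_shift: float = 0.8,
    decoy_rate: float = 0.1,
    noise_sigma: float = 1.0,
) -> tuple[np.ndarray, HitMatrix, str]:
    """Association-level fixture: M-values plus an occupancy matrix.

    One true motif occupies ``planted_fraction`` of the peaks and its
    carriers' M is shifted by ``m_shift``; decoys occupy peaks independently
    at ``decoy_rate``. Returns (m_values, hits, planted_motif_id). With
    ``m_shift=0`` the instance is an all-null screen.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    m = rng.normal(0.0, noise_sigma, size=n_peaks)
    occ = np.zeros((n_peaks, n_decoys + 1), dtype=np.int64)
    carriers = rng.random(n_peaks) < planted_fraction
    occ[carriers, 0] = 1
    m[carriers] += m_shift
    occ[:, 1:] = (rng.random((n_peaks, n_decoys)) < decoy_rate).astype(np.int64)
    hits = HitMatrix(
        peak_index=[f"peak{i}" for i in range(n_peaks)],
        motif_index=["PLANTED.1"] + [f"DECOY.{i}" for i in range(n_decoys)],
        occupancy=occ,
    )
    return m, hits, "PLANTED.1"
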