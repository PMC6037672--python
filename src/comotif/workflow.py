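"""Stage orchestration: normalization -> scanning -> association.

Functions here wire the module-level operations into the full comparison
workflow and own all file output. Tables are written atomically (temp file
+ rename) so a failed stage never leaves a truncated output behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Sequence

import numpy as np

from . import assoc, manorm, motifs
from .genomic import (
    BiasClass,
    Peak,
    PeakOrigin,
    count_reads_for_peaks,
    peaks_to_dataframe,
    read_bed,
    read_peaks,
)

__all__ = [
    "atomic_write",
    "manorm_stage",
    "write_manorm_outputs",
    "ma_plot",
    "run_full_pipeline",
]


@contextmanager
def atomic_write(path: str | Path):
    """Yield a temp path, renamed onto ``path`` only on success."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        yield Path(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_df(df, path: Path) -> None:
    with atomic_write(path) as tmp:
        df.to_csv(tmp, sep="\t", index=False, float_format="%.6g")


def manorm_stage(
    peaks_1: Sequence[Peak],
    peaks_2: Sequence[Peak],
    reads_1,
    reads_2,
    extension: int = 100,
    pseudocount: float = 1.0,
    m_cutoff: float = 1.0,
    p_cutoff: float = 0.01,
) -> manorm.NormalizationModel:
    """Run the full quantitative-comparison stage in place.

    Labels peak origins, counts reads, computes M/A, fits the common-peak
    trend on the common peaks of both samples pooled, normalizes all peaks,
    attaches per-peak P-values, and classifies bias.
    """
    peaks_1, peaks_2 = list(peaks_1), list(peaks_2)
    from .genomic import overlap_peaks

    overlap_peaks(peaks_1, peaks_2)
    for plist in (peaks_1, peaks_2):
        c1 = count_reads_for_peaks(plist, reads_1, extension)
        c2 = count_reads_for_peaks(plist, reads_2, extension)
        for p, a, b in zip(plist, c1, c2):
            p.read_count_1 = int(a)
            p.read_count_2 = int(b)
            p.m_value, p.a_value = manorm.compute_ma(int(a), int(b), pseudocount)
    common = [
        p for p in (*peaks_1, *peaks_2) if p.origin is PeakOrigin.COMMON
    ]
    model = manorm.fit_normalization(common)
    everything = [*peaks_1, *peaks_2]
    manorm.apply_normalization(everything, model)
    for p in everything:
        p.p_value = manorm.peak_pvalue(
            p.read_count_1, p.read_count_2, model, pseudocount
        )
    manorm.classify_bias(everything, m_cutoff, p_cutoff)
    return model


def write_manorm_outputs(
    peaks_1: Sequence[Peak],
    peaks_2: Sequence[Peak],
    model: manorm.NormalizationModel,
    outdir: str | Path,
) -> None:
    """Per-sample peak tables, a merged common-peak table, and a fit report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_df(peaks_to_dataframe(peaks_1), outdir / "sample1_peaks.tsv")
    _write_df(peaks_to_dataframe(peaks_2), outdir / "sample2_peaks.tsv")
    common = [
        p for p in (*peaks_1, *peaks_2) if p.origin is PeakOrigin.COMMON
    ]
    _write_df(peaks_to_dataframe(common), outdir / "common_peaks.tsv")
    classes = [p.bias_class.value for p in (*peaks_1, *peaks_2)]
    report = {
        "intercept_a": model.intercept_a,
        "slope_b": model.slope_b,
        "n_common": model.n_common,
        "iterations": model.iterations,
        "converged": model.converged,
        "n_sample1_biased": classes.count(BiasClass.SAMPLE1.value),
        "n_sample2_biased": classes.count(BiasClass.SAMPLE2.value),
        "n_unbiased": classes.count(BiasClass.UNBIASED.value),
    }
    with atomic_write(outdir / "normalization_report.json") as tmp:
        with open(tmp, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")


def ma_plot(peaks: Sequence[Peak], model, path: str | Path) -> None:
    """MA scatter before and after trend removal, with the fitted line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.array([p.a_value for p in peaks], dtype=float)
    m = np.array([p.m_value for p in peaks], dtype=float)
    mn = np.array([p.m_normalized for p in peaks], dtype=float)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, vals, title in zip(axes, (m, mn), ("raw", "normalized")):
        ax.scatter(a, vals, s=4, alpha=0.4, rasterized=True)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("A (mean log2 intensity)")
        ax.set_title(title)
    grid = np.linspace(a.min(), a.max(), 50)
    axes[0].plot(grid, model.trend(grid), color="red", lw=1)
    axes[0].set_ylabel("M (log2 ratio)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_full_pipeline(
    peaks1_path: str | Path,
    peaks2_path: str | Path,
    reads1_path: str | Path,
    reads2_path: str | Path,
    genome_path: str | Path,
    jaspar_path: str | Path,
    outdir: str | Path,
    peak_dialect: str = "bed",
    extension: int = 100,
    pseudocount: float = 1.0,
    m_cutoff: float = 1.0,
    p_cutoff: float = 0.01,
    threshold_pvalue: float = 1e-4,
    window: str = "whole-peak",
    summit_radius: int = 100,
    direction: str = "sample1",
    baseline: bool = False,
    genes_path: str | Path | None = None,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 2000,
    promoter_only: bool = False,
) -> dict:
    """Run normalization, scanning and association end to end.

    The association universe is sample 1's peaks (optionally restricted to
    those at promoters of ``genes_path``). Writes the stage tables plus
    ``motif_ranking.tsv`` (and ``baseline_enrichment.tsv`` when requested)
    under ``outdir``; returns a summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peaks_1 = read_peaks(peaks1_path, peak_dialect)
    peaks_2 = read_peaks(peaks2_path, peak_dialect)
    reads_1 = read_bed(reads1_path)
    reads_2 = read_bed(reads2_path)
    model = manorm_stage(
        peaks_1,
        peaks_2,
        reads_1,
        reads_2,
        extension=extension,
        pseudocount=pseudocount,
        m_cutoff=m_cutoff,
        p_cutoff=p_cutoff,
    )
    write_manorm_outputs(peaks_1, peaks_2, model, outdir)

    universe = list(peaks_1)
    if promoter_only:
        if genes_path is None:
            raise ValueError("promoter_only requires a gene annotation file")
        from .genomic import assign_to_promoters, read_gene_annotation

        genes = read_gene_annotation(genes_path)
        assigned = assign_to_promoters(
            universe, genes, promoter_upstream, promoter_downstream
        )
        keep = {p.key for plist in assigned.values() for p in plist}
        universe = [p for p in universe if p.key in keep]

    motif_models = motifs.read_jaspar(jaspar_path)
    hit_rows: list = []
    hits = motifs.build_hit_matrix(
        universe,
        genome_path,
        motif_models,
        window=window,
        summit_radius=summit_radius,
        threshold_pvalue=threshold_pvalue,
        collect_hits=hit_rows,
    )
    with atomic_write(outdir / "hit_matrix.tsv") as tmp:
        hits.write_tsv(tmp)
    import pandas as pd

    _write_df(
        pd.DataFrame(
            hit_rows, columns=["peak", "motif", "offset", "strand", "score"]
        ),
        outdir / "hits.tsv",
    )

    kept = {k: i for i, k in enumerate(hits.peak_index)}
    universe = [p for p in universe if p.key in kept]
    names = {m.motif_id: m.name for m in motif_models}
    records = assoc.run_all_motifs(universe, hits, direction=direction)
    for r in records:
        r.name = names.get(r.motif_id, "")
    ranking = assoc.records_to_dataframe(records)
    _write_df(ranking, outdir / "motif_ranking.tsv")

    summary = {
        "model": model,
        "ranking": ranking,
        "records": records,
        "n_peaks_tested": len(universe),
    }
    if baseline:
        biased_class = (
            BiasClass.SAMPLE1 if direction != "sample2" else BiasClass.SAMPLE2
        )
        other_class = (
            BiasClass.SAMPLE2 if direction != "sample2" else BiasClass.SAMPLE1
        )
        biased = [p for p in universe if p.bias_class is biased_class]
        other = [p for p in universe if p.bias_class is other_class]
        table = assoc.overlap_baseline(biased, other, hits)
        _write_df(table, outdir / "baseline_enrichment.tsv")
        summary["baseline"] = table
    return summary
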