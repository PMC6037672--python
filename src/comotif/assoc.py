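"""Motif - differential-binding association: the toolkit's core statistic.

For each motif, peaks are split into carriers (occupancy > 0) and
non-carriers, and the normalized M-values of the two groups are compared
with a Welch unequal-variance t test and a Wilcoxon rank-sum test, one-sided
in each direction. A motif whose carrier peaks have systematically higher
(or lower) normalized M than the rest is a candidate co-factor for
sample-1-biased (resp. sample-2-biased) binding. P-values are
Benjamini-Hochberg adjusted across motifs within each one-sided test
family, and motifs are ranked by the conservative combination
score = max(q_t, q_rank) on the requested side.

The module also provides the traditional overlap-based enrichment baseline
(Fisher exact test of motif presence in biased vs other peaks) and the
generic Fisher gene-set enrichment used for promoter/expression
integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic import Peak
from .motifs import HitMatrix

__all__ = [
    "AssociationRecord",
    "welch_t",
    "association_test",
    "run_all_motifs",
    "records_to_dataframe",
    "bh_adjust",
    "overlap_baseline",
    "gene_set_enrichment",
]


@dataclass
class AssociationRecord:
    """Per-motif association result (adjusted fields filled by the runner)."""

    motif_id: str
    name: str = ""
    n_hit: int = 0
    n_nohit: int = 0
    mean_m_hit: float = math.nan
    mean_m_nohit: float = math.nan
    t_statistic: float = math.nan
    p_t_right: float = 1.0
    p_t_left: float = 1.0
    p_rank_right: float = 1.0
    p_rank_left: float = 1.0
    q_t_right: float = math.nan
    q_t_left: float = math.nan
    q_rank_right: float = math.nan
    q_rank_left: float = math.nan
    score: float = math.nan
    direction: str = ""
    tests_available: bool = True


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t statistic with one-sided P-values (right, left).

    Degenerate inputs are resolved deterministically: zero pooled standard
    error gives t = 0 (P = 0.5 each side) when the means agree and
    t = +-inf (P = 0 or 1) when they differ.
    """
    n1, n2 = len(x), len(y)
    m1, m2 = float(np.mean(x)), float(np.mean(y))
    v1 = float(np.var(x, ddof=1)) if n1 > 1 else 0.0
    v2 = float(np.var(y, ddof=1)) if n2 > 1 else 0.0
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        if m1 == m2:
            return 0.0, 0.5, 0.5
        t = math.inf if m1 > m2 else -math.inf
        return t, (0.0 if t > 0 else 1.0), (1.0 if t > 0 else 0.0)
    t = (m1 - m2) / math.sqrt(se2)
    denom = 0.0
    if n1 > 1:
        denom += (v1 / n1) ** 2 / (n1 - 1)
    if n2 > 1:
        denom += (v2 / n2) ** 2 / (n2 - 1)
    df = se2**2 / denom if denom > 0 else float(n1 + n2 - 2)
    p_right = float(stats.t.sf(t, df))
    p_left = float(stats.t.cdf(t, df))
    return t, p_right, p_left


def association_test(
    m_values: Sequence[float],
    hit_flags: Sequence[bool],
    motif_id: str = "",
    compute_rank: bool = True,
) -> AssociationRecord:
    """Compare normalized M of motif-carrier vs non-carrier peaks.

    Welch t (needs >=2 peaks per group) and rank-sum (normal approximation
    with tie and continuity correction; needs >=1 per group), each one-sided
    in both directions. If all flags are identical the record is returned
    with ``tests_available=False`` and every P = 1.
    """
    m = np.asarray(m_values, dtype=float)
    flags = np.asarray(hit_flags, dtype=bool)
    if m.shape != flags.shape:
        raise ValueError("m_values and hit_flags must have equal length")
    x, y = m[flags], m[~flags]
    rec = AssociationRecord(motif_id=motif_id, n_hit=len(x), n_nohit=len(y))
    rec.mean_m_hit = float(np.mean(x)) if len(x) else math.nan
    rec.mean_m_nohit = float(np.mean(y)) if len(y) else math.nan
    if len(x) == 0 or len(y) == 0:
        rec.tests_available = False
        return rec
    if len(x) >= 2 and len(y) >= 2:
        rec.t_statistic, rec.p_t_right, rec.p_t_left = welch_t(x, y)
    else:
        rec.tests_available = False
    if compute_rank:
        rec.p_rank_right = float(
            stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue
        )
        rec.p_rank_left = float(
            stats.mannwhitneyu(x, y, alternative="less", method="asymptotic").pvalue
        )
    return rec


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_all_motifs(
    peaks: Sequence[Peak] | np.ndarray,
    hits: HitMatrix,
    direction: str = "sample1",
) -> list[AssociationRecord]:
    """Test every motif column, BH-adjust per family, rank by score.

    ``peaks`` may be a list of normalized Peak objects aligned with
    ``hits.peak_index`` or a bare array of normalized M-values. Direction
    "sample1" ranks by right-sided tests (carriers with higher M),
    "sample2" by left-sided, "both" by the better of the two sides per
    motif. Ordering: score ascending, |t| descending, motif_id.
    """
    if direction not in ("sample1", "sample2", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if isinstance(peaks, np.ndarray) or (
        len(peaks) > 0 and not isinstance(peaks[0], Peak)
    ):
        m = np.asarray(peaks, dtype=float)
    else:
        for p in peaks:
            if p.m_normalized is None:
                raise ValueError(f"peak {p.key} lacks m_normalized")
        m = np.array([p.m_normalized for p in peaks], dtype=float)
    if len(m) != len(hits.peak_index):
        raise ValueError(
            f"peak count {len(m)} does not match hit matrix rows "
            f"{len(hits.peak_index)}"
        )

    binary = hits.binary
    records = [
        association_test(m, binary[:, j], motif_id=hits.motif_index[j])
        for j in range(len(hits.motif_index))
    ]
    if not records:
        return []
    for fam in ("p_t_right", "p_t_left", "p_rank_right", "p_rank_left"):
        q = bh_adjust([getattr(r, fam) for r in records])
        for r, qv in zip(records, q):
            setattr(r, "q" + fam[1:], float(qv))
    for r in records:
        score_right = max(r.q_t_right, r.q_rank_right)
        score_left = max(r.q_t_left, r.q_rank_left)
        if direction == "sample1":
            r.score, r.direction = score_right, "sample1"
        elif direction == "sample2":
            r.score, r.direction = score_left, "sample2"
        else:
            if score_right <= score_left:
                r.score, r.direction = score_right, "sample1"
            else:
                r.score, r.direction = score_left, "sample2"
    records.sort(key=lambda r: (r.score, -abs_or_zero(r.t_statistic), r.motif_id))
    return records


def abs_or_zero(x: float) -> float:
    return abs(x) if math.isfinite(x) else (math.inf if x == x else 0.0)


_RANK_COLUMNS = [
    "motif_id",
    "name",
    "n_hit",
    "n_nohit",
    "mean_m_hit",
    "mean_m_nohit",
    "t_statistic",
    "p_t",
    "q_t",
    "p_rank",
    "q_rank",
    "score",
    "direction",
]


def records_to_dataframe(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Ranked table with the reported side's P/q columns."""
    rows = []
    for r in records:
        right = r.direction != "sample2"
        rows.append(
            {
                "motif_id": r.motif_id,
                "name": r.name,
                "n_hit": r.n_hit,
                "n_nohit": r.n_nohit,
                "mean_m_hit": r.mean_m_hit,
                "mean_m_nohit": r.mean_m_nohit,
                "t_statistic": r.t_statistic,
                "p_t": r.p_t_right if right else r.p_t_left,
                "q_t": r.q_t_right if right else r.q_t_left,
                "p_rank": r.p_rank_right if right else r.p_rank_left,
                "q_rank": r.q_rank_right if right else r.q_rank_left,
                "score": r.score,
                "direction": r.direction,
            }
        )
    return pd.DataFrame(rows, columns=_RANK_COLUMNS)


def overlap_baseline(
    peaks_biased: Sequence[Peak],
    peaks_other: Sequence[Peak],
    hits: HitMatrix,
) -> pd.DataFrame:
    """Traditional enrichment baseline: motif presence in biased vs other peaks.

    Per motif, a 2x2 table of (biased vs other) x (carrier vs non-carrier)
    is tested one-sided (over-representation among the biased peaks) with
    Fisher's exact test; the odds ratio uses a +0.5 Haldane correction when
    any cell is zero. P-values are BH-adjusted across motifs. An empty
    biased set yields all P = 1 with the table flagged unavailable.
    """
    occ_biased = hits.rows_for([p.key for p in peaks_biased]) > 0
    occ_other = hits.rows_for([p.key for p in peaks_other]) > 0
    rows = []
    for j, motif_id in enumerate(hits.motif_index):
        a = int(occ_biased[:, j].sum())
        b = int(len(peaks_biased) - a)
        c = int(occ_other[:, j].sum())
        d = int(len(peaks_other) - c)
        if len(peaks_biased) == 0:
            p = 1.0
            oddsratio = math.nan
            available = False
        else:
            p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
            if min(a, b, c, d) == 0:
                oddsratio = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            else:
                oddsratio = (a * d) / (b * c)
            available = True
        rows.append(
            {
                "motif_id": motif_id,
                "n_biased_hit": a,
                "n_biased_nohit": b,
                "n_other_hit": c,
                "n_other_nohit": d,
                "odds_ratio": oddsratio,
                "fisher_p": p,
                "available": available,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["fisher_p"].to_numpy()) if len(df) else []
    return df.sort_values(
        ["fisher_p", "motif_id"], ignore_index=True, kind="mergesort"
    )


def gene_set_enrichment(
    target_genes: set[str],
    reference_genes: set[str],
    background_genes: set[str],
) -> tuple[int, float, float]:
    """Two-sided Fisher exact enrichment of target against reference genes.

    Both sets must be subsets of the background universe. Returns
    (overlap_count, fold_enrichment, two_sided_p) where fold_enrichment is
    the observed overlap fraction of the target relative to the reference's
    background rate.
    """
    background = set(background_genes)
    if not background:
        raise ValueError("background gene set is empty")
    target = set(target_genes)
    reference = set(reference_genes)
    stray_t = target - background
    stray_r = reference - background
    if stray_t or stray_r:
        raise ValueError(
            "genes outside background: "
            f"target={sorted(stray_t)[:5]}, reference={sorted(stray_r)[:5]}"
        )
    n_b, n_t, n_r = len(background), len(target), len(reference)
    overlap = len(target & reference)
    table = [
        [overlap, n_t - overlap],
        [n_r - overlap, n_b - n_t - n_r + overlap],
    ]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if n_t == 0 or n_r == 0:
        fold = math.nan
    else:
        fold = (overlap / n_t) / (n_r / n_b)
    return overlap, fold, p
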