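"""MA-transform normalization of two ChIP-seq samples of the same protein.

The model: for a peak with raw read counts (c1, c2) in the two samples,
M = log2((c1+p)/(c2+p)) and A = 0.5*log2((c1+p)(c2+p)). Peaks common to both
samples are assumed to be, on average, equally bound, so any systematic
linear trend of M against A over the common peaks reflects technical bias
(sequencing depth, IP efficiency). That trend M = a + b*A is fitted by
Huber-weighted iteratively reweighted least squares on the common peaks and
subtracted from every peak of both samples, re-centering common peaks at
M = 0. A per-peak two-sided binomial test on the depth-rescaled counts then
scores each peak's differential binding, and peaks passing both an |M|
cutoff and a significance cutoff are classed as biased toward one sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genomic import BiasClass, Peak

__all__ = [
    "NormalizationModel",
    "DegenerateFitError",
    "compute_ma",
    "fit_normalization",
    "apply_normalization",
    "peak_pvalue",
    "classify_bias",
    "IDENTITY_MODEL",
]

HUBER_C = 1.345
MAX_ITER = 50
COEF_TOL = 1e-8


class DegenerateFitError(ValueError):
    """Raised when the common-peak regression cannot be fitted."""


@dataclass(frozen=True)
class NormalizationModel:
    """Fitted linear M-A trend: M_trend(A) = intercept_a + slope_b * A."""

    intercept_a: float
    slope_b: float
    n_common: int
    iterations: int
    converged: bool

    def trend(self, a_value: float | np.ndarray) -> float | np.ndarray:
        return self.intercept_a + self.slope_b * np.asarray(a_value, dtype=float)


#: Convenience no-op model (no depth bias), mainly for tests and single-sample use.
IDENTITY_MODEL = NormalizationModel(0.0, 0.0, n_common=0, iterations=0, converged=True)


def compute_ma(
    count_1: int, count_2: int, pseudocount: float = 1.0
) -> tuple[float, float]:
    """MA transform of a raw count pair.

    M is the log2 intensity ratio (positive = higher in sample 1), A the
    average log2 intensity. The pseudocount keeps both finite at zero counts.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if count_1 < 0 or count_2 < 0:
        raise ValueError("counts must be non-negative")
    x1 = count_1 + pseudocount
    x2 = count_2 + pseudocount
    return math.log2(x1 / x2), 0.5 * math.log2(x1 * x2)


def _mad_scale(residuals: np.ndarray) -> float:
    """Robust residual scale: median absolute deviation / 0.6745."""
    med = np.median(residuals)
    return float(np.median(np.abs(residuals - med)) / 0.6745)


def fit_normalization(common_peaks: Sequence[Peak]) -> NormalizationModel:
    """Fit M = a + b*A on common peaks by Huber IRLS.

    Huber weights with tuning constant 1.345 (95% Gaussian efficiency),
    MAD residual scale, at most 50 iterations, convergence when the max
    coefficient change drops below 1e-8. Requires >=2 common peaks with
    distinct A values.
    """
    a_vals = np.array([p.a_value for p in common_peaks], dtype=float)
    m_vals = np.array([p.m_value for p in common_peaks], dtype=float)
    if a_vals.size < 2:
        raise DegenerateFitError("degenerate fit: fewer than 2 common peaks")
    if np.ptp(a_vals) == 0:
        raise DegenerateFitError("degenerate fit: all A values identical")

    X = np.column_stack([np.ones_like(a_vals), a_vals])
    beta, *_ = np.linalg.lstsq(X, m_vals, rcond=None)
    converged = False
    iterations = 0
    for iterations in range(1, MAX_ITER + 1):
        resid = m_vals - X @ beta
        scale = _mad_scale(resid)
        if scale < 1e-12:
            # perfect (or constant-residual) fit; nothing left to reweight
            converged = True
            break
        u = np.abs(resid / scale)
        w = np.where(u <= HUBER_C, 1.0, HUBER_C / u)
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], m_vals * sw, rcond=None)
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if delta < COEF_TOL:
            converged = True
            break
    return NormalizationModel(
        intercept_a=float(beta[0]),
        slope_b=float(beta[1]),
        n_common=int(a_vals.size),
        iterations=iterations,
        converged=converged,
    )


def apply_normalization(
    peaks: Sequence[Peak], model: NormalizationModel
) -> list[Peak]:
    """Set ``m_normalized = m - (a + b*A)`` on every peak (common and unique)."""
    for p in peaks:
        if p.m_value is None or p.a_value is None:
            raise ValueError(f"peak {p.key} lacks M/A values")
        p.m_normalized = p.m_value - float(model.trend(p.a_value))
    return list(peaks)


def peak_pvalue(
    count_1: int,
    count_2: int,
    model: NormalizationModel,
    pseudocount: float = 1.0,
) -> float:
    """Two-sided binomial tail P-value for differential binding of one peak.

    Sample 2's count is rescaled toward sample 1 by the fitted trend,
    c2' = round(c2 * 2**(a + b*A)) (round-half-to-even), and the pair
    (c1, c2') is tested against Binomial(n = c1 + c2', p = 1/2):
    P = min(1, 2 * P(X >= max(c1, c2'))). n = 0 returns 1.
    """
    if count_1 < 0 or count_2 < 0:
        raise ValueError("counts must be non-negative")
    _, a_value = compute_ma(count_1, count_2, pseudocount)
    c2_rescaled = int(round(count_2 * 2.0 ** float(model.trend(a_value))))
    n = count_1 + c2_rescaled
    if n == 0:
        return 1.0
    k = max(count_1, c2_rescaled)
    # P(X >= k) under Binomial(n, 1/2)
    tail = float(stats.binom.sf(k - 1, n, 0.5))
    return min(1.0, 2.0 * tail)


def classify_bias(
    peaks: Sequence[Peak], m_cutoff: float = 1.0, p_cutoff: float = 0.01
) -> list[Peak]:
    """Partition peaks into sample1-biased / sample2-biased / unbiased.

    A peak is biased toward sample 1 iff m_normalized >= m_cutoff and
    p_value <= p_cutoff (mirrored for sample 2); everything else is
    unbiased. Boundary values are inclusive.
    """
    if m_cutoff <= 0:
        raise ValueError("m_cutoff must be > 0")
    if not (0.0 < p_cutoff < 1.0):
        raise ValueError("p_cutoff must be in (0, 1)")
    for p in peaks:
        if p.m_normalized is None or p.p_value is None:
            raise ValueError(f"peak {p.key} lacks m_normalized/p_value")
        if p.m_normalized >= m_cutoff and p.p_value <= p_cutoff:
            p.bias_class = BiasClass.SAMPLE1
        elif p.m_normalized <= -m_cutoff and p.p_value <= p_cutoff:
            p.bias_class = BiasClass.SAMPLE2
        else:
            p.bias_class = BiasClass.UNBIASED
    return list(peaks)
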