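"""Combine per-feature p-values of a gene into a single gene-level p-value.

Testing differential expression at a sub-gene level (exons, transcripts,
equivalence classes) yields several p-values per gene that must be reduced to
one.  Four combiners are provided:

* :func:`fisher_combine` — Fisher's method, ``T = Σ −2 ln p_i ~ χ²_{2K}``,
  valid for independent p-values.
* :func:`lancaster_combine` — Lancaster's weighted generalisation: each p_i is
  converted to a chi-square deviate with ``w_i`` degrees of freedom and the sum
  is referred to ``χ²_{Σ w_i}``.  Weights of 2 recover Fisher exactly.
* :func:`brown_combine` — Brown's dependence correction: the Fisher statistic
  is referred to a rescaled chi-square ``c·χ²_f`` whose scale ``c`` and degrees
  of freedom ``f`` are derived from the covariance of the ``−2 ln p`` variables
  (:func:`brown_correction`).
* :func:`empirical_brown_combine` — empirical Brown's method (EBM): the
  covariance is estimated nonparametrically from the per-feature data matrix,
  so no distributional model of the dependence is needed.

Exon counts of one gene are strongly positively correlated, which makes
Fisher/Lancaster anti-conservative there; Brown-type combiners absorb that
dependence into the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AggregationResult",
    "BrownCorrection",
    "fisher_combine",
    "lancaster_combine",
    "brown_correction",
    "brown_combine",
    "empirical_brown_combine",
]

#: p-values below this are clamped before taking logs or quantiles so the
#: Fisher statistic stays finite; p = 1 is kept (contributes 0).
P_FLOOR = 1e-300


@dataclass(frozen=True)
class BrownCorrection:
    """Rescaled chi-square null ``c·χ²_f`` for a sum of dependent −2 ln p terms.

    Under independence ``c = 1`` and ``f = 2K``, which reduces Brown's method
    to Fisher's.
    """

    c: float
    f: float

    def __post_init__(self) -> None:
        if not (self.c > 0 and self.f > 0):
            raise ValueError("degenerate covariance: c and f must be positive")


@dataclass(frozen=True)
class AggregationResult:
    """Outcome of one p-value combination.

    ``statistic`` is the chi-square-type sum, ``dof`` the degrees of freedom of
    the reference distribution, ``scale`` the Brown scale factor (1 for
    Fisher/Lancaster) and ``p_combined`` the gene-level p-value.
    """

    statistic: float
    dof: float
    scale: float
    p_combined: float
    method: str


def _validate_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("no features: empty p-value vector")
    if np.any(~np.isfinite(p)):
        raise ValueError("p-values must be finite")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return np.clip(p, P_FLOOR, 1.0)


def fisher_combine(p) -> AggregationResult:
    """Fisher's method for K independent p-values.

    ``statistic = Σ −2 ln p_i`` is referred to the upper tail of a chi-square
    with ``2K`` degrees of freedom.  A single p-value is returned unchanged.
    """
    p = _validate_p(p)
    k = p.size
    statistic = float(np.sum(-2.0 * np.log(p)))
    if k == 1:
        p_comb = float(p[0])
    else:
        p_comb = float(stats.chi2.sf(statistic, 2 * k))
    return AggregationResult(statistic, float(2 * k), 1.0, p_comb, "fisher")


def lancaster_combine(p, weights) -> AggregationResult:
    """Lancaster's weighted combination.

    Each p_i is mapped to the upper-tail chi-square quantile with ``w_i``
    degrees of freedom; the sum follows a chi-square with ``Σ w_i`` degrees of
    freedom under independence.  ``w_i = 2`` for all i recovers Fisher's method
    because the 2-dof upper-tail quantile of p is exactly ``−2 ln p``.
    """
    p = _validate_p(p)
    w = np.asarray(weights, dtype=float).ravel()
    if w.size != p.size:
        raise ValueError(
            f"weights length {w.size} does not match p-value length {p.size}"
        )
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be positive and finite")
    statistic = float(np.sum(stats.chi2.isf(p, w)))
    dof = float(np.sum(w))
    if p.size == 1:
        p_comb = float(p[0])
    else:
        p_comb = float(stats.chi2.sf(statistic, dof))
    return AggregationResult(statistic, dof, 1.0, p_comb, "lancaster")


def brown_correction(cov) -> BrownCorrection:
    """Scale factor and degrees of freedom of Brown's rescaled chi-square null.

    ``cov`` is the K×K covariance matrix of the ``−2 ln p_i`` variables.  The
    marginal variance of each term is fixed at its theoretical value 4
    (chi-square with 2 dof); only the off-diagonal entries of ``cov`` are used.
    With ``E = 2K`` and ``Var = 4K + 2 Σ_{i<j} cov_ij``::

        f = 2 E² / Var        c = Var / (2 E)

    so zero off-diagonals give ``(c, f) = (1, 2K)`` exactly.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(cov, cov.T, atol=1e-8, rtol=1e-6):
        raise ValueError("covariance must be symmetric")
    if np.any(np.diag(cov) <= 0):
        raise ValueError("covariance diagonal must be positive")
    k = cov.shape[0]
    off_sum = float(np.sum(np.triu(cov, 1)))
    expect = 2.0 * k
    var = 4.0 * k + 2.0 * off_sum
    if var <= 0:
        raise ValueError("degenerate covariance: total variance is nonpositive")
    f = 2.0 * expect**2 / var
    c = var / (2.0 * expect)
    return BrownCorrection(c=c, f=f)


def brown_combine(p, correction: BrownCorrection) -> AggregationResult:
    """Brown's method: Fisher's statistic against the rescaled null ``c·χ²_f``.

    With ``correction = (c=1, f=2K)`` this is identical to
    :func:`fisher_combine`.  A single p-value is returned unchanged.
    """
    p = _validate_p(p)
    statistic = float(np.sum(-2.0 * np.log(p)))
    if p.size == 1:
        p_comb = float(p[0])
    else:
        p_comb = float(stats.chi2.sf(statistic / correction.c, correction.f))
    return AggregationResult(
        statistic, float(correction.f), float(correction.c), p_comb, "brown"
    )


def _ecdf_fisher_transform(row: np.ndarray) -> np.ndarray:
    # Empirical Fisher variable of one feature row: -2 ln of the right-
    # continuous ECDF, rank(x)/S in (0, 1] ('max' ranks handle ties), so the
    # transform never overflows: the smallest value maps to -2 ln(1/S).
    s = row.size
    u = stats.rankdata(row, method="max") / s
    return -2.0 * np.log(u)


def empirical_brown_combine(p, data) -> AggregationResult:
    """Empirical Brown's method: Brown with a data-estimated covariance.

    ``data`` is a K×S matrix, one row per feature (the normalized feature
    expression across the S samples).  Each row is rank-transformed to its
    empirical Fisher variable ``−2 ln ECDF(x)``; the sample covariance (S−1
    denominator) of the transformed rows supplies the off-diagonal entries for
    :func:`brown_correction`.  Constant rows carry no dependence information
    and contribute zero covariance.  If an adverse empirical covariance yields
    a nonpositive variance the correction falls back to the independence case
    ``(c=1, f=2K)`` with a warning.
    """
    p = _validate_p(p)
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a K×S matrix")
    k = p.size
    if data.shape[0] != k:
        raise ValueError(
            f"data has {data.shape[0]} rows but {k} p-values were given"
        )
    if k == 1:
        return AggregationResult(
            float(-2.0 * np.log(p[0])), 2.0, 1.0, float(p[0]), "ebm"
        )
    s = data.shape[1]
    if s < 2:
        raise ValueError("at least 2 samples are required to estimate covariance")

    transformed = np.apply_along_axis(_ecdf_fisher_transform, 1, data)
    constant = np.ptp(data, axis=1) == 0
    cov = np.cov(transformed, ddof=1)
    cov[constant, :] = 0.0
    cov[:, constant] = 0.0
    np.fill_diagonal(cov, 4.0)

    off_sum = float(np.sum(np.triu(cov, 1)))
    var = 4.0 * k + 2.0 * off_sum
    if var <= 0:
        warnings.warn(
            "empirical covariance degenerate; falling back to independence "
            "(c=1, f=2K)",
            RuntimeWarning,
            stacklevel=2,
        )
        corr = BrownCorrection(c=1.0, f=2.0 * k)
    else:
        corr = brown_correction(cov)
    result = brown_combine(p, corr)
    return AggregationResult(
        result.statistic, result.dof, result.scale, result.p_combined, "ebm"
    )
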