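"""Shared statistical primitives.

Vectorised two-group count tests, Benjamini–Hochberg adjustment and
percentage formatting used across the tiling, merging and context modules.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps
from scipy.special import xlogy


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped to 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    m = p.size
    if m == 0:
        return np.empty(0, dtype=float)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def gtest_pooled(
    m1: np.ndarray, n1: np.ndarray, m2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood-ratio (G) test of equal methylation proportion, vectorised.

    Equivalent to the likelihood-ratio test of a binomial logistic
    regression with group as the only covariate: the fitted alternative
    collapses to the pooled per-group proportions, so per-sample counts
    enter only through their group totals.

    Returns ``(statistic, p)`` with p from chi-square with 1 df.
    Entries where either group has zero total coverage get NaN.
    """
    m1 = np.asarray(m1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    u1 = n1 - m1
    u2 = n2 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, m1 / n1, np.nan)
        p2 = np.where(n2 > 0, m2 / n2, np.nan)
        p0 = np.where(n1 + n2 > 0, (m1 + m2) / (n1 + n2), np.nan)
        ll_alt = (xlogy(m1, p1) + xlogy(u1, 1 - p1)
                  + xlogy(m2, p2) + xlogy(u2, 1 - p2))
        ll_null = (xlogy(m1 + m2, p0) + xlogy(u1 + u2, 1 - p0))
    stat = 2.0 * (ll_alt - ll_null)
    stat = np.where(stat < 0, 0.0, stat)  # guard tiny negative round-off
    pval = sps.chi2.sf(stat, df=1)
    bad = (n1 <= 0) | (n2 <= 0)
    stat = np.where(bad, np.nan, stat)
    pval = np.where(bad, np.nan, pval)
    return stat, pval


def estimate_common_dispersion(meth: np.ndarray, cov: np.ndarray,
                               is_control: np.ndarray) -> float:
    """Common overdispersion factor from within-group per-sample residuals.

    Per row (tile or CpG), the Pearson statistic of per-sample counts
    around the pooled group proportions, divided by its residual degrees of
    freedom (valid samples minus two groups), estimates the binomial
    variance-inflation factor; rows are averaged into one common factor,
    floored at 1.  Dividing the likelihood-ratio statistic by this factor
    is the common-dispersion variant of the McCullagh-Nelder correction.
    """
    meth = np.asarray(meth, dtype=float)
    cov = np.asarray(cov, dtype=float)
    is_control = np.asarray(is_control, dtype=bool)
    phis = []
    for group_mask in (is_control, ~is_control):
        m = meth[:, group_mask]
        n = cov[:, group_mask]
        tot = n.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(tot > 0, m.sum(axis=1) / np.maximum(tot, 1), np.nan)
            expect = n * p[:, None]
            var = n * (p * (1 - p))[:, None]
            terms = np.where(var > 0, (m - expect) ** 2 / np.where(var > 0, var, 1), 0.0)
        valid = (n > 0) & (var > 0)
        chi = terms.sum(axis=1)
        df = valid.sum(axis=1) - 1
        ok = df > 0
        if ok.any():
            phis.append(chi[ok].sum() / df[ok].sum())
    if not phis:
        return 1.0
    return float(max(1.0, np.mean(phis)))


def fisher_pooled(m1: int, n1: int, m2: int, n2: int) -> float:
    """Two-sided Fisher exact p on the pooled 2x2 (meth/unmeth x group)."""
    if n1 <= 0 or n2 <= 0:
        return float("nan")
    table = [[int(m1), int(n1 - m1)], [int(m2), int(n2 - m2)]]
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def fisher_pooled_many(m1, n1, m2, n2) -> np.ndarray:
    """Row-wise :func:`fisher_pooled` over parallel count arrays."""
    m1 = np.asarray(m1)
    n1 = np.asarray(n1)
    m2 = np.asarray(m2)
    n2 = np.asarray(n2)
    return np.array(
        [fisher_pooled(a, b, c, d) for a, b, c, d in zip(m1, n1, m2, n2)],
        dtype=float,
    )


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on [[a, b], [c, d]].

    Returns ``(statistic, p)``; degenerate margins give (0, 1).
    """
    a, b, c, d = (float(x) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0 or n == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(sps.chi2.sf(stat, df=1))


def proportion(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage of *numerator* in *denominator*, round-half-up.

    Operates on the 0-100 scale; ``decimals=0`` yields whole percents.
    Raises on a non-positive denominator.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    quantum = Decimal(1).scaleb(-decimals)
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def floor_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage truncated (floored) at *decimals* places.

    Used for intersection-fraction summaries, which report truncated
    percentages (892 of 3545 -> 25.1, not 25.2).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    scale = 10 ** decimals
    pct = Decimal(numerator) * 100 * scale / Decimal(denominator)
    return float(int(pct) / scale)
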