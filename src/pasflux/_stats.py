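"""Shared statistical primitives.

Row-vectorized Welch t-tests (with an exact label-permutation fallback for
degenerate zero-variance rows), Benjamini-Hochberg adjustment, and a
two-sided Fisher exact test computed by hypergeometric tail summation.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "welch_rows",
    "fisher_exact_two_sided",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment; NaNs pass through as NaN."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _exact_permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for the difference in means.

    Enumerates every relabeling of the pooled observations. Only used when
    both groups have exactly zero variance (Welch t is undefined there), so
    the enumeration is over at most a handful of replicates.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    obs = abs(x.mean() - y.mean())
    total = pooled.sum()
    count = 0
    labelings = list(combinations(range(len(pooled)), n1))
    for idx in labelings:
        m1 = pooled[list(idx)].mean()
        m2 = (total - pooled[list(idx)].sum()) / (len(pooled) - n1)
        if abs(m1 - m2) >= obs - 1e-12:
            count += 1
    return count / len(labelings)


def welch_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test applied independently to each row.

    Parameters
    ----------
    x, y : arrays of shape (n_rows, n1) and (n_rows, n2)
        Per-replicate observations for the two conditions.

    Returns
    -------
    p : array of shape (n_rows,)

    Degenerate rows (zero variance in both groups) get p = 1 when the means
    are equal, otherwise an exact permutation p over replicate labelings.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n1, n2 = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    se2 = vx / n1 + vy / n2
    p = np.ones(x.shape[0])
    regular = se2 > 0
    if regular.any():
        t = (mx[regular] - my[regular]) / np.sqrt(se2[regular])
        num = se2[regular] ** 2
        den = (vx[regular] / n1) ** 2 / (n1 - 1) + (vy[regular] / n2) ** 2 / (n2 - 1)
        df = num / den
        p[regular] = 2.0 * special.stdtr(df, -np.abs(t))
    degenerate = ~regular
    for i in np.nonzero(degenerate)[0]:
        if np.isclose(mx[i], my[i]):
            p[i] = 1.0
        else:
            p[i] = _exact_permutation_p(x[i], y[i])
    return p


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    The p-value sums hypergeometric point probabilities over all tables with
    the observed margins whose probability does not exceed that of the
    observed table (with a small relative tolerance for float ties), the
    classic two-sided definition. Returns ``(odds_ratio, p)``; the odds ratio
    uses the Haldane-Anscombe 0.5 correction when any cell is zero.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("contingency counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0, 1.0
    row1 = a + b
    col1 = a + c
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(1.0, p)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), p
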