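"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the peak oracle
enumerates every candidate window; the Fisher oracle sums the
hypergeometric pmf; the t-test oracle applies the textbook pooled-variance
formula.
"""

from math import comb, sqrt

import numpy as np
from scipy import stats


def oracle_peak_windows(mask, min_positive: int = 4, max_gaps: int = 1):
    """All maximal non-overlapping gap-tolerant runs, by window enumeration.

    Enumerates every window whose boundary positions are positive, with at
    most ``max_gaps`` interior non-positive positions and at least
    ``min_positive`` positives, then selects greedily by leftmost start
    (ties: longest), skipping overlaps.
    """
    mask = np.asarray(mask, dtype=bool)
    n = len(mask)
    cum = np.concatenate([[0], np.cumsum(mask)])  # prefix positives
    valid = []
    for i in range(n):
        if not mask[i]:
            continue
        for j in range(i, n):
            if not mask[j]:
                continue
            n_pos = int(cum[j + 1] - cum[i])
            gaps = (j - i + 1) - n_pos
            if gaps <= max_gaps and n_pos >= min_positive:
                valid.append((i, j, n_pos))
    valid.sort(key=lambda t: (t[0], -(t[1] - t[0])))
    chosen, last_end = [], -1
    for i, j, n_pos in valid:
        if i > last_end:
            chosen.append((i, j, n_pos))
            last_end = j
    return chosen


def oracle_percentile_95(values):
    """95th percentile by explicit sorted-order linear interpolation."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = 0.95 * (len(v) - 1)
    lo = int(np.floor(pos))
    frac = pos - lo
    if lo + 1 < len(v):
        return v[lo] + frac * (v[lo + 1] - v[lo])
    return v[lo]


def oracle_fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric summation."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row = a + b
    col = a + c

    def pmf(x: int) -> float:
        return comb(row, x) * comb(n - row, col - x) / comb(n, col)

    p_obs = pmf(a)
    lo = max(0, col - (n - row))
    hi = min(col, row)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


def oracle_pooled_t_pvalue(a, b) -> float:
    """Two-sided equal-variance two-sample t-test, textbook formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    return 2 * stats.t.sf(abs(t), df)
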