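"""Independent brute-force oracles used to validate the statistical layer.

These deliberately avoid the code paths (and where possible the library
routines) used by the implementation: ranks are computed by counting,
ECDFs by scanning, the t-test from the explicit pooled-variance formula
with only a numeric t CDF, and the moving average by a plain loop.
"""

import numpy as np
from scipy.special import stdtr


def average_ranks(x):
    """Average ranking with ties sharing the mean rank, by counting."""
    x = np.asarray(x, float)
    ranks = np.empty(len(x))
    for i, xi in enumerate(x):
        less = np.sum(x < xi)
        equal = np.sum(x == xi)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation of brute-force average ranks."""
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def ks_d_oracle(x, y):
    """Exhaustive ECDF-difference scan over every observed value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    best = 0.0
    for value in np.concatenate([x, y]):
        fx = np.mean(x <= value)
        fy = np.mean(y <= value)
        best = max(best, abs(fx - fy))
    return best


def pooled_ttest_oracle(a, b):
    """Two-sided pooled-variance t-test from the textbook formula.

    Returns (t, p) with df = n1 + n2 - 2; the t CDF is evaluated
    numerically via the regularized incomplete beta (scipy.special.stdtr).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    s_pooled = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / np.sqrt(s_pooled * (1 / n1 + 1 / n2))
    p = 2.0 * stdtr(df, -abs(t))
    return float(t), float(p)


def moving_average_oracle(values, window):
    """Centered shrinking-edge boxcar mean by explicit loop."""
    values = np.asarray(values, float)
    left = (window - 1) // 2
    right = window // 2
    out = np.empty_like(values)
    for i in range(len(values)):
        lo = max(0, i - left)
        hi = min(len(values), i + right + 1)
        out[i] = values[lo:hi].mean()
    return out
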