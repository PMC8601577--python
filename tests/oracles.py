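"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the package's own code paths: plain order
statistics, exhaustive threshold scans, explicit ANOVA sums and
hypergeometric enumeration.
"""

import numpy as np


def type7_quantile(values, p):
    """Linear interpolation between order statistics at h = (n-1)p."""
    xs = sorted(values)
    h = (len(xs) - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def brute_force_roc(nhi, pwa):
    """Exhaustive scan of every value +/- epsilon as a threshold for
    the rule "score <= threshold is positive"; ties broken toward the
    larger threshold.  Returns (sens+spec, threshold, sens, spec)."""
    candidates = set()
    for v in list(nhi) + list(pwa):
        candidates.update([v - 1e-9, v, v + 1e-9])
    candidates.update([-1e9, 1e9])
    best = None
    for t in sorted(candidates):
        sens = float(np.mean(np.asarray(pwa) <= t))
        spec = float(np.mean(np.asarray(nhi) > t))
        if best is None or sens + spec >= best[0] - 1e-12:
            if best is None or sens + spec > best[0] + 1e-12 or t > best[1]:
                best = (sens + spec, t, sens, spec)
    return best


def anova_icc_a1_oracle(x):
    """Brute-force two-way decomposition with explicit loops."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    from math import comb

    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total
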