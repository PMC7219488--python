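"""Independent brute-force oracles used by the tests.

Everything here is coded directly from textbook definitions with explicit
loops, deliberately sharing no code with the package implementation.
"""

import math

from scipy import stats


def anova_oracle(x):
    """Two-way one-observation-per-cell sums of squares by definition."""
    n = len(x)
    k = len(x[0])
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            ss_err += (x[i][j] - row_means[i] - col_means[j] + grand) ** 2
    return {
        "msr": ss_rows / (n - 1),
        "msc": ss_cols / (k - 1),
        "mse": ss_err / ((n - 1) * (k - 1)),
        "ss_rows": ss_rows,
        "ss_cols": ss_cols,
        "ss_err": ss_err,
    }


def icc_a1_oracle(x, alpha=0.05):
    """ICC(A,1) + F-based CI + SEM, step by step from the mean squares."""
    n = len(x)
    k = len(x[0])
    a = anova_oracle(x)
    msr, msc, mse = a["msr"], a["msc"], a["mse"]
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    sem = math.sqrt(mse)
    if mse == 0.0 and msc == 0.0:
        return icc, 1.0, 1.0, sem
    if 1.0 - icc <= 1e-12:
        return icc, icc, 1.0, sem
    ca = k * icc / (n * (1.0 - icc))
    cb = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
    den = (ca * msc) ** 2 / (k - 1) + (cb * mse) ** 2 / ((n - 1) * (k - 1))
    v = (ca * msc + cb * mse) ** 2 / den if den > 0 else 1.0
    v = max(v, 1.0)
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    mix = k * msc + (k * n - k - n) * mse
    lo = n * (msr - f_l * mse) / (f_l * mix + n * msr)
    hi = n * (f_u * msr - mse) / (mix + n * f_u * msr)
    return icc, min(lo, icc), max(hi, icc), sem
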