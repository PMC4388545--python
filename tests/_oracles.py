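"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: the ICC oracle
computes the two-way ANOVA sums of squares with explicit Python loops by
their definitions; the Spearman oracle assigns mid-ranks by hand and
applies the Pearson formula; the sine oracle scans an (a, c) lattice.
"""

import math
from itertools import permutations

import numpy as np


def icc_agreement_oracle(vals):
    """ICC(A,1) from by-definition ANOVA loops."""
    vals = np.asarray(vals, dtype=float)
    n, k = vals.shape
    grand = sum(vals[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(vals[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(vals[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sse = sum(
        (vals[i, j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def icc_consistency_oracle(vals):
    """Consistency-type ICC(C,1), insensitive to rater offsets."""
    vals = np.asarray(vals, dtype=float)
    n, k = vals.shape
    grand = vals.mean()
    row_means = vals.mean(axis=1)
    col_means = vals.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((vals - grand) ** 2).sum() - (n - 1) * msr - (k - 1) * msc
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


def midranks(x):
    """Average ranks with mid-ranks for ties, by explicit enumeration."""
    x = list(map(float, x))
    ranks = []
    for xi in x:
        less = sum(1 for xj in x if xj < xi)
        equal = sum(1 for xj in x if xj == xi)
        # ranks occupied by the tie group: less+1 .. less+equal, averaged
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def spearman_oracle(x, y):
    """Spearman rho: Pearson correlation of hand-assigned mid-ranks."""
    rx, ry = midranks(x), midranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def spearman_exact_p_oracle(x, y):
    """Two-sided exact permutation p-value for Spearman rho."""
    obs = abs(spearman_oracle(x, y))
    count = total = 0
    for perm in permutations(y):
        if abs(spearman_oracle(x, perm)) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def sine_grid_oracle(u, v, b, a_max, n_a=400, n_c=720):
    """Best (a, c) for fixed b over a brute-force lattice; returns (a, c, rss)."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    cs = np.linspace(0.0, 2 * np.pi, n_c, endpoint=False)
    sines = np.sin(b * u[None, :] - cs[:, None])  # (n_c, n)
    s_vv = float(v @ v)
    s_sv = sines @ v  # (n_c,)
    s_ss = np.einsum("ij,ij->i", sines, sines)
    a_grid = np.linspace(0.0, a_max, n_a)
    # rss(a, c) = v.v - 2 a (s.v) + a^2 (s.s)
    rss = s_vv - 2.0 * a_grid[None, :] * s_sv[:, None] + a_grid[None, :] ** 2 * s_ss[:, None]
    ci, ai = np.unravel_index(np.argmin(rss), rss.shape)
    return float(a_grid[ai]), float(cs[ci]), float(rss[ci, ai])
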