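"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written from the definitions, by direct enumeration,
with no code shared with the package.
"""

import itertools
import math

import numpy as np


def pi_pairwise(data):
    """θ_π by enumerating all C(n,2) haplotype pairs (mean pairwise differences)."""
    n = data.shape[0]
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += int(np.sum(data[i] != data[j]))
    return total / math.comb(n, 2)


def theta_w_direct(data):
    n = data.shape[0]
    counts = data.sum(axis=0)
    s = int(np.sum((counts > 0) & (counts < n)))
    return s / sum(1.0 / i for i in range(1, n))


def theta_h_direct(data):
    """θ_H from per-site derived counts: Σ 2 i² / (n(n−1))."""
    n = data.shape[0]
    counts = data.sum(axis=0)
    seg = counts[(counts > 0) & (counts < n)]
    return float(sum(2.0 * i * i for i in seg) / (n * (n - 1)))


def tajima_d_direct(data):
    n = data.shape[0]
    counts = data.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    s = int(seg.sum())
    if s == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = pi_pairwise(data[:, seg])
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def faywu_h_direct(data):
    n = data.shape[0]
    counts = data.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    if not seg.any():
        return float("nan")
    return pi_pairwise(data[:, seg]) - theta_h_direct(data)


def ld_direct(col_a, col_b):
    """D, D', r² from the 2×2 haplotype table by hand arithmetic."""
    n = len(col_a)
    p_a = sum(col_a) / n
    p_b = sum(col_b) / n
    p_ab = sum(1 for x, y in zip(col_a, col_b) if x == 1 and y == 1) / n
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = d / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return d, d_prime, r2


def vst_direct(x, y):
    """V_ST by hand: population (divide-by-n) variances on both sides."""
    pooled = list(x) + list(y)

    def var(v):
        m = sum(v) / len(v)
        return sum((u - m) ** 2 for u in v) / len(v)

    v_t = var(pooled)
    v_s = (len(x) * var(x) + len(y) * var(y)) / (len(x) + len(y))
    if v_t == 0:
        return v_t, v_s, 0.0
    return v_t, v_s, (v_t - v_s) / v_t


def random_segregating_matrix(rng, n_max=8, s_max=20):
    """Random small haplotype matrix with only segregating sites."""
    n = int(rng.integers(4, n_max + 1))
    s = int(rng.integers(1, s_max + 1))
    cols = []
    while len(cols) < s:
        col = rng.integers(0, 2, size=n)
        if 0 < col.sum() < n:
            cols.append(col)
    return np.array(cols, dtype=np.int8).T
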