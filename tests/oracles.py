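"""Independent brute-force oracles for the exact tests.

These enumerate outcomes directly with exact integer / rational
arithmetic (math.comb), sharing no code with the implementations they
check. Two-sided sums use the minimum-likelihood convention with the same
1e-7 relative tie tolerance the package documents.
"""

import math
from fractions import Fraction

import numpy as np

TIE_NUM = 10**7 + 1  # w_x <= w_a * (1 + 1e-7)  <=>  w_x * 10^7 <= w_a * (10^7 + 1)
TIE_DEN = 10**7


def binom_minlike_oracle(k: int, n: int, p: float) -> float:
    pmf = [math.comb(n, j) * (p ** j) * ((1 - p) ** (n - j)) for j in range(n + 1)]
    obs = pmf[k]
    return min(1.0, sum(q for q in pmf if q <= obs * (1 + 1e-7)))


def hypergeom_weights(N: int, K: int, n: int):
    """Exact integer table weights over the support of the (1,1) cell."""
    lo = max(0, n - (N - K))
    hi = min(K, n)
    xs = list(range(lo, hi + 1))
    ws = [math.comb(K, x) * math.comb(N - K, n - x) for x in xs]
    return xs, ws


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    N, K, n = a + b + c + d, a + b, a + c
    if K == 0 or K == N or n == 0 or n == N:
        return 1.0
    xs, ws = hypergeom_weights(N, K, n)
    wa = ws[xs.index(a)]
    num = sum(w for w in ws if w * TIE_DEN <= wa * TIE_NUM)
    return min(1.0, float(Fraction(num, sum(ws))))


def fisher_upper_oracle(a: int, b: int, c: int, d: int) -> float:
    N, K, n = a + b + c + d, a + b, a + c
    if K == 0 or K == N or n == 0 or n == N:
        return 1.0
    xs, ws = hypergeom_weights(N, K, n)
    num = sum(w for x, w in zip(xs, ws) if x >= a)
    return min(1.0, float(Fraction(num, sum(ws))))


def fisher_oracle_margin_group(N: int, K: int, n: int):
    """Vectorized oracle for every table sharing margins (N, K, n).

    Returns (support, two_sided, upper) arrays: p-values for the table
    whose (1,1) cell is each support value. Exact integer weights are
    evaluated in float64; the 1e-7 tie tolerance dwarfs float rounding.
    """
    xs, ws = hypergeom_weights(N, K, n)
    w = np.array([float(v) for v in ws])
    total = float(sum(ws))
    include = w[None, :] <= w[:, None] * (1 + 1e-7)
    two = np.minimum(1.0, (include * w[None, :]).sum(axis=1) / total)
    upper = np.minimum(1.0, (w[::-1].cumsum()[::-1]) / total)
    return np.array(xs), two, upper
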