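"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately naive (window-by-window comparison, explicit
breakpoint scans, exact rational arithmetic) and shares no code path with the
implementation it checks.
"""

from fractions import Fraction
from math import comb

import numpy as np


def naive_scan(seq: str, seed7_pat: str, seed6_pat: str) -> list[tuple[int, str]]:
    """All-windows seed scan: (start, class) pairs sorted by start.

    Every window equal to the 7-nt pattern is a seed7 site; windows equal to
    the 6-nt pattern are seed6 sites unless contained in a seed7 window.
    """
    seq = seq.upper()
    sites7 = []
    for i in range(len(seq) - 6):
        if all(seq[i + j] == seed7_pat[j] for j in range(7)):
            sites7.append(i)
    shadow = {i for t in sites7 for i in (t, t + 1)}
    sites6 = []
    for i in range(len(seq) - 5):
        if i in shadow:
            continue
        if all(seq[i + j] == seed6_pat[j] for j in range(6)):
            sites6.append(i)
    out = [(i, "seed7") for i in sites7] + [(i, "seed6") for i in sites6]
    return sorted(out)


def ks_D_bruteforce(a, b) -> float:
    """sup |F_a - F_b| by explicit scan over every observed breakpoint."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.count_nonzero(a <= x) / a.size
        fb = np.count_nonzero(b <= x) / b.size
        best = max(best, abs(fa - fb))
    return best


def bh_stepup(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up recipe."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def hypergeom_upper_tail(a: int, N: int, K: int, n: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(N, K, n), exact rational arithmetic."""
    total = comb(N, n)
    acc = Fraction(0)
    for k in range(max(a, 0), min(K, n) + 1):
        acc += Fraction(comb(K, k) * comb(N - K, n - k), total)
    return float(min(acc, Fraction(1)))
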