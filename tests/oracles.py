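"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most direct method possible
(exhaustive scans, recursive enumeration, literal definitions) and share
no code with the implementation paths they check.
"""
from __future__ import annotations

import math

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def brute_longest_orf_codons(seq: str) -> int:
    """Longest ATG..stop ORF over six frames by scanning every ATG."""
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for s in (seq.upper(), rc(seq.upper())):
        n = len(s)
        for i in range(n - 2):
            if s[i : i + 3] == "ATG":
                j = i + 3
                while j + 3 <= n:
                    if s[j : j + 3] in stops:
                        best = max(best, (j - i) // 3)
                        break
                    j += 3
    return best


def sw_dp_oracle(a: str, b: str, match=1, mismatch=-2, open_=-5, extend=-2) -> int:
    """Plain-Python Gotoh local alignment (open cost on first gap base)."""
    neg = -(10**9)
    m, n = len(a), len(b)
    h_prev = [0] * (n + 1)
    e_prev = [neg] * (n + 1)
    best = 0
    for i in range(1, m + 1):
        h_cur = [0] * (n + 1)
        e_cur = [neg] * (n + 1)
        f = neg
        for j in range(1, n + 1):
            e_cur[j] = max(h_prev[j] + open_, e_prev[j] + extend)
            f = max(h_cur[j - 1] + open_, f + extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h_cur[j] = max(0, h_prev[j - 1] + s, e_cur[j], f)
            if h_cur[j] > best:
                best = h_cur[j]
        h_prev, e_prev = h_cur, e_cur
    return best


def sw_enumerate_oracle(a: str, b: str, match=1, mismatch=-2, open_=-5, extend=-2) -> int:
    """Exhaustive enumeration of every local alignment (tiny inputs only)."""
    best = 0

    def rec(i: int, j: int, score: float, state: str) -> None:
        nonlocal best
        best = max(best, score)
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            rec(i + 1, j, score + (extend if state == "I" else open_), "I")
        if j < len(b):
            rec(i, j + 1, score + (extend if state == "D" else open_), "D")

    for i0 in range(len(a) + 1):
        for j0 in range(len(b) + 1):
            rec(i0, j0, 0, "start")
    return int(best)


def bh_oracle(p_values) -> list[float]:
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(indexed):
        candidates = [
            p_values[indexed[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def binom_two_sided_oracle(k1: int, k2: int, n1: int, n2: int) -> float:
    """Exact binomial split test by direct pmf summation."""
    s = k1 + k2
    if s == 0:
        return 1.0
    pi = n1 / (n1 + n2)
    pmf = [
        math.comb(s, k) * pi**k * (1 - pi) ** (s - k) for k in range(s + 1)
    ]
    obs = pmf[k1]
    return min(1.0, sum(p for p in pmf if p <= obs * (1 + 1e-10)))
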