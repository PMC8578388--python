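"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the algorithms used by the package: exact
matches are found by scanning every diagonal of the full comparison
matrix, the hypergeometric and Poisson probabilities are summed from
exact combinatorial terms, and chaining is checked by enumeration.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _scan_diagonals(ref: str, q: str, k: int):
    """Yield (ref_start, q_start, length) for maximal match runs >= k."""
    a = np.frombuffer(ref.encode(), np.uint8)
    b = np.frombuffer(q.encode(), np.uint8)
    n, m = a.size, b.size
    ncode = ord("N")
    for d in range(-(m - 1), n):
        i0, j0 = max(d, 0), max(-d, 0)
        length = min(n - i0, m - j0)
        if length < k:
            continue
        eq = (a[i0 : i0 + length] == b[j0 : j0 + length]) & (a[i0 : i0 + length] != ncode)
        padded = np.concatenate(([0], eq.view(np.uint8), [0]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            if e - s >= k:
                yield i0 + int(s), j0 + int(s), int(e - s)


def mems_bruteforce(ref: str, query: str, k: int) -> set[tuple[int, int, int, int, str]]:
    """All maximal exact matches >= k on both strands.

    Returns tuples (ref_start, ref_end, query_start, query_end, strand)
    with query coordinates on the forward strand.
    """
    out = set()
    for i, j, length in _scan_diagonals(ref, query, k):
        out.add((i, i + length, j, j + length, "+"))
    m = len(query)
    for i, j, length in _scan_diagonals(ref, revcomp(query), k):
        out.add((i, i + length, m - (j + length), m - j, "-"))
    return out


def hypergeom_pmf_exact(N: int, n: int, X: int, j: int) -> float:
    """PMF from exact integer binomial coefficients."""
    if j < max(0, n + X - N) or j > min(n, X):
        return 0.0
    return math.comb(n, j) * math.comb(N - n, X - j) / math.comb(N, X)


def hypergeom_two_tailed_exact(N: int, n: int, X: int, k: int) -> float:
    """Minimum-likelihood two-tailed p by direct PMF summation."""
    pk = hypergeom_pmf_exact(N, n, X, k)
    total = 0.0
    for j in range(max(0, n + X - N), min(n, X) + 1):
        pj = hypergeom_pmf_exact(N, n, X, j)
        if pj <= pk * (1 + 1e-9):
            total += pj
    return min(1.0, total)


def hypergeom_upper_exact(N: int, n: int, X: int, k: int) -> float:
    return min(1.0, sum(
        hypergeom_pmf_exact(N, n, X, j) for j in range(k, min(n, X) + 1)
    ))


def poisson_upper_exact(x: int, lam: float) -> float:
    """P(X >= x) by direct summation of PMF terms from x upward.

    Terms start at log-scale PMF(x) and follow the multiplicative
    recurrence; summation stops when additional terms can no longer
    affect the total at double precision.
    """
    if x <= 0:
        return 1.0
    if lam <= 0:
        return 0.0
    term = math.exp(-lam + x * math.log(lam) - math.lgamma(x + 1))
    total = 0.0
    j = x
    while True:
        total += term
        j += 1
        term *= lam / j
        if term < total * 1e-18 + 1e-320:
            break
    return min(1.0, total)
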