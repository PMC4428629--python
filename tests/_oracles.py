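"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own code paths (and scipy's
fisher_exact) so that agreement is a genuine two-route check.
"""

from __future__ import annotations

import math
from math import lgamma


def brute_force_scan(positions: list[set[str]], sequence: str) -> list[int]:
    """Window-by-window motif scan: start offsets of all matching windows."""
    w = len(positions)
    out = []
    for start in range(len(sequence) - w + 1):
        ok = True
        for offset, cls in enumerate(positions):
            residue = sequence[start + offset]
            if residue == "X":
                if len(cls) < 20:
                    ok = False
                    break
            elif residue not in cls:
                ok = False
                break
        if ok:
            out.append(start)
    return out


def _log_choose(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeom_pmf(a: int, row1: int, col1: int, n: int) -> float:
    """P(top-left cell = a) with fixed margins, via log-factorials."""
    row2 = n - row1
    if a < 0 or a > row1 or col1 - a < 0 or col1 - a > row2:
        return 0.0
    return math.exp(
        _log_choose(row1, a) + _log_choose(row2, col1 - a) - _log_choose(n, col1)
    )


def fisher_oracle(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """(one-sided upper tail of a, minimum-likelihood two-sided p)."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    pmfs = {k: hypergeom_pmf(k, row1, col1, n) for k in range(lo, hi + 1)}
    p_one = sum(p for k, p in pmfs.items() if k >= a)
    observed = pmfs[a]
    # Same relative gate as R / scipy for floating-point ties.
    p_two = sum(p for p in pmfs.values() if p <= observed * (1 + 1e-7))
    return min(p_one, 1.0), min(p_two, 1.0)
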