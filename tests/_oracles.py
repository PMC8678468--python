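"""Independent brute-force oracles the tests check the implementation against.

Deliberately written as straight-line scalar code, structured differently
from the package's vectorised implementations.
"""

from __future__ import annotations

from math import comb


def decision_table(p1: float, p2: float, h: float, fold: float = 1.25, eps: float = 0.01) -> str:
    """Scalar re-derivation of the nine-way classification rule."""

    def similar(a: float, b: float) -> bool:
        big, small = (a, b) if a >= b else (b, a)
        return (big + eps) / (small + eps) <= fold

    near1 = similar(h, p1)
    near2 = similar(h, p2)
    if near1 and near2:
        return "conserved"
    if near1:
        return "dominant_cg_up" if p1 > p2 else "dominant_cg_down"
    if near2:
        return "dominant_wl_up" if p2 > p1 else "dominant_wl_down"
    low, high = min(p1, p2), max(p1, p2)
    if low < h < high:
        return "additive_cg_high" if p1 > p2 else "additive_wl_high"
    if h >= high:
        return "over_dominant"
    return "under_dominant"


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums P(X = x) over the support for every table at least as extreme
    (probability no greater than the observed one, with the conventional
    1 + 1e-7 relative tie guard).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    denom = comb(n, c1)
    pmf = {x: comb(r1, x) * comb(r2, c1 - x) / denom for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))


def bh_step_up(pvalues: list[float]) -> list[float]:
    """Hand-computed Benjamini-Hochberg: adjusted_(i) = min_{j>=i} p_(j) * n / j."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted_sorted = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        value = min(1.0, pvalues[i] * n / rank)
        running_min = min(running_min, value)
        adjusted_sorted[rank - 1] = running_min
    out = [0.0] * n
    for rank, i in enumerate(order):
        out[i] = adjusted_sorted[rank]
    return out


def mannwhitney_u(x: list[float], y: list[float]) -> float:
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u
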