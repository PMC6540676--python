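"""Independent brute-force oracles used to check the implementation.

These deliberately share no code with the package: plain-Python dynamic
programming and exhaustive scans, usable only at small input sizes.
"""

from __future__ import annotations

NEG = float("-inf")


def sw_local_score(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> float:
    """Exhaustive affine-gap Smith–Waterman optimum.

    A gap of length k costs gap_open + k * gap_extend.
    """
    n, m = len(a), len(b)
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            F[i][j] = max(F[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def nw_global_score(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
    free_end_gaps: bool = True,
) -> float:
    """Exhaustive affine-gap global (or semi-global) optimum."""
    n, m = len(a), len(b)

    def gap(k: int) -> float:
        return 0.0 if k == 0 else -(gap_open + k * gap_extend)

    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for i in range(1, n + 1):
        H[i][0] = 0.0 if free_end_gaps else gap(i)
        E[i][0] = H[i][0]
    for j in range(1, m + 1):
        H[0][j] = 0.0 if free_end_gaps else gap(j)
        F[0][j] = H[0][j]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            F[i][j] = max(F[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    if not free_end_gaps:
        return H[n][m]
    best = max(max(H[i][m] for i in range(n + 1)), max(H[n][j] for j in range(m + 1)))
    return best


def brute_force_window(spans, threshold: float):
    """Column-by-column scan for the feasible-boundary window.

    spans: iterable of (start, end) half-open intervals. Returns
    (start, end) of [min F, max F + 1) or None when F is empty.
    """
    import math

    spans = list(spans)
    k = math.ceil(threshold * len(spans))
    lo = min(s for s, _ in spans)
    hi = max(e for _, e in spans)
    feasible = [
        p for p in range(lo, hi) if sum(1 for s, e in spans if s <= p < e) >= k
    ]
    if not feasible:
        return None
    return feasible[0], feasible[-1] + 1


def brute_force_mbh(fwd_best, back_best):
    """Exhaustive mutual-best check.

    fwd_best: map member -> its best reference; back_best: map reference ->
    its best member. Returns the set of (member, reference) mutual pairs.
    """
    return {
        (c, r)
        for c, r in fwd_best.items()
        if back_best.get(r) == c
    }


def p_distance(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y) / len(a)
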