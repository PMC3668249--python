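"""Independent, maximally naive reference implementations used as oracles.

These are deliberately literal double-loop transcriptions, kept free of any
code from the package so they can arbitrate its optimized paths.
"""

from __future__ import annotations


def kic_naive(window: str, policy: str = "count_as_zero") -> float:
    """Naive lag-scan Kappa IC: for each lag u = 1..N (N = len-1), compare
    the window against itself shifted by u over the first N characters only
    (the final character never participates); each non-empty lag contributes
    100 * matches / lag_length; the empty maximal lag contributes 0 and is
    kept in (count_as_zero) or dropped from (exclude_from_mean) the mean.
    Ambiguous N never matches.  Rounded half-to-even to 2 decimals.
    """
    A = window
    N = len(A) - 1
    if N < 1:
        raise ValueError("window too short")
    total = 0.0
    for u in range(1, N + 1):
        B = A[u:N]  # characters u+1..N in 1-based terms
        if not B:
            continue  # empty lag: contributes 0 either way
        C = 0
        for i in range(len(B)):
            if A[i] == B[i] and A[i] != "N":
                C += 1
        total += C / len(B) * 100.0
    denom = N if policy == "count_as_zero" else N - 1
    if denom == 0:
        raise ValueError("no non-empty lag to average")
    return round(total / denom, 2)


def mean_xy_naive(points) -> tuple[float, float]:
    """Separate plain-Python summation mean, as a centroid cross-check."""
    sx = sy = 0.0
    n = 0
    for x, y in points:
        sx += x
        sy += y
        n += 1
    return sx / n, sy / n
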