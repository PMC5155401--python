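"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written from the problem definitions,
not from the package's code paths: a full O(n*m) affine-gap DP, an
exhaustive sliding-window scan, and a naive two-pass symmetric set
difference on multisets of variant keys.
"""

from __future__ import annotations

NEG = float("-inf")


def affine_global_score(
    a: str,
    b: str,
    match: int = 5,
    mismatch: int = -2,
    gap_open: int = -20,
    gap_extend: int = 0,
) -> int:
    """Unrestricted global alignment score with affine gap costs."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * i
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1].upper() == b[j - 1].upper() else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + gap_open + gap_extend,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open + gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open + gap_extend,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open + gap_extend,
            )
        # also fill row entries for j == 0 transitions (done above)
    return int(max(M[n][m], X[n][m], Y[n][m]))


def window_filter_oracle(
    runs: list[tuple[int, int]],
    discrepant: list[bool],
    window: int,
    max_disc: int,
) -> list[bool]:
    """For each half-open run, True iff it survives the window filter.

    Enumerates every fully contained window of ``window`` columns (the
    whole alignment when shorter) and excludes a run iff some over-dense
    window overlaps it.
    """
    n = len(discrepant)
    if n <= window:
        windows = [(0, n)]
    else:
        windows = [(w0, w0 + window) for w0 in range(n - window + 1)]
    over_dense = [
        (lo, hi) for lo, hi in windows if sum(discrepant[lo:hi]) > max_disc
    ]
    kept = []
    for s, e in runs:
        bad = any(lo < e and s < hi for lo, hi in over_dense)
        kept.append(not bad)
    return kept


def symmetric_difference_oracle(
    R: list[tuple], A: list[tuple]
) -> tuple[int, int, list[tuple]]:
    """(|shared|, |RV|, RV multiset) by two explicit one-sided passes."""
    from collections import Counter

    cr, ca = Counter(R), Counter(A)
    shared = sum((cr & ca).values())
    r_only = list((cr - ca).elements())
    a_only = list((ca - cr).elements())
    rv = r_only + a_only
    return shared, len(rv), sorted(rv)
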