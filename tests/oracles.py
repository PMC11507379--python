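"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the implementation's code paths (and the
libraries it delegates to): local alignment is a plain dynamic-programming
Smith-Waterman, interval logic is exhaustive O(n^2)/O(n^3) scanning.
"""

from __future__ import annotations

import numpy as np


def smith_waterman(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> tuple[int, float, tuple[int, int], tuple[int, int]]:
    """Affine-gap local alignment by full dynamic programming.

    A gap of length k costs |gap_open| + k*|gap_extend| (the convention of
    the production scoring scheme).  Returns (score, percent_identity,
    (a_start, a_end), (b_start, b_end)) for the single best alignment.
    """
    n, m = len(a), len(b)
    NEG = -(10**9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)  # best ending in match/mismatch or 0
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in b (vertical)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in a (horizontal)
    open_cost = gap_open + gap_extend
    best, best_pos = 0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + open_cost, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + open_cost, F[i][j - 1] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best, best_pos = H[i][j], (i, j)
    if best == 0:
        return 0, 0.0, (0, 0), (0, 0)
    # traceback
    i, j = best_pos
    matches = cols = 0
    state = "H"
    while i > 0 and j > 0 and H[i][j] > 0:
        if state == "H":
            s = match if a[i - 1] == b[j - 1] else mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                matches += a[i - 1] == b[j - 1]
                cols += 1
                i, j = i - 1, j - 1
                if H[i][j] == 0:
                    break
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols += 1
            if E[i][j] == E[i - 1][j] + gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"
        else:
            cols += 1
            if F[i][j] == F[i][j - 1] + gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
    identity = 100.0 * matches / cols if cols else 0.0
    return int(best), identity, (i, best_pos[0]), (j, best_pos[1])


def brute_force_merge(hsps, max_gap_nuclear, max_gap_mito, pair_mergeable) -> list[set]:
    """Transitive closure over an explicit pairwise predicate, by repeated
    sweeps until a fixed point (no union-find)."""
    n = len(hsps)
    groups = [{i} for i in range(n)]
    changed = True
    while changed:
        changed = False
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                if any(
                    pair_mergeable(hsps[i], hsps[j])
                    for i in groups[gi]
                    for j in groups[gj]
                ):
                    groups[gi] |= groups[gj]
                    del groups[gj]
                    changed = True
                    break
            if changed:
                break
    return groups


def brute_force_overlap_calls(intervals, deletions, min_fraction, margin):
    """O(n*m) scan classifying each interval against deletion variants."""
    calls = []
    for iv in intervals:
        best = None
        for d in deletions:
            if iv[0] != d[0]:
                continue
            ov = max(0, min(iv[2], d[2]) - max(iv[1], d[1]))
            frac = ov / (iv[2] - iv[1])
            if frac >= min_fraction:
                key = (frac, -abs((d[2] - d[1]) - (iv[2] - iv[1])))
                if best is None or key > best[0]:
                    best = (key, d)
        if best is None:
            calls.append("fixed")
        else:
            d = best[1]
            calls.append(
                "absent_large_sv"
                if (d[2] - d[1]) > (iv[2] - iv[1]) + margin
                else "absent_clean"
            )
    return calls


def welch_closed_form(x, y):
    """Welch's t, Welch-Satterthwaite df and two-sided p from the textbook
    formulas, using only elementary numpy plus the t survival function."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1 = x.var(ddof=1) / n1
    v2 = y.var(ddof=1) / n2
    t = (x.mean() - y.mean()) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p
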