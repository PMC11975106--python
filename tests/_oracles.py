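"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming and
vectorised implementations: the DTW oracle enumerates every monotone
warping path explicitly, and the pattern oracle tries every candidate
(earlier, later) segment pair with plain-list comparisons.
"""

from __future__ import annotations

import math


def brute_force_subsequence_dtw(perf, ref, local_cost, cost_cap):
    """Minimum over all monotone warping paths, open begin/end on ref.

    A path starts at (0, j0) for any j0, steps by (1,1), (1,0) or
    (0,1), and may end at any cell of the last performance row. Returns
    the normalised distance of the lexicographically minimal
    (cumulative cost, path length) path.
    """
    m, n = len(perf), len(ref)
    cost = [[local_cost(perf[i], ref[j]) for j in range(n)] for i in range(m)]
    best = [math.inf, 0]

    def walk(i, j, cum, length):
        if i == m - 1 and (cum, length) < tuple(best):
            best[0], best[1] = cum, length
        if i + 1 < m and j + 1 < n:
            walk(i + 1, j + 1, cum + cost[i + 1][j + 1], length + 1)
        if i + 1 < m:
            walk(i + 1, j, cum + cost[i + 1][j], length + 1)
        if j + 1 < n:
            walk(i, j + 1, cum + cost[i][j + 1], length + 1)

    for j0 in range(n):
        walk(0, j0, cost[0][j0], 1)
    return best[0] / (best[1] * cost_cap)


def oracle_pattern_notes(pitches, min_len, kind):
    """Notes claimed by later occurrences of earlier material.

    Simulates the documented greedy leftmost-longest claim rule, but
    finds each candidate by exhaustively testing every (earlier start,
    later start, length) triple with plain-list slicing. ``kind`` is
    "retrograde" (earlier reversed equals later) or "sequence" (equal
    interval pattern at a non-zero transposition).
    """
    pitches = list(pitches)
    n = len(pitches)
    if n < 2 * min_len:
        return 0

    if kind == "retrograde":
        def is_match(s, i, length):
            return pitches[s : s + length][::-1] == pitches[i : i + length]
    elif kind == "sequence":
        def is_match(s, i, length):
            a = pitches[s : s + length]
            b = pitches[i : i + length]
            return (
                [y - x for x, y in zip(a, a[1:])]
                == [y - x for x, y in zip(b, b[1:])]
                and a[0] != b[0]
            )
    else:
        raise ValueError(kind)

    total = 0
    i = 0
    while i + min_len <= n:
        claimed = 0
        for length in range(n - i, min_len - 1, -1):
            if any(is_match(s, i, length) for s in range(0, i - length + 1)):
                claimed = length
                break
        if claimed:
            total += claimed
            i += claimed
        else:
            i += 1
    return total
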