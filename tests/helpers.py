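"""Independent oracles used by the test suite.

These deliberately use naive algorithms (exhaustive enumeration, quadratic
scans, textbook dynamic programming) so they share no code path with the
implementations they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def brute_force_pairs(reference: str, cut_up: int, cut_down: int,
                      excluded: list[tuple[int, int]] = (), min_len: int = 3,
                      primer_span: tuple[int, int] | None = None) -> set:
    """All maximal identical segment pairs flanking the cut(s), by direct
    enumeration of every (i, j, length) triple."""
    n = len(reference)
    ps, pe = primer_span if primer_span is not None else (0, n)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            if reference[i:i + min_len] != reference[j:j + min_len]:
                continue
            # extendable one base left => not maximal
            if i > 0 and j > 0 and reference[i - 1] == reference[j - 1]:
                continue
            # extend right as far as equality holds (even into overlapping
            # copies: an extendable pair is not maximal either way)
            length = min_len
            while j + length < n and reference[i + length] == reference[j + length]:
                length += 1
            up, down = (i, i + length), (j, j + length)
            if not (ps <= up[0] and up[1] <= cut_up):
                continue
            if not (cut_down <= down[0] and down[1] <= pe):
                continue
            if any(min(e, iv[1]) > max(s, iv[0]) for (s, e) in (up, down) for iv in excluded):
                continue
            out.add((up, down, reference[i:i + length]))
    return out


def indel_distance(a: str, b: str) -> int:
    """Insertion/deletion-only edit distance: |a| + |b| - 2*LCS(a, b)."""
    la, lb = len(a), len(b)
    prev = list(range(0, 1))  # LCS DP
    dp = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            if a[i - 1] == b[j - 1]:
                dp[i][j] = dp[i - 1][j - 1] + 1
            else:
                dp[i][j] = max(dp[i - 1][j], dp[i][j - 1])
    return la + lb - 2 * dp[la][lb]


def mwu_exhaustive(a, b) -> float:
    """Two-tailed exact Mann-Whitney p by enumerating every group assignment."""
    na = len(a)
    pooled = list(a) + list(b)
    n = len(pooled)
    ranks = _midranks(pooled)
    u_obs = sum(ranks[i] for i in range(na)) - na * (na + 1) / 2
    lo = hi = 0
    for idx in combinations(range(n), na):
        u = sum(ranks[i] for i in idx) - na * (na + 1) / 2
        if u <= u_obs + 1e-9:
            lo += 1
        if u >= u_obs - 1e-9:
            hi += 1
    return min(1.0, 2 * min(lo, hi) / comb(n, na))


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and values[order[j]] == values[order[i]]:
            j += 1
        mid = (i + 1 + j) / 2
        for k in range(i, j):
            ranks[order[k]] = mid
        i = j
    return ranks


def best_single_deletion_placements(read: str, reference: str, d: int) -> dict[int, int]:
    """Mismatch count of every alignment read = ref[:a] + ref[a+d:...] with
    one deletion of length d at reference position a (read 3' end free)."""
    out = {}
    for a in range(0, len(reference) - d + 1):
        if a > len(read):
            break
        model = reference[:a] + reference[a + d:]
        if len(model) < len(read):
            continue
        out[a] = sum(x != y for x, y in zip(read, model[:len(read)]))
    return out
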