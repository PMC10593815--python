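"""Independent oracles used by the test suite.

These deliberately re-derive results by the dumbest correct route (pure-Python
dynamic programming, exhaustive subset enumeration, two-pass covariance) so
they share no code with the implementation they check.
"""

from __future__ import annotations

import itertools
import math


def overlap_align_oracle(q: str, r: str) -> tuple[int, int, int, int]:
    """Pure-Python overlap alignment: (score, matches, aligned_cols, q_bases).

    Match +1, mismatch -1, gap -1, free end gaps on both sequences. The
    declared tie-break order (recurrence: diagonal, then up/consume-query,
    then left; end cell: last row at the smallest column first, then the last
    column at the smallest row) matches the package's contract.
    """
    n, m = len(q), len(r)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        qi = q[i - 1]
        row, prev = H[i], H[i - 1]
        for j in range(1, m + 1):
            s = 1 if qi == r[j - 1] else -1
            row[j] = max(prev[j - 1] + s, prev[j] - 1, row[j - 1] - 1)
    ei, ej, best = n, 0, H[n][0]
    for j in range(1, m + 1):
        if H[n][j] > best:
            best, ei, ej = H[n][j], n, j
    for i in range(0, n):
        if H[i][m] > best:
            best, ei, ej = H[i][m], i, m
    matches = cols = qbases = 0
    i, j = ei, ej
    while i > 0 and j > 0:
        s = 1 if q[i - 1] == r[j - 1] else -1
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += s == 1
            cols += 1
            qbases += 1
            i -= 1
            j -= 1
        elif H[i][j] == H[i - 1][j] - 1:
            cols += 1
            qbases += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return best, matches, cols, qbases


def hypergeom_null_by_enumeration(N: int, n1: int, n2: int) -> dict[int, float]:
    """Null distribution of the shared-site count by brute force: place the
    ASV on every possible ``n2``-subset of ``N`` sites with the species fixed
    on the first ``n1`` sites, and tally overlaps."""
    species = set(range(n1))
    counts: dict[int, int] = {}
    total = 0
    for subset in itertools.combinations(range(N), n2):
        j = len(species.intersection(subset))
        counts[j] = counts.get(j, 0) + 1
        total += 1
    return {j: c / total for j, c in counts.items()}


def pearson_two_pass(x, y) -> float:
    """Naive two-pass Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
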