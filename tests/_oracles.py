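"""Independent slow oracles used to verify the DP aligners.

``slow_local`` is the classic cubic-time local alignment with explicit
gap-length enumeration (a different recurrence from the Gotoh kernel it
checks); ``enum_local`` exhaustively enumerates every monotone alignment
path at tiny sizes and validates slow_local itself.
"""

from __future__ import annotations

import numpy as np


def slow_local(a, b, sub, gap_open, gap_extend):
    """Best local alignment score by explicit gap-length maximization."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            v = max(0.0, H[i - 1][j - 1] + sub[a[i - 1], b[j - 1]])
            for k in range(1, i + 1):
                v = max(v, H[i - k][j] + gap_open + k * gap_extend)
            for k in range(1, j + 1):
                v = max(v, H[i][j - k] + gap_open + k * gap_extend)
            H[i][j] = v
            best = max(best, v)
    return best


def enum_local(a, b, sub, gap_open, gap_extend):
    """Exhaustive enumeration of all local alignment paths (tiny inputs only)."""
    best = 0.0
    n, m = len(a), len(b)
    for i0 in range(n):
        for j0 in range(m):
            stack = [(i0, j0, 0.0, None)]
            while stack:
                i, j, sc, last = stack.pop()
                best = max(best, sc)
                if i < n and j < m:
                    stack.append((i + 1, j + 1, sc + sub[a[i], b[j]], "d"))
                if i < n:
                    cost = gap_extend if last == "u" else gap_open + gap_extend
                    stack.append((i + 1, j, sc + cost, "u"))
                if j < m:
                    cost = gap_extend if last == "l" else gap_open + gap_extend
                    stack.append((i, j + 1, sc + cost, "l"))
    return best


def hamming(a: str, b: str) -> int:
    """Naive per-position mismatch count (motif-scan oracle)."""
    assert len(a) == len(b)
    d = 0
    for x, y in zip(a, b):
        if x != y or x not in "ACGT":
            d += 1
    return d
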