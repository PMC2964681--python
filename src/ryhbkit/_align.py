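"""Shared affine-gap local-alignment dynamic programming kernel.

One Gotoh-style kernel serves protein alignment (orthology), nucleotide
core searches (srna_discovery) and antiparallel duplex scoring
(target_prediction); only the substitution table changes.

Gap convention: a gap of length k costs ``gap_open + k * gap_extend``
(both parameters are <= 0), i.e. the first gapped column already pays
``gap_open + gap_extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# traceback codes for the H matrix
_STOP, _DIAG, _UP, _LEFT = 0, 1, 2, 3


@njit(cache=True)
def _fill(a, b, sub, gap_open, gap_extend):  # pragma: no cover - exercised via wrappers
    n = a.shape[0]
    m = b.shape[0]
    neg = -1.0e30
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in `a` (consumes b[j-1])
    F = np.full((n + 1, m + 1), neg)  # gap in `b` (consumes a[i-1])
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0: opened from H, 1: extended
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.uint8)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open + gap_extend
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptr_e[i, j] = 0
            else:
                E[i, j] = e_ext
                ptr_e[i, j] = 1
            f_open = H[i - 1, j] + gap_open + gap_extend
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptr_f[i, j] = 0
            else:
                F[i, j] = f_ext
                ptr_f[i, j] = 1
            diag = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            best = 0.0
            p = 0
            if diag > best:
                best = diag
                p = 1
            if F[i, j] > best:
                best = F[i, j]
                p = 2
            if E[i, j] > best:
                best = E[i, j]
                p = 3
            H[i, j] = best
            ptr_h[i, j] = p
    return H, ptr_h, ptr_e, ptr_f


def _traceback(a_codes, b_codes, ptr_h, ptr_e, ptr_f, i, j):
    """Walk pointers from endpoint (i, j); returns (qstart, sstart, moves).

    `moves` is a list of (ai, bi) index pairs with -1 marking a gap, in
    alignment (left-to-right) order.
    """
    moves = []
    state = "H"
    while True:
        if state == "H":
            p = ptr_h[i, j]
            if p == _STOP:
                break
            if p == _DIAG:
                moves.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif p == _UP:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            moves.append((i - 1, -1))
            opened = ptr_f[i, j] == 0
            i -= 1
            if opened:
                state = "H"
        else:  # E
            moves.append((-1, j - 1))
            opened = ptr_e[i, j] == 0
            j -= 1
            if opened:
                state = "H"
    moves.reverse()
    return i, j, moves


def local_align_codes(a_codes, b_codes, sub, gap_open, gap_extend, tie="start"):
    """Exact affine-gap local alignment on integer-encoded sequences.

    Returns (score, qstart, qend, sstart, send, moves). Ties between
    co-optimal endpoints are resolved toward the smallest query start,
    then smallest subject start (``tie="start"``), or toward the shortest
    alignment, then smallest query start (``tie="short"``).
    """
    a = np.ascontiguousarray(a_codes, dtype=np.int64)
    b = np.ascontiguousarray(b_codes, dtype=np.int64)
    H, ptr_h, ptr_e, ptr_f = _fill(a, b, np.asarray(sub, dtype=np.float64),
                                   float(gap_open), float(gap_extend))
    score = float(H.max())
    if score <= 0.0:
        return 0.0, 0, 0, 0, 0, []
    ends = np.argwhere(H == H.max())
    best = None
    for i, j in ends:
        qs, ss, moves = _traceback(a, b, ptr_h, ptr_e, ptr_f, int(i), int(j))
        if tie == "short":
            key = (len(moves), qs, ss, int(i), int(j))
        else:
            key = (qs, ss, len(moves), int(i), int(j))
        if best is None or key < best[0]:
            best = (key, qs, ss, int(i), int(j), moves)
    _, qs, ss, qe, se, moves = best
    return score, qs, qe, ss, se, moves


def render_gapped(a_seq, b_seq, moves, gap_char="-"):
    """Render the two gapped alignment strings from traceback moves."""
    top = []
    bot = []
    for ai, bi in moves:
        top.append(a_seq[ai] if ai >= 0 else gap_char)
        bot.append(b_seq[bi] if bi >= 0 else gap_char)
    return "".join(top), "".join(bot)
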