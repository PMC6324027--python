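"""Numba dynamic-programming kernels for pairwise alignment.

Affine gap convention: a gap of length L costs ``gap_open + gap_extend * L``
(so the first gapped residue costs open+extend, as in BLAST's 11/1).
Scores are int32; substitution matrices are dense int32 lookups over the
encoded alphabet.

Tie-breaking is fixed so output is deterministic: the best local cell is
the first maximum in row-major order, and tracebacks prefer diagonal,
then horizontal (gap in the query), then vertical moves.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10**9))


@njit(cache=False)
def sw_score(a, b, sub, gap_open, gap_extend):
    """Best local (Smith-Waterman) score; linear memory."""
    n = a.size
    m = b.size
    go = gap_open + gap_extend
    ge = gap_extend
    h_prev = np.zeros(m + 1, np.int32)
    f_prev = np.full(m + 1, NEG, np.int32)
    best = np.int32(0)
    for i in range(1, n + 1):
        h_curr = np.zeros(m + 1, np.int32)
        f_curr = np.empty(m + 1, np.int32)
        f_curr[0] = NEG
        e = NEG
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = max(h_curr[j - 1] - go, e - ge)
            f = max(h_prev[j] - go, f_prev[j] - ge)
            f_curr[j] = f
            h = h_prev[j - 1] + sub[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_curr[j] = h
            if h > best:
                best = h
        h_prev = h_curr
        f_prev = f_curr
    return best


@njit(cache=False)
def sw_align(a, b, sub, gap_open, gap_extend):
    """Full Smith-Waterman with traceback.

    Returns ``(score, q_positions, s_positions)`` where the position
    arrays are the 1-based aligned residue pairs in order.
    """
    n = a.size
    m = b.size
    go = gap_open + gap_extend
    ge = gap_extend
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG, np.int32)
    F = np.full((n + 1, m + 1), NEG, np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = max(H[i, j - 1] - go, E[i, j - 1] - ge)
            f = max(H[i - 1, j] - go, F[i - 1, j] - ge)
            E[i, j] = e
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    qpos = np.empty(n + m, np.int32)
    spos = np.empty(n + m, np.int32)
    k = 0
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = E (horizontal), 2 = F (vertical)
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if h == H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]:
                qpos[k] = i
                spos[k] = j
                k += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            if E[i, j] == H[i, j - 1] - go:
                j -= 1
                state = 0
            else:
                j -= 1
        else:
            if F[i, j] == H[i - 1, j] - go:
                i -= 1
                state = 0
            else:
                i -= 1
    return best, qpos[:k][::-1].copy(), spos[:k][::-1].copy()


@njit(cache=False)
def nw_align_scored(S, gap_open, gap_extend):
    """Global (Needleman-Wunsch/Gotoh) alignment over a precomputed
    column-pair score matrix ``S`` (float64, shape n x m).

    End gaps are penalized like internal ones.  Returns
    ``(score, a_cols, b_cols)`` where the column arrays give, per
    alignment column, the 0-based input column index or -1 for a gap.
    """
    n, m = S.shape
    go = gap_open + gap_extend
    ge = gap_extend
    BIG = -1e18
    H = np.empty((n + 1, m + 1), np.float64)
    E = np.full((n + 1, m + 1), BIG, np.float64)
    F = np.full((n + 1, m + 1), BIG, np.float64)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = -(go + ge * (j - 1))
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = -(go + ge * (i - 1))
        H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = max(H[i, j - 1] - go, E[i, j - 1] - ge)
            f = max(H[i - 1, j] - go, F[i - 1, j] - ge)
            E[i, j] = e
            F[i, j] = f
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
    a_cols = np.empty(n + m, np.int64)
    b_cols = np.empty(n + m, np.int64)
    k = 0
    i = n
    j = m
    state = 0
    eps = 1e-9
    while i > 0 or j > 0:
        if state == 0:
            if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + S[i - 1, j - 1])) < eps:
                a_cols[k] = i - 1
                b_cols[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif j > 0 and abs(H[i, j] - E[i, j]) < eps:
                state = 1
            else:
                state = 2
        elif state == 1:
            a_cols[k] = -1
            b_cols[k] = j - 1
            k += 1
            if abs(E[i, j] - (H[i, j - 1] - go)) < eps:
                j -= 1
                state = 0
            else:
                j -= 1
            if j == 0 and state == 1:
                state = 0
        else:
            a_cols[k] = i - 1
            b_cols[k] = -1
            k += 1
            if abs(F[i, j] - (H[i - 1, j] - go)) < eps:
                i -= 1
                state = 0
            else:
                i -= 1
            if i == 0 and state == 2:
                state = 0
    return H[n, m], a_cols[:k][::-1].copy(), b_cols[:k][::-1].copy()
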