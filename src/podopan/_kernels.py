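"""Numba dynamic-programming kernels: exact Gotoh local alignment (affine
gaps, BLAST convention: a gap of length k costs open + k*extend) and global
profile-profile alignment for the progressive aligner.

Pointer codes: 0 = stop/origin, 1 = diagonal, 2 = up (gap in second seq),
3 = left (gap in first seq).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**8)


@njit(cache=True)
def gotoh_local(a, b, S, gap_open, gap_extend):
    """Exact Smith-Waterman-Gotoh.  Returns (score, end_i, end_j, pointers,
    state) where pointers/state allow traceback from (end_i, end_j)."""
    m, n = a.shape[0], b.shape[0]
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)  # gap in a (left moves)
    F = np.full((m + 1, n + 1), NEG, np.int32)  # gap in b (up moves)
    ptr = np.zeros((m + 1, n + 1), np.uint8)
    first = gap_open + gap_extend
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            e = E[i][j - 1] - gap_extend
            t = H[i][j - 1] - first
            if t > e:
                e = t
            E[i][j] = e
            f = F[i - 1][j] - gap_extend
            t = H[i - 1][j] - first
            if t > f:
                f = t
            F[i][j] = f
            d = H[i - 1][j - 1] + S[ai, b[j - 1]]
            h = d
            p = 1
            if e > h:
                h = e
                p = 3
            if f > h:
                h = f
                p = 2
            if h <= 0:
                h = 0
                p = 0
            H[i][j] = h
            ptr[i][j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, H, E, F, ptr


@njit(cache=True)
def gotoh_local_score(a, b, S, gap_open, gap_extend):
    """Score-only Gotoh local alignment (linear memory)."""
    n = b.shape[0]
    H = np.zeros(n + 1, np.int32)
    E = np.full(n + 1, NEG, np.int32)
    first = gap_open + gap_extend
    best = 0
    for i in range(a.shape[0]):
        ai = a[i]
        diag = 0
        F = NEG
        for j in range(1, n + 1):
            up = H[j]
            e = E[j] - gap_extend
            t = up - first
            if t > e:
                e = t
            E[j] = e
            f = F - gap_extend
            t = H[j - 1] - first
            if t > f:
                f = t
            F = f
            h = diag + S[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = up
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def profile_global(S, gap_open, gap_extend):
    """Global affine alignment given the (m, n) column-pair score matrix
    ``S``.  Terminal gaps are penalized; a gap of length k costs
    open + k*extend.  Returns the filled (H, E, F) matrices; the traceback
    is decoded by the caller."""
    m, n = S.shape
    H = np.full((m + 1, n + 1), -1e30, np.float64)
    E = np.full((m + 1, n + 1), -1e30, np.float64)
    F = np.full((m + 1, n + 1), -1e30, np.float64)
    first = gap_open + gap_extend
    H[0][0] = 0.0
    for j in range(1, n + 1):
        E[0][j] = -gap_open - gap_extend * j
        H[0][j] = E[0][j]
    for i in range(1, m + 1):
        F[i][0] = -gap_open - gap_extend * i
        H[i][0] = F[i][0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = E[i][j - 1] - gap_extend
            t = H[i][j - 1] - first
            if t > e:
                e = t
            E[i][j] = e
            f = F[i - 1][j] - gap_extend
            t = H[i - 1][j] - first
            if t > f:
                f = t
            F[i][j] = f
            d = H[i - 1][j - 1] + S[i - 1, j - 1]
            h = d
            if e > h:
                h = e
            if f > h:
                h = f
            H[i][j] = h
    return H, E, F


@njit(cache=True)
def pdist_pairs(codes, pair_i, pair_j, cols):
    """Pairwise p-distances over selected columns.

    ``codes``: (n_rows, L) uint8 residue codes with 255 = gap; ``cols``:
    column indices (bootstrap sample or arange).  Returns (p, comparable)
    arrays over the pair list."""
    npairs = pair_i.shape[0]
    out = np.zeros(npairs, np.float64)
    comp = np.zeros(npairs, np.int64)
    for p in range(npairs):
        r1 = codes[pair_i[p]]
        r2 = codes[pair_j[p]]
        mism = 0
        tot = 0
        for c in cols:
            x = r1[c]
            y = r2[c]
            if x != 255 and y != 255:
                tot += 1
                if x != y:
                    mism += 1
        comp[p] = tot
        out[p] = mism / tot if tot > 0 else np.nan
    return out, comp
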