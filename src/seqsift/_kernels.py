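"""Scalar affine-gap DP kernels (numba-jitted).

These are the correctness oracle for the striped kernels and the
algorithmic analog of a naive one-thread-per-alignment GPU kernel.
All kernels use the Gotoh three-state recurrence with the gap-cost
convention: a gap of length L costs ``go + (L - 1) * ge``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(1 << 28)  # effectively -infinity; safe against int64 underflow


@njit(cache=True)
def sw_scalar(S, q, t, go, ge):  # pragma: no cover - exercised via wrappers
    """Smith-Waterman local alignment.

    Returns (score, query_end, target_end) with 0-based inclusive ends,
    (-1, -1) for the empty alignment.  Ties broken by smallest
    target_end, then smallest query_end.
    """
    m = q.shape[0]
    n = t.shape[0]
    h_prev = np.zeros(n + 1, np.int64)
    h_cur = np.zeros(n + 1, np.int64)
    f_col = np.full(n + 1, NEG, np.int64)
    best = 0
    bq = -1
    bt = -1
    for i in range(1, m + 1):
        e = NEG
        h_cur[0] = 0
        qi = q[i - 1]
        for j in range(1, n + 1):
            f = h_prev[j] - go
            fe = f_col[j] - ge
            if fe > f:
                f = fe
            f_col[j] = f
            eo = h_cur[j - 1] - go
            e = e - ge
            if eo > e:
                e = eo
            h = h_prev[j - 1] + S[qi, t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_cur[j] = h
            if h > best:
                best = h
                bq = i - 1
                bt = j - 1
            elif h == best and h > 0:
                if j - 1 < bt or (j - 1 == bt and i - 1 < bq):
                    bq = i - 1
                    bt = j - 1
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    return best, bq, bt


@njit(cache=True)
def sg_scalar(S, q, t, go, ge, free_q_prefix, free_t_prefix):  # pragma: no cover
    """Semi-global DP (no zero floor) under the given prefix boundary flags.

    Returns (last_row, last_col): last_row[j] = H[m][j] for j in 0..n,
    last_col[i] = H[i][n] for i in 0..m.  The suffix-flag reduction over
    these vectors is done by the (shared) Python helper.
    """
    m = q.shape[0]
    n = t.shape[0]
    h_prev = np.empty(n + 1, np.int64)
    h_cur = np.empty(n + 1, np.int64)
    f_col = np.full(n + 1, NEG, np.int64)
    last_col = np.empty(m + 1, np.int64)
    h_prev[0] = 0
    for j in range(1, n + 1):
        h_prev[j] = 0 if free_t_prefix else -(go + (j - 1) * ge)
    last_col[0] = h_prev[n]
    for i in range(1, m + 1):
        h_cur[0] = 0 if free_q_prefix else -(go + (i - 1) * ge)
        e = NEG
        qi = q[i - 1]
        for j in range(1, n + 1):
            f = h_prev[j] - go
            fe = f_col[j] - ge
            if fe > f:
                f = fe
            f_col[j] = f
            eo = h_cur[j - 1] - go
            e = e - ge
            if eo > e:
                e = eo
            h = h_prev[j - 1] + S[qi, t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            h_cur[j] = h
        last_col[i] = h_cur[n]
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    return h_prev.copy(), last_col


@njit(cache=True)
def fill_matrices(S, q, t, go, ge, local, free_q_prefix, free_t_prefix):  # pragma: no cover
    """Full H/E/F matrices for traceback over a (small) prefix rectangle."""
    m = q.shape[0]
    n = t.shape[0]
    H = np.zeros((m + 1, n + 1), np.int64)
    E = np.full((m + 1, n + 1), NEG, np.int64)
    F = np.full((m + 1, n + 1), NEG, np.int64)
    if not local:
        for i in range(1, m + 1):
            H[i, 0] = 0 if free_q_prefix else -(go + (i - 1) * ge)
        for j in range(1, n + 1):
            H[0, j] = 0 if free_t_prefix else -(go + (j - 1) * ge)
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = H[i, j - 1] - go
            ee = E[i, j - 1] - ge
            if ee > e:
                e = ee
            E[i, j] = e
            f = H[i - 1, j] - go
            fe = F[i - 1, j] - ge
            if fe > f:
                f = fe
            F[i, j] = f
            h = H[i - 1, j - 1] + S[qi, t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if local and h < 0:
                h = 0
            H[i, j] = h
    return H, E, F
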