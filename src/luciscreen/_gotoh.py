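"""Affine-gap alignment dynamic programming (Gotoh three-state recurrences).

The fill kernels work on a precomputed column-score matrix so the same code
aligns sequence vs sequence (substitution-matrix lookups) and profile vs
profile (frequency-weighted column scores). A gap of length k costs
``gap_open + (k-1) * gap_extend``.

State convention: M pairs a[i-1] with b[j-1]; X puts a gap in sequence b
(consumes a residue of a); Y puts a gap in sequence a (consumes b).
Traceback prefers M over Y over X on exact score ties, so alignments are
bit-stable across runs and platforms.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def fill_global(sub, gap_open, gap_extend):
    n, m = sub.shape
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            M[i, j] = best + sub[i - 1, j - 1]
            x = M[i - 1, j] - gap_open
            if Y[i - 1, j] - gap_open > x:
                x = Y[i - 1, j] - gap_open
            if X[i - 1, j] - gap_extend > x:
                x = X[i - 1, j] - gap_extend
            X[i, j] = x
            y = M[i, j - 1] - gap_open
            if X[i, j - 1] - gap_open > y:
                y = X[i, j - 1] - gap_open
            if Y[i, j - 1] - gap_extend > y:
                y = Y[i, j - 1] - gap_extend
            Y[i, j] = y
    return M, X, Y


@njit(cache=True)
def fill_local(sub, gap_open, gap_extend):
    n, m = sub.shape
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            v = best + sub[i - 1, j - 1]
            M[i, j] = v if v > 0.0 else 0.0
            x = M[i - 1, j] - gap_open
            if Y[i - 1, j] - gap_open > x:
                x = Y[i - 1, j] - gap_open
            if X[i - 1, j] - gap_extend > x:
                x = X[i - 1, j] - gap_extend
            X[i, j] = x
            y = M[i, j - 1] - gap_open
            if X[i, j - 1] - gap_open > y:
                y = X[i, j - 1] - gap_open
            if Y[i, j - 1] - gap_extend > y:
                y = Y[i, j - 1] - gap_extend
            Y[i, j] = y
    return M, X, Y


_M, _Y, _X = 0, 1, 2  # priority order on ties: M > Y > X


def _pick(m_ok: float, y_ok: float, x_ok: float) -> int:
    best = max(m_ok, y_ok, x_ok)
    if m_ok == best:
        return _M
    if y_ok == best:
        return _Y
    return _X


def _eq(v: float, target: float) -> float:
    return 0.0 if abs(v - target) < 1e-9 else NEG


def _step_back(state, i, j, M, X, Y, sub, gap_open, gap_extend):
    """One traceback step; returns (op, next_state, i, j)."""
    if state == _M:
        target = M[i, j] - sub[i - 1, j - 1]
        nxt = _pick(
            _eq(M[i - 1, j - 1], target),
            _eq(Y[i - 1, j - 1], target),
            _eq(X[i - 1, j - 1], target),
        )
        return "M", nxt, i - 1, j - 1
    if state == _X:
        target = X[i, j]
        nxt = _pick(
            _eq(M[i - 1, j] - gap_open, target),
            _eq(Y[i - 1, j] - gap_open, target),
            _eq(X[i - 1, j] - gap_extend, target),
        )
        return "X", nxt, i - 1, j
    target = Y[i, j]
    nxt = _pick(
        _eq(M[i, j - 1] - gap_open, target),
        _eq(Y[i, j - 1] - gap_extend, target),
        _eq(X[i, j - 1] - gap_open, target),
    )
    return "Y", nxt, i, j - 1


def traceback_global(M, X, Y, sub, gap_open, gap_extend):
    """Return (score, ops): ops is a left-to-right list of column types,
    'M' residue-residue, 'X' gap in b, 'Y' gap in a."""
    n, m = M.shape[0] - 1, M.shape[1] - 1
    state = _pick(
        _eq(M[n, m], max(M[n, m], X[n, m], Y[n, m])),
        _eq(Y[n, m], max(M[n, m], X[n, m], Y[n, m])),
        _eq(X[n, m], max(M[n, m], X[n, m], Y[n, m])),
    )
    score = (M[n, m], Y[n, m], X[n, m])[state]
    ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        op, state, i, j = _step_back(state, i, j, M, X, Y, sub, gap_open, gap_extend)
        ops.append(op)
    ops.reverse()
    return float(score), ops


def traceback_local(M, X, Y, sub, gap_open, gap_extend):
    """Return (score, ops, a_start, b_start, a_end, b_end); 0-based
    half-open coordinates into the input sequences; empty ops when no
    positive-scoring segment pair exists.

    Best cells are scanned in ascending (i, j) order with strict '>' so the
    first maximum wins; local alignments start and end in state M.
    """
    n, m = M.shape[0] - 1, M.shape[1] - 1
    best = 0.0
    bi = bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if M[i, j] > best:
                best = M[i, j]
                bi, bj = i, j
    if best <= 0.0:
        return 0.0, [], 0, 0, 0, 0
    ops: list[str] = []
    state = _M
    i, j = bi, bj
    while True:
        if state == _M and abs(M[i, j] - sub[i - 1, j - 1]) < 1e-9:
            # predecessor value is 0: this column starts the alignment
            ops.append("M")
            i -= 1
            j -= 1
            break
        op, state, i, j = _step_back(state, i, j, M, X, Y, sub, gap_open, gap_extend)
        ops.append(op)
    ops.reverse()
    return float(best), ops, i, j, bi, bj
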