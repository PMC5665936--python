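"""Affine-gap dynamic-programming kernels (numba).

Conventions shared by all kernels:

* sequences are int8 code arrays (A=0, C=1, G=2, T=3, other=4);
* ``S`` is a float64 (5, 5) substitution score matrix;
* a gap of length L scores ``go + ge * L`` (open + per-base extend);
* traceback pointers are packed per cell into one uint8:
  bits 0-2 = H-state source (0 start, 1 diagonal, 2 wrap-diagonal, 3 E, 4 F),
  bit 3 = E opened from H, bit 4 = F opened from H.

Op codes emitted by tracebacks: 0 '=', 1 'X', 2 'I' (query only),
3 'D' (reference only).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e18

SRC_MASK = 0b111
SRC_STOP = 0
SRC_DIAG = 1
SRC_WRAP = 2
SRC_E = 3
SRC_F = 4
E_OPEN = 0b01000
F_OPEN = 0b10000


@njit(cache=True)
def sw_full(q, r, S, go, ge):
    """Full local Smith-Waterman with affine gaps. Returns (best, bi, bj, ptr)."""
    n = q.shape[0]
    m = r.shape[0]
    ptr = np.zeros((n + 1, m + 1), np.uint8)
    Hprev = np.zeros(m + 1, np.float64)
    Hcur = np.zeros(m + 1, np.float64)
    Eprev = np.full(m + 1, NEG, np.float64)
    Ecur = np.full(m + 1, NEG, np.float64)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        Hcur[0] = 0.0
        f = NEG
        for j in range(1, m + 1):
            p = np.uint8(0)
            eo = Hprev[j] + go + ge
            ee = Eprev[j] + ge
            if eo >= ee:
                e = eo
                p |= E_OPEN
            else:
                e = ee
            Ecur[j] = e
            fo = Hcur[j - 1] + go + ge
            fe = f + ge
            if fo >= fe:
                f = fo
                p |= F_OPEN
            else:
                f = fe
            d = Hprev[j - 1] + S[q[i - 1], r[j - 1]]
            h = 0.0
            src = SRC_STOP
            if d > h:
                h = d
                src = SRC_DIAG
            if e > h:
                h = e
                src = SRC_E
            if f > h:
                h = f
                src = SRC_F
            Hcur[j] = h
            ptr[i, j] = p | np.uint8(src)
            if h > best:
                best = h
                bi = i
                bj = j
        for j in range(m + 1):
            Hprev[j] = Hcur[j]
            Eprev[j] = Ecur[j]
    return best, bi, bj, ptr


@njit(cache=True)
def tb_full(ptr, q, r, bi, bj):
    """Traceback for sw_full from (bi, bj); returns reversed op codes."""
    n = ptr.shape[0] - 1 + ptr.shape[1] - 1
    ops = np.empty(2 * n + 16, np.int8)
    k = 0
    i = bi
    j = bj
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 or j > 0:
        p = ptr[i, j]
        if state == 0:
            src = p & SRC_MASK
            if src == SRC_STOP:
                break
            if src == SRC_DIAG:
                ops[k] = 0 if q[i - 1] == r[j - 1] else 1
                k += 1
                i -= 1
                j -= 1
            elif src == SRC_E:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 2
            k += 1
            if p & E_OPEN:
                state = 0
            i -= 1
        else:
            ops[k] = 3
            k += 1
            if p & F_OPEN:
                state = 0
            j -= 1
    return ops[:k], i, j


@njit(cache=True)
def banded(q, r, S, go, ge, dlo, dhi, local):
    """Banded affine DP on diagonals d = j - i in [dlo, dhi].

    local=0: query-global, reference ends free (glocal); best cell is in the
    last row.  local=1: local on both (Smith-Waterman within the band).
    Returns (best, bi, bw, ptr) with w = j - i - dlo.
    """
    n = q.shape[0]
    m = r.shape[0]
    W = dhi - dlo + 1
    ptr = np.zeros((n + 1, W), np.uint8)
    Hprev = np.full(W, NEG, np.float64)
    Hcur = np.full(W, NEG, np.float64)
    Eprev = np.full(W, NEG, np.float64)
    Ecur = np.full(W, NEG, np.float64)
    for w in range(W):
        j = dlo + w
        if 0 <= j <= m:
            Hprev[w] = 0.0
    best = NEG
    if local:
        best = 0.0
    bi = 0
    bw = 0
    for i in range(1, n + 1):
        f = NEG
        for w in range(W):
            j = i + dlo + w
            Hcur[w] = NEG
            Ecur[w] = NEG
            if j < 1 or j > m:
                if j == 0:
                    # vertical-only column: query base deleted before ref start
                    p = np.uint8(0)
                    eo = Hprev[w + 1] + go + ge if w + 1 < W else NEG
                    ee = Eprev[w + 1] + ge if w + 1 < W else NEG
                    if eo >= ee:
                        e = eo
                        p |= E_OPEN
                    else:
                        e = ee
                    Ecur[w] = e
                    h = e
                    src = SRC_E
                    if local and 0.0 >= h:
                        h = 0.0
                        src = SRC_STOP
                    Hcur[w] = h
                    ptr[i, w] = p | np.uint8(src)
                f = NEG
                continue
            p = np.uint8(0)
            # E: from (i-1, j) -> band w+1 in previous row
            eo = Hprev[w + 1] + go + ge if w + 1 < W else NEG
            ee = Eprev[w + 1] + ge if w + 1 < W else NEG
            if eo >= ee:
                e = eo
                p |= E_OPEN
            else:
                e = ee
            Ecur[w] = e
            # F: from (i, j-1) -> band w-1 in same row
            fo = Hcur[w - 1] + go + ge if w >= 1 else NEG
            fe = f + ge
            if fo >= fe:
                fnew = fo
                p |= F_OPEN
            else:
                fnew = fe
            f = fnew
            # diagonal: from (i-1, j-1) -> same w in previous row
            d = Hprev[w] + S[q[i - 1], r[j - 1]]
            h = d
            src = SRC_DIAG
            if e > h:
                h = e
                src = SRC_E
            if f > h:
                h = f
                src = SRC_F
            if local and 0.0 >= h:
                h = 0.0
                src = SRC_STOP
            Hcur[w] = h
            ptr[i, w] = p | np.uint8(src)
            if local:
                if h > best:
                    best = h
                    bi = i
                    bw = w
            elif i == n and h > best:
                best = h
                bi = i
                bw = w
        for w in range(W):
            Hprev[w] = Hcur[w]
            Eprev[w] = Ecur[w]
    return best, bi, bw, ptr


@njit(cache=True)
def tb_banded(ptr, q, r, bi, bw, dlo, local):
    """Traceback for banded(); returns (reversed ops, end_i, end_j)."""
    n = ptr.shape[0] - 1
    ops = np.empty(2 * (n + ptr.shape[1]) + 16, np.int8)
    k = 0
    i = bi
    w = bw
    state = 0
    while i > 0:
        p = ptr[i, w]
        j = i + dlo + w
        if state == 0:
            src = p & SRC_MASK
            if src == SRC_STOP:
                if local:
                    break
                else:
                    break
            if src == SRC_DIAG:
                ops[k] = 0 if q[i - 1] == r[j - 1] else 1
                k += 1
                i -= 1
            elif src == SRC_E:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 2
            k += 1
            if p & E_OPEN:
                state = 0
            i -= 1
            w += 1
        else:
            ops[k] = 3
            k += 1
            if p & F_OPEN:
                state = 0
            w -= 1
    return ops[:k], i, i + dlo + w


@njit(cache=True)
def wrap(q, u, S, go, ge):
    """Wraparound DP: query-global vs a single unit with free end-to-start
    return on the diagonal. Start position within the unit is free.
    Returns (best, bj, ptr)."""
    n = q.shape[0]
    m = u.shape[0]
    ptr = np.zeros((n + 1, m + 1), np.uint8)
    Hprev = np.zeros(m + 1, np.float64)
    Hcur = np.full(m + 1, NEG, np.float64)
    Eprev = np.full(m + 1, NEG, np.float64)
    Ecur = np.full(m + 1, NEG, np.float64)
    Hprev[0] = NEG  # column 0 unused after row 0
    for i in range(1, n + 1):
        Hcur[0] = NEG
        f = NEG
        for j in range(1, m + 1):
            p = np.uint8(0)
            eo = Hprev[j] + go + ge
            ee = Eprev[j] + ge
            if eo >= ee:
                e = eo
                p |= E_OPEN
            else:
                e = ee
            Ecur[j] = e
            if j >= 2:
                fo = Hcur[j - 1] + go + ge
                fe = f + ge
                if fo >= fe:
                    f = fo
                    p |= F_OPEN
                else:
                    f = fe
            else:
                f = NEG
            if j == 1:
                d = Hprev[m] + S[q[i - 1], u[0]]
                dsrc = SRC_WRAP
            else:
                d = Hprev[j - 1] + S[q[i - 1], u[j - 1]]
                dsrc = SRC_DIAG
            h = d
            src = dsrc
            if e > h:
                h = e
                src = SRC_E
            if f > h:
                h = f
                src = SRC_F
            Hcur[j] = h
            ptr[i, j] = p | np.uint8(src)
        for j in range(m + 1):
            Hprev[j] = Hcur[j]
            Eprev[j] = Ecur[j]
    best = NEG
    bj = 1
    for j in range(1, m + 1):
        if Hprev[j] > best:
            best = Hprev[j]
            bj = j
    return best, bj, ptr


@njit(cache=True)
def tb_wrap(ptr, q, u, bj):
    """Traceback for wrap(); returns reversed (ops, unit columns, wrap flags)."""
    n = ptr.shape[0] - 1
    m = ptr.shape[1] - 1
    cap = 3 * (n + m) + 16
    ops = np.empty(cap, np.int8)
    cols = np.empty(cap, np.int32)
    wraps = np.empty(cap, np.int8)
    k = 0
    i = n
    j = bj
    state = 0
    while i > 0:
        p = ptr[i, j]
        if state == 0:
            src = p & SRC_MASK
            if src == SRC_DIAG or src == SRC_WRAP:
                ops[k] = 0 if q[i - 1] == u[j - 1] else 1
                cols[k] = j
                wraps[k] = 1 if src == SRC_WRAP else 0
                k += 1
                i -= 1
                j = m if src == SRC_WRAP else j - 1
            elif src == SRC_E:
                state = 1
            elif src == SRC_F:
                state = 2
            else:
                break
        elif state == 1:
            ops[k] = 2
            cols[k] = j
            wraps[k] = 0
            k += 1
            if p & E_OPEN:
                state = 0
            i -= 1
        else:
            ops[k] = 3
            cols[k] = j
            wraps[k] = 0
            k += 1
            if p & F_OPEN:
                state = 0
            j -= 1
    return ops[:k], cols[:k], wraps[:k]
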