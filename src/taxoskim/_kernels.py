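"""Numba dynamic-programming kernels for the alignment engine.

One banded Gotoh local-alignment kernel serves both paths of the aligner:
with a full-width band it is exhaustive Smith-Waterman (used for short
pairs), with a narrow band around seed diagonals it is the gapped
extension stage. A linear-gap Needleman-Wunsch kernel backs global
(end-to-end) comparisons. Pointer matrices come back to Python, where the
traceback reconstructs column-level operations.

Sequences are int8-coded (A=0, C=1, G=2, T=3, N=4); N never scores as a
match.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10 ** 9)

# pointer codes (H matrix): 0 stop, 1 diagonal, 2 from E (gap in subject
# direction, consumes subject), 3 from F (consumes query)
# E/F pointers: 0 = gap open (came from H), 1 = gap extend


@njit(cache=True)
def banded_gotoh_local(q, s, dlo, dhi, match, mismatch, gap_open, gap_extend):
    """Banded affine-gap Smith-Waterman over diagonals j-i in [dlo, dhi].

    Returns (best_score, best_i, best_k, ptrH, ptrE, ptrF) with band
    coordinate k = j - i - dlo.
    """
    m = len(q)
    n = len(s)
    w = dhi - dlo + 1
    H = np.full((m + 1, w), NEG, dtype=np.int64)
    E = np.full((m + 1, w), NEG, dtype=np.int64)
    F = np.full((m + 1, w), NEG, dtype=np.int64)
    ptrH = np.zeros((m + 1, w), dtype=np.uint8)
    ptrE = np.zeros((m + 1, w), dtype=np.uint8)
    ptrF = np.zeros((m + 1, w), dtype=np.uint8)

    for i in range(m + 1):
        for k in range(w):
            j = i + dlo + k
            if 0 <= j <= n:
                if i == 0 or j == 0:
                    H[i, k] = 0

    best = 0
    bi = 0
    bk = 0
    for i in range(1, m + 1):
        for k in range(w):
            j = i + dlo + k
            if j < 1 or j > n:
                continue
            qa = q[i - 1]
            sb = s[j - 1]
            sub = match if (qa == sb and qa < 4) else mismatch

            diag = H[i - 1, k]
            hd = diag + sub if diag > NEG // 2 else NEG

            e = NEG
            pe = 0
            if k - 1 >= 0:
                ho = H[i, k - 1]
                eo = E[i, k - 1]
                if ho > NEG // 2 and ho - gap_open - gap_extend > e:
                    e = ho - gap_open - gap_extend
                    pe = 0
                if eo > NEG // 2 and eo - gap_extend > e:
                    e = eo - gap_extend
                    pe = 1
            E[i, k] = e
            ptrE[i, k] = pe

            f = NEG
            pf = 0
            if k + 1 < w:
                ho = H[i - 1, k + 1]
                fo = F[i - 1, k + 1]
                if ho > NEG // 2 and ho - gap_open - gap_extend > f:
                    f = ho - gap_open - gap_extend
                    pf = 0
                if fo > NEG // 2 and fo - gap_extend > f:
                    f = fo - gap_extend
                    pf = 1
            F[i, k] = f
            ptrF[i, k] = pf

            h = 0
            p = 0
            if hd > h:
                h = hd
                p = 1
            if e > h:
                h = e
                p = 2
            if f > h:
                h = f
                p = 3
            H[i, k] = h
            ptrH[i, k] = p
            if h > best:
                best = h
                bi = i
                bk = k
    return best, bi, bk, ptrH, ptrE, ptrF


@njit(cache=True)
def nw_global_linear(q, s, match, mismatch, gap):
    """Linear-gap global alignment; returns (score, ptr) where ptr codes
    1=diagonal, 2=gap consuming subject, 3=gap consuming query."""
    m = len(q)
    n = len(s)
    prev = np.empty(n + 1, dtype=np.int64)
    cur = np.empty(n + 1, dtype=np.int64)
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)
    for j in range(n + 1):
        prev[j] = j * gap
        if j > 0:
            ptr[0, j] = 2
    for i in range(1, m + 1):
        cur[0] = i * gap
        ptr[i, 0] = 3
        qa = q[i - 1]
        for j in range(1, n + 1):
            sb = s[j - 1]
            sub = match if (qa == sb and qa < 4) else mismatch
            d = prev[j - 1] + sub
            l = cur[j - 1] + gap
            u = prev[j] + gap
            # deterministic preference: diagonal, then subject-gap, then query-gap
            bestv = d
            p = 1
            if l > bestv:
                bestv = l
                p = 2
            if u > bestv:
                bestv = u
                p = 3
            cur[j] = bestv
            ptr[i, j] = p
        prev, cur = cur, prev
    return prev[n], ptr
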