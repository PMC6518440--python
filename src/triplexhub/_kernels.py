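"""Compiled window-enumeration kernels for the triplex engine.

The search space for one RNA/DNA pair is every (RNA window, DNA window,
strand, orientation, motif) combination.  Windows of a fixed orientation
live on (anti)diagonals of the RNA x purine-strand pairing matrix, so each
(anti)diagonal is reduced to a binary match/mismatch vector and windows are
enumerated from the mismatch positions directly: a window with exactly j
mismatches is delimited by a consecutive block of j mismatch positions plus
a start in the match run before the block and an end in the match run after
it.  A window of length L tolerates floor(max_error_rate/100 * L)
mismatches, i.e. a window carrying j mismatches needs L >= 100*j/rate, so
for each block start the block size j is advanced only while some longer
block could still reach its required length (a suffix-maximum bound over
"gap minus 100/rate" increments).  On random sequence mismatches are dense
and the scan is effectively linear per diagonal; enumeration cost beyond
that is proportional to the number of emitted windows.
"""

from __future__ import annotations

import numpy as np
from numba import njit, types
from numba.typed import List as NumbaList

_EPS = 1e-9


@njit(cache=True)
def _emit_block(out, M, i, jj, min_len, err_pct, terminal, i0, j0, antiparallel):
    """Emit all windows whose mismatch set is the block M[i..i+jj-1]."""
    prev = M[i - 1]
    m_lo = M[i]
    m_hi = M[i + jj - 1]
    nxt = M[i + jj]
    if terminal:
        s_lo, s_hi = prev + 1, m_lo - 1
        e_lo, e_hi = m_hi + 1, nxt - 1
    else:
        s_lo, s_hi = prev + 1, m_lo
        e_lo, e_hi = m_hi, nxt - 1
    lreq_err = int(np.ceil(100.0 * jj / err_pct - _EPS))
    lreq = lreq_err if lreq_err > min_len else min_len
    for s in range(s_lo, s_hi + 1):
        e_min = s + lreq - 1
        if e_min < e_lo:
            e_min = e_lo
        for e in range(e_min, e_hi + 1):
            L = e - s + 1
            rna_start = i0 + s
            if antiparallel:
                pstart = j0 - s - L + 1
            else:
                pstart = j0 + s
            out.append(rna_start)
            out.append(pstart)
            out.append(L)
            out.append(jj)


@njit(cache=True)
def _process_diag(R, P, valid, i0, j0, jstep, D, min_len, err_pct, terminal,
                  out, M, W, B):
    """Enumerate qualifying windows along one (anti)diagonal of length D."""
    antiparallel = jstep < 0
    # Collect mismatch positions (diagonal-local) with sentinels.
    t = 0
    M[0] = -1
    for k in range(D):
        if not valid[R[i0 + k], P[j0 + jstep * k]]:
            t += 1
            M[t] = k
    M[t + 1] = D

    # Zero-mismatch windows: every sub-window of every long-enough match run.
    for idx in range(t + 1):
        lo = M[idx] + 1
        hi = M[idx + 1] - 1
        run = hi - lo + 1
        if run >= min_len:
            for L in range(min_len, run + 1):
                for s in range(lo, hi - L + 2):
                    rna_start = i0 + s
                    if antiparallel:
                        pstart = j0 - s - L + 1
                    else:
                        pstart = j0 + s
                    out.append(rna_start)
                    out.append(pstart)
                    out.append(L)
                    out.append(0)

    if err_pct <= 0.0 or t == 0:
        return

    # W[k]: change in feasibility slack when the block absorbs mismatch k+1;
    # B[k]: best cumulative future change starting at k (suffix max).
    for k in range(1, t + 1):
        W[k] = err_pct * (M[k + 1] - M[k]) - 100.0
    B[t] = W[t]
    for k in range(t - 1, 0, -1):
        s = W[k] + B[k + 1]
        B[k] = W[k] if W[k] > s else s

    for i in range(1, t + 1):
        prev = M[i - 1]
        # F = err_pct * max_span - 100*jj ; feasible iff F >= 0.
        F = err_pct * (M[i + 1] - prev - 1) - 100.0
        jj = 1
        while True:
            if F >= -_EPS:
                _emit_block(out, M, i, jj, min_len, err_pct, terminal,
                            i0, j0, antiparallel)
            k = i + jj
            if k > t:
                break
            if F + B[k] < -_EPS:
                break
            F += W[k]
            jj += 1


@njit(cache=True)
def _scan_pair(R, P, valid, antiparallel, min_len, err_pct, terminal):
    """All qualifying windows of one motif/orientation on one purine strand.

    Returns a flat int64 list: (rna_start, purine_strand_start, length,
    n_mismatches) per window.  ``P`` is the purine-strand sequence in its
    own 5'->3' order.
    """
    n = len(R)
    p = len(P)
    out = NumbaList.empty_list(types.int64)
    if n < min_len or p < min_len:
        return out
    size = min(n, p) + 2
    M = np.empty(size, dtype=np.int64)
    W = np.empty(size, dtype=np.float64)
    B = np.empty(size, dtype=np.float64)
    if not antiparallel:
        for d in range(-(n - 1), p):
            i0 = -d if d < 0 else 0
            j0 = i0 + d
            D = min(n - i0, p - j0)
            if D >= min_len:
                _process_diag(R, P, valid, i0, j0, 1, D, min_len, err_pct,
                              terminal, out, M, W, B)
    else:
        for c in range(n + p - 1):
            i0 = c - (p - 1) if c > p - 1 else 0
            j0 = c - i0
            D = min(n - i0, j0 + 1)
            if D >= min_len:
                _process_diag(R, P, valid, i0, j0, -1, D, min_len, err_pct,
                              terminal, out, M, W, B)
    return out
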