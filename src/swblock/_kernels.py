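"""Numba-compiled dynamic-programming kernels.

Two independent code paths live here on purpose:

* :func:`full_matrices` materialises the complete H/E/F matrices with the
  textbook double loop.  It is the reference oracle for tests and for small
  inputs; memory is O(m*n).
* :func:`block_kernel` computes one vertical block of BW columns with O(BW)
  row buffers plus the H/E boundary columns exchanged between blocks.  The
  score-only engine for long pairs is built from repeated block invocations.

Residues are encoded as uint8 codes: A=0, C=1, G=2, T=3, anything else
(including N and the pad symbol) = 4.  Two residues match iff their codes are
equal *and* below 4, so non-ACGT residues mismatch everything, themselves
included.

All arithmetic is int64; narrower integer widths are enforced a priori by the
overflow guard in :mod:`swblock.core`, never by saturating arithmetic here.
"""

import numpy as np
from numba import njit

__all__ = ["full_matrices", "block_kernel"]


@njit(cache=True)
def full_matrices(a, b, match, mismatch, gap_open, gap_extend):
    """Full H, E, F matrices (shape (m+1, n+1)) with zero borders.

    Row/column 0 hold the i=0 / j=0 initialisation (all three matrices 0).
    """
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1), np.int64)
    E = np.zeros((m + 1, n + 1), np.int64)
    F = np.zeros((m + 1, n + 1), np.int64)
    oe = gap_open + gap_extend
    for i in range(1, m + 1):
        ca = a[i - 1]
        for j in range(1, n + 1):
            e = H[i, j - 1] - oe
            t = E[i, j - 1] - gap_extend
            if t > e:
                e = t
            f = H[i - 1, j] - oe
            t = F[i - 1, j] - gap_extend
            if t > f:
                f = t
            if ca == b[j - 1] and ca < 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if h < 0:
                h = 0
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
    return H, E, F


@njit(cache=True)
def block_kernel(a, block, match, mismatch, gap_open, gap_extend,
                 h_in, e_in, h_out, e_out):
    """Process one BW-wide vertical block row by row, top to bottom.

    ``h_in``/``e_in`` are the previous block's last-column H and E values for
    rows 1..m (index i-1); an all-zero pair encodes the j=0 initialisation
    column.  ``h_out``/``e_out`` (same layout) receive this block's last
    column.  Only the two length-BW row buffers for H and F are kept inside.

    Returns ``(block_max, max_i, max_jj)`` where ``max_jj`` is 1-based within
    the block and ``(max_i, max_jj) = (0, 0)`` when no cell is positive.  The
    first maximal cell in the row-by-row scan order is reported, which is
    row-major order within the block.
    """
    m = a.shape[0]
    bw = block.shape[0]
    oe = gap_open + gap_extend
    h_row = np.zeros(bw, np.int64)
    f_row = np.zeros(bw, np.int64)
    best = np.int64(0)
    bi = np.int64(0)
    bj = np.int64(0)
    h = np.int64(0)
    e = np.int64(0)
    for i in range(1, m + 1):
        ca = a[i - 1]
        if i >= 2:
            diag = h_in[i - 2]
        else:
            diag = np.int64(0)
        h_left = h_in[i - 1]
        e_left = e_in[i - 1]
        for jj in range(bw):
            e = h_left - oe
            t = e_left - gap_extend
            if t > e:
                e = t
            f = h_row[jj] - oe
            t = f_row[jj] - gap_extend
            if t > f:
                f = t
            if ca == block[jj] and ca < 4:
                s = match
            else:
                s = mismatch
            h = diag + s
            if h < 0:
                h = 0
            if e > h:
                h = e
            if f > h:
                h = f
            diag = h_row[jj]
            h_row[jj] = h
            f_row[jj] = f
            h_left = h
            e_left = e
            if h > best:
                best = h
                bi = i
                bj = jj + 1
        h_out[i - 1] = h
        e_out[i - 1] = e
    return best, bi, bj
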