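"""Numba kernels for the pair-prefix dynamic programs.

The SA-model forward recurrence

    F(i, j) = em[x_i, y_j] F(i-1, j-1) + ed[x_i] F(i-1, j) + ei[y_j] F(i, j-1)

with F(0, 0) = 1 is run in linear space with per-row rescaling (the log of
the scale is accumulated), so reads of arbitrary length cannot underflow.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["sa_forward_scaled", "sa_semiglobal_llr"]


@njit(cache=True, fastmath=True)
def sa_forward_scaled(xi, yi, em, ei, ed):
    """log F(|x|, |y|): joint probability of consuming both sequences.

    ``em`` already includes the q_match factor (shape (n, n)); ``ei`` and
    ``ed`` include q_insertion / q_deletion (shape (n,)).
    """
    n = xi.shape[0]
    m = yi.shape[0]
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    prev[0] = 1.0
    for j in range(1, m + 1):
        prev[j] = prev[j - 1] * ei[yi[j - 1]]
    log_scale = 0.0
    for i in range(1, n + 1):
        d_fac = ed[xi[i - 1]]
        cur[0] = prev[0] * d_fac
        best = cur[0]
        for j in range(1, m + 1):
            v = (
                em[xi[i - 1], yi[j - 1]] * prev[j - 1]
                + d_fac * prev[j]
                + ei[yi[j - 1]] * cur[j - 1]
            )
            cur[j] = v
            if v > best:
                best = v
        if best <= 0.0:
            return -np.inf
        inv = 1.0 / best
        for j in range(m + 1):
            cur[j] *= inv
        log_scale += math.log(best)
        tmp = prev
        prev = cur
        cur = tmp
    if prev[m] <= 0.0:
        return -np.inf
    return math.log(prev[m]) + log_scale


@njit(cache=True, fastmath=True)
def sa_semiglobal_llr(xi, yi, rm, ri, rd):
    """Log-likelihood ratio with free x flanks (y fully consumed).

    The recurrence runs in ratio space: ``rm[a, b]`` is the match-column
    factor divided by the background probability of both characters, and
    ``ri`` / ``rd`` are the insertion / deletion factors divided by the
    background probability of the emitted character.  Unconsumed x flanks
    are generated by the background model, so they contribute factor 1;
    the result sums alignments over every x sub-interval.  Alignments are
    canonicalized to never begin with a deletion column (a leading
    deletion is the same configuration as a shorter window with that
    character in the flank), which is why column 0 holds only the fresh
    start and is not extended by the deletion factor.

    Row maxima are rescaled out.  The unscaled row maximum is always
    >= 1 because a fresh alignment may start at any row, so the running
    scale never goes negative; terms that underflow relative to it are
    negligible in the sum.
    """
    n = xi.shape[0]
    m = yi.shape[0]
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    prev[0] = 1.0
    for j in range(1, m + 1):
        prev[j] = prev[j - 1] * ri[yi[j - 1]]
    log_scale = 0.0
    total = math.log(prev[m]) if prev[m] > 0.0 else -np.inf
    for i in range(1, n + 1):
        d_fac = rd[xi[i - 1]]
        cur[0] = math.exp(-log_scale)  # fresh alignment start, factor 1
        best = cur[0]
        for j in range(1, m + 1):
            v = (
                rm[xi[i - 1], yi[j - 1]] * prev[j - 1]
                + d_fac * prev[j]
                + ri[yi[j - 1]] * cur[j - 1]
            )
            cur[j] = v
            if v > best:
                best = v
        if cur[m] > 0.0:
            contrib = math.log(cur[m]) + log_scale
            if contrib > total:
                total, contrib = contrib, total
            total = total + math.log1p(math.exp(contrib - total))
        inv = 1.0 / best
        for j in range(m + 1):
            cur[j] *= inv
        log_scale += math.log(best)
        tmp = prev
        prev = cur
        cur = tmp
    return total
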