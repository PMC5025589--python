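"""Numba kernels for the per-position HMM recursions.

Pure log-space dynamic programming; the surrounding bookkeeping (masks,
pseudocounts, expected-count accumulation) stays in numpy.  The emission
matrix passed in has 21 columns: the 20 canonical letters plus the
class-neutral ambiguity column, addressed by symbol code -1.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NEG_INF = -np.inf


@njit(cache=True)
def forward_lattice(logpi, logT, logB, codes):
    L = codes.shape[0]
    n = logpi.shape[0]
    alpha = np.empty((L, n))
    for i in range(n):
        alpha[0, i] = logpi[i] + logB[i, codes[0]]
    for t in range(1, L):
        for j in range(n):
            m = _NEG_INF
            for i in range(n):
                v = alpha[t - 1, i] + logT[i, j]
                if v > m:
                    m = v
            if m == _NEG_INF:
                alpha[t, j] = _NEG_INF
            else:
                s = 0.0
                for i in range(n):
                    v = alpha[t - 1, i] + logT[i, j]
                    if v != _NEG_INF:
                        s += np.exp(v - m)
                alpha[t, j] = m + np.log(s) + logB[j, codes[t]]
    return alpha


@njit(cache=True)
def backward_lattice(logT, logB, codes):
    L = codes.shape[0]
    n = logT.shape[0]
    beta = np.empty((L, n))
    for i in range(n):
        beta[L - 1, i] = 0.0
    for t in range(L - 2, -1, -1):
        for i in range(n):
            m = _NEG_INF
            for j in range(n):
                v = logT[i, j] + logB[j, codes[t + 1]] + beta[t + 1, j]
                if v > m:
                    m = v
            if m == _NEG_INF:
                beta[t, i] = _NEG_INF
            else:
                s = 0.0
                for j in range(n):
                    v = logT[i, j] + logB[j, codes[t + 1]] + beta[t + 1, j]
                    if v != _NEG_INF:
                        s += np.exp(v - m)
                beta[t, i] = m + np.log(s)
    return beta


@njit(cache=True)
def viterbi_lattice(logpi, logT, logB, codes):
    """Final delta row and backpointers; strict `>` updates keep the
    lowest-index predecessor on ties."""
    L = codes.shape[0]
    n = logpi.shape[0]
    delta = np.empty(n)
    for i in range(n):
        delta[i] = logpi[i] + logB[i, codes[0]]
    psi = np.zeros((L, n), dtype=np.int64)
    nxt = np.empty(n)
    for t in range(1, L):
        for j in range(n):
            best = _NEG_INF
            arg = 0
            for i in range(n):
                v = delta[i] + logT[i, j]
                if v > best:
                    best = v
                    arg = i
            psi[t, j] = arg
            nxt[j] = best + logB[j, codes[t]]
        for j in range(n):
            delta[j] = nxt[j]
    return delta, psi
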