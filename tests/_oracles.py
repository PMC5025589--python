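"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming code paths:
likelihoods come from explicit enumeration of every state path, threshold
quality from an exhaustive scan, and the scaled-arithmetic forward from a
linear-space recursion with per-position renormalisation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from tahmm.alphabet import AMBIGUOUS_CODE, N_SYMBOLS
from tahmm.hmm import PSEUDOCOUNT, HmmParameters


def _log_emit(params: HmmParameters, state: int, code: int) -> float:
    if code == AMBIGUOUS_CODE:
        return -math.log(N_SYMBOLS)
    return float(params.log_emission[state, code])


def path_log_prob(params: HmmParameters, codes, path) -> float:
    lp = float(params.log_initial[path[0]]) + _log_emit(params, path[0], codes[0])
    for t in range(1, len(codes)):
        lp += float(params.log_transition[path[t - 1], path[t]])
        lp += _log_emit(params, path[t], codes[t])
    return lp


def enumerate_paths(params: HmmParameters, codes):
    n = params.n_states
    for path in itertools.product(range(n), repeat=len(codes)):
        yield path, path_log_prob(params, codes, path)


def brute_force_forward(params: HmmParameters, codes) -> float:
    logs = [lp for _, lp in enumerate_paths(params, codes)]
    m = max(logs)
    if m == -math.inf:
        return -math.inf
    return m + math.log(sum(math.exp(v - m) for v in logs))

def brute_force_viterbi(params: HmmParameters, codes):
    best_path, best = None, -math.inf
    for path, lp in enumerate_paths(params, codes):
        if lp > best:
            best_path, best = path, lp
    return best_path, best


def scaled_forward(params: HmmParameters, codes) -> float:
    """Linear-space forward with per-position renormalisation; returns the
    log-likelihood as the sum of log scale factors."""
    with np.errstate(under="ignore"):
        pi = np.exp(params.log_initial)
        T = np.exp(np.where(params.transition_mask, params.log_transition, -np.inf))
        B = np.exp(params.log_emission)
    Bext = np.hstack([B, np.full((params.n_states, 1), 1.0 / N_SYMBOLS)])
    v = pi * Bext[:, codes[0]]
    log_scale = 0.0
    c = v.sum()
    v /= c
    log_scale += math.log(c)
    for t in range(1, len(codes)):
        v = (v @ T) * Bext[:, codes[t]]
        c = v.sum()
        v /= c
        log_scale += math.log(c)
    return log_scale


def exhaustive_ber_scan(pos, neg):
    """Minimal BER over every midpoint/sentinel candidate threshold."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    values = np.unique(np.concatenate([pos, neg]))
    cands = [-math.inf, math.inf] + [
        (a + b) / 2 for a, b in zip(values[:-1], values[1:])
    ]
    bers = []
    for thr in cands:
        fn = np.count_nonzero(pos < thr) / pos.size
        fp = np.count_nonzero(neg >= thr) / neg.size
        bers.append((fn + fp) / 2)
    return min(bers)


def trapezoid_auc(points: np.ndarray) -> float:
    """Area under the stepwise ROC by the trapezoid rule."""
    x = points[:, 0]
    y = points[:, 1]
    return float(np.trapezoid(y, x))


def random_dense_hmm(rng: np.random.Generator, n_states: int) -> HmmParameters:
    """A random fully-connected HMM over the 20-letter alphabet."""
    init = rng.dirichlet(np.ones(n_states))
    trans = rng.dirichlet(np.ones(n_states), size=n_states)
    emit = rng.dirichlet(np.ones(N_SYMBOLS) * 0.5, size=n_states)
    emit = (emit + PSEUDOCOUNT)
    emit /= emit.sum(axis=1, keepdims=True)
    return HmmParameters(
        state_ids=[f"s{i}" for i in range(n_states)],
        regions=["globular"] * n_states,
        log_initial=np.log(init),
        log_transition=np.log(trans),
        log_emission=np.log(emit),
    )
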