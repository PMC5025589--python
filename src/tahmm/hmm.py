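"""Discrete-alphabet hidden Markov model engine in log space.

All probabilities are stored as natural logarithms; structurally forbidden
transitions are ``-inf`` and are kept ``-inf`` through training, so a model's
topology (the region grammar) is invariant under Baum-Welch re-estimation.
Forward, Viterbi and the forward-backward recursions use log-sum-exp and do
not underflow for sequences of several thousand residues.

There is no explicit end state: the forward likelihood terminates by summing
over all states at the last position, Viterbi by maximising over them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .alphabet import (
    ALPHABET,
    AMBIGUOUS_CODE,
    AminoAcidSequence,
    N_SYMBOLS,
    SequenceError,
    as_sequence,
)

TOPOLOGY_VERSION = "tahmm-topology-1"

#: Orientation flags: which terminus the model reads first.
READS_N_TO_C = "reads-N-to-C"
READS_C_TO_N = "reads-C-to-N"

_LOG_AMBIG = -np.log(N_SYMBOLS)  # class-neutral emission for ambiguity codes

#: Pseudocount applied at every M-step (emissions: all letters; transitions
#: and initial probabilities: structurally allowed entries only).
PSEUDOCOUNT = 1e-6

_NORM_TOL = 1e-9


class HmmError(ValueError):
    """Invalid model parameters or inadmissible decoding problem."""


class NoAdmissiblePathError(HmmError):
    """Raised by Viterbi when every state path has probability zero."""


@dataclass
class HmmParameters:
    """A discrete HMM with region-tagged states and sparse transitions.

    Attributes
    ----------
    state_ids : list of str
        Stable state identifiers, e.g. ``"tmd_07"``.
    regions : list of str
        Region label of each state (``tail``, ``TMD``, ``cap``, ...).
    log_initial : (n,) ndarray
        Log initial probabilities; ``-inf`` outside the initial support.
    log_transition : (n, n) ndarray
        Log transition probabilities; ``-inf`` for structurally forbidden
        pairs.  ``transition_mask`` records the allowed set, which training
        never enlarges.
    log_emission : (n, 20) ndarray
        Log emission probabilities over :data:`tahmm.alphabet.ALPHABET`.
    orientation : str
        ``reads-N-to-C`` or ``reads-C-to-N``.  Models that read from the
        C-terminus expect the *caller* to reverse input sequences.
    """

    state_ids: list[str]
    regions: list[str]
    log_initial: np.ndarray
    log_transition: np.ndarray
    log_emission: np.ndarray
    orientation: str = READS_N_TO_C
    topology_version: str = TOPOLOGY_VERSION
    transition_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    initial_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.log_initial = np.asarray(self.log_initial, dtype=float)
        self.log_transition = np.asarray(self.log_transition, dtype=float)
        self.log_emission = np.asarray(self.log_emission, dtype=float)
        if self.transition_mask is None:
            self.transition_mask = np.isfinite(self.log_transition)
        if self.initial_mask is None:
            self.initial_mask = np.isfinite(self.log_initial)
        self.transition_mask = np.asarray(self.transition_mask, dtype=bool)
        self.initial_mask = np.asarray(self.initial_mask, dtype=bool)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_ids)

    def validate(self) -> None:
        n = self.n_states
        if len(self.regions) != n:
            raise HmmError("regions and state_ids length mismatch")
        if self.log_initial.shape != (n,):
            raise HmmError("log_initial has wrong shape")
        if self.log_transition.shape != (n, n):
            raise HmmError("log_transition has wrong shape")
        if self.log_emission.shape != (n, N_SYMBOLS):
            raise HmmError("log_emission has wrong shape")
        if self.orientation not in (READS_N_TO_C, READS_C_TO_N):
            raise HmmError(f"unknown orientation {self.orientation!r}")
        if np.any(np.isfinite(self.log_transition) & ~self.transition_mask):
            raise HmmError("finite transition outside the structural mask")
        if np.any(np.isfinite(self.log_initial) & ~self.initial_mask):
            raise HmmError("finite initial probability outside its support")
        if abs(np.exp(logsumexp(self.log_initial)) - 1.0) > _NORM_TOL:
            raise HmmError("initial distribution does not sum to 1")
        rows = np.exp(logsumexp(self.log_transition, axis=1))
        if np.any(np.abs(rows - 1.0) > _NORM_TOL):
            raise HmmError("a transition row does not sum to 1")
        erows = np.exp(logsumexp(self.log_emission, axis=1))
        if np.any(np.abs(erows - 1.0) > _NORM_TOL):
            raise HmmError("an emission row does not sum to 1")

    # ------------------------------------------------------------------
    def _log_emission_ext(self) -> np.ndarray:
        """Emission matrix with an extra column for ambiguity codes."""
        ext = np.empty((self.n_states, N_SYMBOLS + 1))
        ext[:, :N_SYMBOLS] = self.log_emission
        ext[:, N_SYMBOLS] = _LOG_AMBIG
        return ext

    def region_of(self, state: int) -> str:
        return self.regions[state]

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        """JSON-ready dict with *linear* probabilities (exact round-trip)."""
        with np.errstate(under="ignore"):
            trans = {}
            for i in range(self.n_states):
                row = {
                    self.state_ids[j]: float(np.exp(self.log_transition[i, j]))
                    for j in range(self.n_states)
                    if self.transition_mask[i, j]
                }
                trans[self.state_ids[i]] = row
            initial = {
                self.state_ids[i]: float(np.exp(self.log_initial[i]))
                for i in range(self.n_states)
                if self.initial_mask[i]
            }
            emissions = {
                self.state_ids[i]: {
                    a: float(np.exp(self.log_emission[i, k]))
                    for k, a in enumerate(ALPHABET)
                }
                for i in range(self.n_states)
            }
        return {
            "topology_version": self.topology_version,
            "orientation": self.orientation,
            "states": [
                {"id": s, "region": r}
                for s, r in zip(self.state_ids, self.regions)
            ],
            "initial": initial,
            "transitions": trans,
            "emissions": emissions,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "HmmParameters":
        try:
            states = data["states"]
            state_ids = [s["id"] for s in states]
            regions = [s["region"] for s in states]
            idx = {s: i for i, s in enumerate(state_ids)}
            n = len(state_ids)
            log_init = np.full(n, -np.inf)
            for s, p in data["initial"].items():
                log_init[idx[s]] = np.log(p) if p > 0 else -np.inf
            init_mask = np.zeros(n, dtype=bool)
            for s in data["initial"]:
                init_mask[idx[s]] = True
            log_trans = np.full((n, n), -np.inf)
            mask = np.zeros((n, n), dtype=bool)
            for s, row in data["transitions"].items():
                for t, p in row.items():
                    mask[idx[s], idx[t]] = True
                    log_trans[idx[s], idx[t]] = np.log(p) if p > 0 else -np.inf
            log_em = np.full((n, N_SYMBOLS), -np.inf)
            for s, row in data["emissions"].items():
                for a, p in row.items():
                    k = ALPHABET.index(a)
                    log_em[idx[s], k] = np.log(p) if p > 0 else -np.inf
            return cls(
                state_ids=state_ids,
                regions=regions,
                log_initial=log_init,
                log_transition=log_trans,
                log_emission=log_em,
                orientation=data["orientation"],
                topology_version=data["topology_version"],
                transition_mask=mask,
                initial_mask=init_mask,
            )
        except (KeyError, IndexError, ValueError) as exc:
            raise HmmError(f"corrupt model parameters: {exc!r}") from exc

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "HmmParameters":
        return cls.from_dict(json.loads(text))

    def copy(self) -> "HmmParameters":
        return replace(
            self,
            log_initial=self.log_initial.copy(),
            log_transition=self.log_transition.copy(),
            log_emission=self.log_emission.copy(),
            transition_mask=self.transition_mask.copy(),
            initial_mask=self.initial_mask.copy(),
        )


# ----------------------------------------------------------------------
# Inference
# ----------------------------------------------------------------------

def _encode(seq) -> np.ndarray:
    seq = as_sequence(seq)
    return seq.encode()


def _forward_matrix(params: HmmParameters, codes: np.ndarray) -> np.ndarray:
    """Log forward lattice alpha[t, i] = log P(x_1..t, s_t = i)."""
    from . import _kernels

    return _kernels.forward_lattice(
        params.log_initial, params.log_transition,
        params._log_emission_ext(), codes,
    )


def _backward_matrix(params: HmmParameters, codes: np.ndarray) -> np.ndarray:
    """Log backward lattice beta[t, i] = log P(x_{t+1}..L | s_t = i)."""
    from . import _kernels

    return _kernels.backward_lattice(
        params.log_transition, params._log_emission_ext(), codes
    )


def forward_log_likelihood(params: HmmParameters, seq) -> float:
    """Log of the total probability of ``seq``, summed over all state paths.

    Terminates by summing over all states at the final position (the models
    have no end state).
    """
    codes = _encode(seq)
    alpha = _forward_matrix(params, codes)
    return float(logsumexp(alpha[-1]))


def viterbi_decode(params: HmmParameters, seq) -> tuple[np.ndarray, float]:
    """Most probable state path and its joint log probability.

    Ties are broken toward the lowest state index at every backtrack step,
    which makes the decoded path deterministic across platforms.
    """
    from . import _kernels

    codes = _encode(seq)
    L = codes.shape[0]
    delta, psi = _kernels.viterbi_lattice(
        params.log_initial, params.log_transition,
        params._log_emission_ext(), codes,
    )
    # np.argmax returns the first (= lowest-index) maximiser.
    last = int(np.argmax(delta))
    joint = float(delta[last])
    if not np.isfinite(joint):
        raise NoAdmissiblePathError(
            "no state path has nonzero probability for this sequence"
        )
    path = np.empty(L, dtype=np.int64)
    path[L - 1] = last
    for t in range(L - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path, joint


# ----------------------------------------------------------------------
# Training
# ----------------------------------------------------------------------

def baum_welch_fit(
    params: HmmParameters,
    seqs: list,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[HmmParameters, list[float]]:
    """Baum-Welch (EM) re-estimation of initial/transition/emission rows.

    Structural zeros are preserved: pseudocounts (1e-6) are added only to
    structurally allowed transitions and to the initial support; emission
    rows receive the pseudocount on every letter so no residue ever has
    exactly zero probability.  Ambiguous residues contribute to the state
    posteriors but not to emission counts.

    Returns the re-estimated parameters and the per-iteration total
    log-likelihood trace (evaluated under the parameters at the *start* of
    each iteration), which is non-decreasing.  Iteration stops when the
    relative change of the total log-likelihood falls below ``tol`` or after
    ``max_iter`` iterations.
    """
    if not seqs:
        raise HmmError("baum_welch_fit requires at least one sequence")
    all_codes = [_encode(s) for s in seqs]
    if max(c.shape[0] for c in all_codes) == 1 and params.n_states > 1:
        warnings.warn(
            "model longer than data: every training sequence has length 1 "
            "but the model has several states",
            stacklevel=2,
        )
    cur = params.copy()
    trace: list[float] = []
    prev_ll = None
    for _ in range(max_iter):
        new, total_ll = _baum_welch_step(cur, all_codes)
        trace.append(total_ll)
        if prev_ll is not None:
            denom = max(abs(prev_ll), 1.0)
            if (total_ll - prev_ll) / denom < tol:
                cur = new
                break
        prev_ll = total_ll
        cur = new
    return cur, trace


def _baum_welch_step(
    params: HmmParameters, all_codes: list[np.ndarray]
) -> tuple[HmmParameters, float]:
    """One EM iteration; returns updated parameters and the pre-update
    total log-likelihood."""
    n = params.n_states
    logT = params.log_transition
    logB = params._log_emission_ext()
    init_counts = np.zeros(n)
    trans_counts = np.zeros((n, n))
    emit_counts = np.zeros((n, N_SYMBOLS))
    total_ll = 0.0
    linT = np.exp(np.where(params.transition_mask, logT, -np.inf))
    with np.errstate(divide="ignore", under="ignore"):
        for codes in all_codes:
            alpha = _forward_matrix(params, codes)
            beta = _backward_matrix(params, codes)
            ll = logsumexp(alpha[-1])
            total_ll += ll
            gamma = np.exp(alpha + beta - ll)  # (L, n) posteriors
            init_counts += gamma[0]
            L = codes.shape[0]
            if L > 1:
                # xi_t = exp(alpha_t(i) + logT(i,j) + logB(j, x_{t+1})
                #            + beta_{t+1}(j) - ll) factorises into
                # T * (a^T b) with per-position normalisers m_t, so the
                # whole transition-count sum is one matrix product.
                m = alpha[:-1].max(axis=1)  # (L-1,)
                a = np.exp(alpha[:-1] - m[:, None])  # (L-1, n)
                w = logB[:, codes[1:]].T + beta[1:]  # (L-1, n)
                b = np.exp(w - (ll - m)[:, None])  # (L-1, n)
                trans_counts += linT * (a.T @ b)
            canonical = codes >= 0
            np.add.at(emit_counts.T, codes[canonical], gamma[canonical])
    # M-step with support-restricted pseudocounts.
    init = np.where(params.initial_mask, init_counts + PSEUDOCOUNT, 0.0)
    init /= init.sum()
    trans = np.where(params.transition_mask, trans_counts + PSEUDOCOUNT, 0.0)
    trans /= trans.sum(axis=1, keepdims=True)
    emit = emit_counts + PSEUDOCOUNT
    emit /= emit.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        new = replace(
            params.copy(),
            log_initial=np.log(init),
            log_transition=np.log(trans),
            log_emission=np.log(emit),
        )
    return new, float(total_ll)


def expected_state_occupancy(params: HmmParameters, seqs: list) -> np.ndarray:
    """Total posterior occupancy of each state over the given sequences.

    Entry ``i`` is the expected number of residues emitted by state ``i``
    under the forward-backward posterior; useful for occupancy-weighted
    region summaries of trained models.
    """
    occ = np.zeros(params.n_states)
    with np.errstate(under="ignore"):
        for seq in seqs:
            codes = _encode(seq)
            alpha = _forward_matrix(params, codes)
            beta = _backward_matrix(params, codes)
            ll = logsumexp(alpha[-1])
            occ += np.exp(alpha + beta - ll).sum(axis=0)
    return occ


# ----------------------------------------------------------------------
# Sampling
# ----------------------------------------------------------------------

def sample_sequence(
    params: HmmParameters, length: int, rng
) -> tuple[AminoAcidSequence, np.ndarray]:
    """Draw a (sequence, state path) pair of the given length.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.  The
    path starts from the initial distribution and follows the transition
    rows; residues follow the current state's emission row.  The sequence is
    returned in the model's own reading direction.
    """
    if length < 1:
        raise HmmError("length must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    with np.errstate(under="ignore"):
        p_init = np.exp(params.log_initial)
        p_trans = np.exp(params.log_transition)
        p_emit = np.exp(params.log_emission)
    p_init = p_init / p_init.sum()
    p_trans = p_trans / p_trans.sum(axis=1, keepdims=True)
    p_emit = p_emit / p_emit.sum(axis=1, keepdims=True)
    path = np.empty(length, dtype=np.int64)
    letters = []
    state = rng.choice(params.n_states, p=p_init)
    for t in range(length):
        path[t] = state
        letters.append(ALPHABET[rng.choice(N_SYMBOLS, p=p_emit[state])])
        if t < length - 1:
            state = rng.choice(params.n_states, p=p_trans[state])
    return AminoAcidSequence("sample", "".join(letters)), path
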