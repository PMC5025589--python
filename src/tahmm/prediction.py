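"""Likelihood scores, region decoding and the three TA decision rules.

A sequence is scored against the trained TA, SP and MP models.  The TA
model reads the sequence from the C-terminus (the caller-side reversal
lives here), and its log-likelihood is the maximum over the configured
tail variants.  Scores are per-residue log-likelihood differences

    S_sp = (ln l_ta - ln l_sp) / L        S_mp = (ln l_ta - ln l_mp) / L

with the positive-is-TA-like sign convention; dividing by the sequence
length L removes the trivial length dependence of log-likelihoods.
"Likelihood" defaults to the Viterbi joint probability (likelihoods are
obtained by decoding); a switch selects the forward (summed) likelihood.

Three decision rules are provided:

* the **decoding rule**: Viterbi-decode under the TA model (2-state tail
  variant) and accept iff the decoded state sequence contains a TMD region
  of >= 15 residues and a C-terminal tail region of <= 30 residues;
* the **score rule**: accept iff S (against the relevant negative model)
  is at or above a threshold chosen to minimise the balanced error rate;
* the **combined rule**: accept iff both rules accept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .alphabet import as_sequence
from .hmm import (
    READS_C_TO_N,
    HmmParameters,
    forward_log_likelihood,
    viterbi_decode,
)

#: Decoding-rule failure reasons.
NO_TMD = "no-TMD"
TAIL_TOO_LONG = "tail-too-long"
ALL_TAIL = "all-tail"

MIN_TMD_LEN = 15
MAX_TAIL_LEN = 30


@dataclass(frozen=True)
class RegionSegment:
    """A decoded region in original N->C coordinates (0-based half-open)."""

    region: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


class Scores(NamedTuple):
    ln_l_ta: float
    ln_l_sp: float
    ln_l_mp: float
    s_sp: float
    s_mp: float


@dataclass
class PredictionRecord:
    """Per-sequence likelihoods, scores and verdicts."""

    id: str
    length: int
    ln_l_ta: float
    ln_l_sp: float
    ln_l_mp: float
    s_sp: float
    s_mp: float
    segments: tuple[RegionSegment, ...] = ()
    decoding_verdict: bool | None = None
    decoding_failure: str | None = None
    score_verdict: bool | None = None
    combined_verdict: bool | None = None
    verdict: bool | None = None


@dataclass(frozen=True)
class ThresholdFit:
    """BER-minimising score threshold (classification: score >= threshold)."""

    threshold: float
    ber_at_threshold: float


def _loglik(params: HmmParameters, seq, likelihood: str) -> float:
    if likelihood == "viterbi":
        return viterbi_decode(params, seq)[1]
    if likelihood == "forward":
        return forward_log_likelihood(params, seq)
    raise ValueError(f"unknown likelihood mode {likelihood!r}")


def _oriented(params: HmmParameters, seq):
    seq = as_sequence(seq)
    return seq.reversed() if params.orientation == READS_C_TO_N else seq


def likelihood_scores(bundle, seq, likelihood: str = "viterbi") -> Scores:
    """Per-model log-likelihoods and length-normalised scores.

    ``bundle`` is a trained :class:`tahmm.training.ModelBundle`.  The TA
    likelihood is the maximum over the bundle's tail variants, computed on
    the reversed sequence; SP and MP likelihoods are computed reading
    N-to-C.
    """
    seq = as_sequence(seq)
    L = len(seq)
    if L == 0:
        raise ValueError("cannot score an empty sequence")
    ln_ta = max(
        _loglik(m, _oriented(m, seq), likelihood) for m in bundle.ta.values()
    )
    ln_sp = _loglik(bundle.sp, _oriented(bundle.sp, seq), likelihood)
    ln_mp = _loglik(bundle.mp, _oriented(bundle.mp, seq), likelihood)
    return Scores(
        ln_l_ta=ln_ta,
        ln_l_sp=ln_sp,
        ln_l_mp=ln_mp,
        s_sp=(ln_ta - ln_sp) / L,
        s_mp=(ln_ta - ln_mp) / L,
    )


def decode_regions(ta_model: HmmParameters, seq) -> list[RegionSegment]:
    """Viterbi-decode under the TA model; segments in N->C coordinates.

    The model reads C-to-N, so the sequence is reversed before decoding and
    the decoded runs are mapped back: a run over reversed positions
    ``[a, b)`` of a length-L sequence covers original positions
    ``[L - b, L - a)``.  Consecutive states with the same region label are
    merged; the segments tile ``[0, L)``.
    """
    if ta_model.orientation != READS_C_TO_N:
        raise ValueError("decode_regions expects the C-to-N (TA) model")
    seq = as_sequence(seq)
    L = len(seq)
    path, _ = viterbi_decode(ta_model, seq.reversed())
    segs: list[RegionSegment] = []
    start = 0
    regions = ta_model.regions
    for t in range(1, L + 1):
        if t == L or regions[path[t]] != regions[path[start]]:
            segs.append(RegionSegment(regions[path[start]], L - t, L - start))
            start = t
    segs.reverse()
    return segs


def decoding_rule(
    segments: list[RegionSegment],
) -> tuple[bool, str | None]:
    """Accept iff a TMD segment of >= 15 residues is present and the
    C-terminal tail segment is <= 30 residues.

    Failure reasons: ``all-tail`` (the whole sequence decoded as tail, so
    no transition into the TMD ever occurred), ``no-TMD`` (no qualifying
    TMD segment), ``tail-too-long`` (TMD present but the tail exceeds 30
    residues).
    """
    if len(segments) == 1 and segments[0].region == "tail":
        return False, ALL_TAIL
    has_tmd = any(
        s.region == "TMD" and len(s) >= MIN_TMD_LEN for s in segments
    )
    if not has_tmd:
        return False, NO_TMD
    tail_segments = [s for s in segments if s.region == "tail"]
    tail_len = len(tail_segments[-1]) if tail_segments else 0
    if tail_len > MAX_TAIL_LEN:
        return False, TAIL_TOO_LONG
    return True, None


def select_threshold(scores_pos, scores_neg) -> ThresholdFit:
    """Threshold minimising the balanced error rate on the fitting data.

    Candidates are the midpoints between adjacent distinct values of the
    pooled scores plus ``-inf``/``+inf`` sentinels; classification is
    positive when ``score >= threshold``; ties in BER are broken toward the
    smallest candidate.
    """
    pos = np.asarray(list(scores_pos), dtype=float)
    neg = np.asarray(list(scores_neg), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    values = np.unique(np.concatenate([pos, neg]))
    candidates = [-math.inf]
    candidates.extend(((values[:-1] + values[1:]) / 2.0).tolist())
    candidates.append(math.inf)
    best_thr = None
    best_ber = math.inf
    for thr in candidates:
        fn = float(np.count_nonzero(pos < thr)) / pos.size
        fp = float(np.count_nonzero(neg >= thr)) / neg.size
        ber = (fn + fp) / 2.0
        if ber < best_ber - 1e-12:
            best_ber = ber
            best_thr = thr
    return ThresholdFit(threshold=best_thr, ber_at_threshold=best_ber)


def classify(
    bundle,
    threshold_sp: float | None,
    threshold_mp: float | None,
    seq,
    mode: str = "combined",
    negative_context: str = "mp",
    likelihood: str = "viterbi",
) -> PredictionRecord:
    """Score and decode one sequence, producing all three verdicts.

    ``negative_context`` selects which score/threshold pair the score rule
    uses: ``"sp"`` compares S_sp against ``threshold_sp``, ``"mp"``
    compares S_mp against ``threshold_mp`` (the convention for the MP and
    NO datasets and for pooled negative data).  ``mode`` picks which rule
    fills the final ``verdict``: ``score``, ``decode`` or ``combined``.
    """
    if mode not in ("score", "decode", "combined"):
        raise ValueError(f"unknown mode {mode!r}")
    if negative_context not in ("sp", "mp"):
        raise ValueError(f"unknown negative context {negative_context!r}")
    seq = as_sequence(seq)
    scores = likelihood_scores(bundle, seq, likelihood)
    segments = tuple(decode_regions(bundle.ta[2], seq))
    dec_ok, reason = decoding_rule(list(segments))
    score_verdict: bool | None = None
    if mode in ("score", "combined"):
        if negative_context == "sp":
            if threshold_sp is None:
                raise ValueError("threshold_sp required for SP context")
            score_verdict = scores.s_sp >= threshold_sp
        else:
            if threshold_mp is None:
                raise ValueError("threshold_mp required for MP context")
            score_verdict = scores.s_mp >= threshold_mp
    combined = (dec_ok and score_verdict) if score_verdict is not None else None
    verdict = {
        "decode": dec_ok,
        "score": score_verdict,
        "combined": combined,
    }[mode]
    return PredictionRecord(
        id=seq.id,
        length=len(seq),
        ln_l_ta=scores.ln_l_ta,
        ln_l_sp=scores.ln_l_sp,
        ln_l_mp=scores.ln_l_mp,
        s_sp=scores.s_sp,
        s_mp=scores.s_mp,
        segments=segments,
        decoding_verdict=dec_ok,
        decoding_failure=reason,
        score_verdict=score_verdict,
        combined_verdict=combined,
        verdict=verdict,
    )
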