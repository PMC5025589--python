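"""Model training and the cross-validation scoring protocol.

Three models are trained: the TA model (on TA sequences, reversed, in both
tail variants), the SP model (on single-pass sequences) and the MP model
(on multi-pass sequences).  Non-membrane (NO) sequences have no dedicated
model and are never used for training.

For evaluation, per-sequence likelihoods follow the protocol: for a
sequence of dataset X in {TA, SP, MP}, the likelihood under model X comes
from a k-fold model whose training fold excluded that sequence, while the
likelihoods under the other two models come from models trained on their
full datasets.  NO sequences are scored by full-data models only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AminoAcidSequence, as_sequence
from .hmm import HmmParameters, baum_welch_fit
from .prediction import (
    PredictionRecord,
    _loglik,
    _oriented,
    decode_regions,
    decoding_rule,
)
from .topologies import build_mp_model, build_sp_model, build_ta_model


@dataclass
class TrainConfig:
    tol: float = 1e-6
    max_iter: int = 100
    tail_state_counts: tuple[int, ...] = (2, 4)
    likelihood: str = "viterbi"
    seed: int = 0


@dataclass
class ModelBundle:
    """Trained TA (per tail variant), SP and MP models plus metadata."""

    ta: dict[int, HmmParameters]
    sp: HmmParameters
    mp: HmmParameters
    metadata: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)


def _train_one(
    builder_params: HmmParameters,
    seqs: list[AminoAcidSequence],
    config: TrainConfig,
) -> tuple[HmmParameters, list[float]]:
    oriented = [_oriented(builder_params, s) for s in seqs]
    return baum_welch_fit(
        builder_params, oriented, tol=config.tol, max_iter=config.max_iter
    )


def train_models(
    ta_set,
    sp_set,
    mp_set,
    config: TrainConfig | None = None,
) -> ModelBundle:
    """Baum-Welch-train the three models on their labelled datasets."""
    config = config or TrainConfig()
    for name, dataset in (("TA", ta_set), ("SP", sp_set), ("MP", mp_set)):
        if not dataset:
            raise ValueError(f"{name} training set is empty")
    ta_set = [as_sequence(s) for s in ta_set]
    sp_set = [as_sequence(s) for s in sp_set]
    mp_set = [as_sequence(s) for s in mp_set]
    meta: dict = {
        "n_ta": len(ta_set),
        "n_sp": len(sp_set),
        "n_mp": len(mp_set),
        "tol": config.tol,
        "max_iter": config.max_iter,
        "seed": config.seed,
        "final_log_likelihood": {},
        "n_iterations": {},
    }
    ta_models: dict[int, HmmParameters] = {}
    for k in config.tail_state_counts:
        model, trace = _train_one(build_ta_model(k), ta_set, config)
        ta_models[k] = model
        meta["final_log_likelihood"][f"ta{k}"] = trace[-1]
        meta["n_iterations"][f"ta{k}"] = len(trace)
    sp_model, trace = _train_one(build_sp_model(), sp_set, config)
    meta["final_log_likelihood"]["sp"] = trace[-1]
    meta["n_iterations"]["sp"] = len(trace)
    mp_model, trace = _train_one(build_mp_model(), mp_set, config)
    meta["final_log_likelihood"]["mp"] = trace[-1]
    meta["n_iterations"]["mp"] = len(trace)
    return ModelBundle(ta=ta_models, sp=sp_model, mp=mp_model, metadata=meta)


def assign_folds(ids: list[str], k: int, seed: int) -> np.ndarray:
    """Fold index per id: canonical sort by id, seeded shuffle, round-robin.

    The assignment depends only on the id set, the fold count and the seed,
    never on the input order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError("more folds than sequences")
    order = np.argsort(np.array(ids))
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(len(ids))
    folds = np.empty(len(ids), dtype=np.int64)
    # round-robin over the shuffled canonical order
    for rank, pos in enumerate(shuffled):
        folds[order[pos]] = rank % k
    return folds


def crossvalidated_scores(
    ta_set,
    sp_set,
    mp_set,
    no_set,
    k: int = 5,
    seed: int = 0,
    config: TrainConfig | None = None,
) -> list[PredictionRecord]:
    """Per-sequence likelihoods under the cross-validation protocol.

    Records carry likelihoods, scores and the decoding verdict; score and
    combined verdicts are left unset because thresholds are fitted *after*
    this step (see :func:`tahmm.prediction.select_threshold`).  Every
    record's own-model likelihood comes from a fold model that never saw
    that sequence; TA-set sequences are also decoded with their fold's TA
    2-state-tail model.
    """
    config = config or TrainConfig(seed=seed)
    full = train_models(ta_set, sp_set, mp_set, config)
    ta_set = [as_sequence(s) for s in ta_set]
    sp_set = [as_sequence(s) for s in sp_set]
    mp_set = [as_sequence(s) for s in mp_set]
    no_set = [as_sequence(s) for s in no_set]

    fold_models: dict[str, dict[int, object]] = {"TA": {}, "SP": {}, "MP": {}}
    fold_of: dict[str, np.ndarray] = {}
    for name, dataset in (("TA", ta_set), ("SP", sp_set), ("MP", mp_set)):
        folds = assign_folds([s.id for s in dataset], k, seed)
        fold_of[name] = folds
        for f in range(k):
            train = [s for s, fi in zip(dataset, folds) if fi != f]
            if name == "TA":
                models = {
                    kk: _train_one(build_ta_model(kk), train, config)[0]
                    for kk in config.tail_state_counts
                }
                fold_models["TA"][f] = models
            elif name == "SP":
                fold_models["SP"][f] = _train_one(
                    build_sp_model(), train, config
                )[0]
            else:
                fold_models["MP"][f] = _train_one(
                    build_mp_model(), train, config
                )[0]

    def ta_loglik(models: dict[int, HmmParameters], seq) -> float:
        return max(
            _loglik(m, _oriented(m, seq), config.likelihood)
            for m in models.values()
        )

    records: list[PredictionRecord] = []

    def make_record(seq, ln_ta, ln_sp, ln_mp, ta2_model) -> PredictionRecord:
        L = len(seq)
        segments = tuple(decode_regions(ta2_model, seq))
        dec_ok, reason = decoding_rule(list(segments))
        return PredictionRecord(
            id=seq.id,
            length=L,
            ln_l_ta=ln_ta,
            ln_l_sp=ln_sp,
            ln_l_mp=ln_mp,
            s_sp=(ln_ta - ln_sp) / L,
            s_mp=(ln_ta - ln_mp) / L,
            segments=segments,
            decoding_verdict=dec_ok,
            decoding_failure=reason,
        )

    for seq, f in zip(ta_set, fold_of["TA"]):
        models = fold_models["TA"][int(f)]
        records.append(
            make_record(
                seq,
                ta_loglik(models, seq),
                _loglik(full.sp, _oriented(full.sp, seq), config.likelihood),
                _loglik(full.mp, _oriented(full.mp, seq), config.likelihood),
                models[2] if 2 in models else next(iter(models.values())),
            )
        )
    for seq, f in zip(sp_set, fold_of["SP"]):
        records.append(
            make_record(
                seq,
                ta_loglik(full.ta, seq),
                _loglik(
                    fold_models["SP"][int(f)],
                    _oriented(full.sp, seq),
                    config.likelihood,
                ),
                _loglik(full.mp, _oriented(full.mp, seq), config.likelihood),
                full.ta[2],
            )
        )
    for seq, f in zip(mp_set, fold_of["MP"]):
        records.append(
            make_record(
                seq,
                ta_loglik(full.ta, seq),
                _loglik(full.sp, _oriented(full.sp, seq), config.likelihood),
                _loglik(
                    fold_models["MP"][int(f)],
                    _oriented(full.mp, seq),
                    config.likelihood,
                ),
                full.ta[2],
            )
        )
    for seq in no_set:
        records.append(
            make_record(
                seq,
                ta_loglik(full.ta, seq),
                _loglik(full.sp, _oriented(full.sp, seq), config.likelihood),
                _loglik(full.mp, _oriented(full.mp, seq), config.likelihood),
                full.ta[2],
            )
        )
    return records
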