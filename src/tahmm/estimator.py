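"""Scikit-learn-style estimator wrapping the full train/score/decide
pipeline.

``TailAnchorClassifier`` is fitted on amino-acid sequences labelled
``TA`` / ``SP`` / ``MP`` / ``NO`` and predicts whether a sequence is a
tail-anchored protein.  It composes with sklearn model selection through
``get_params``/``set_params``, ``decision_function`` and boolean
``predict``; fitted state lives in trailing-underscore attributes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .alphabet import as_sequence
from .prediction import classify, select_threshold
from .training import ModelBundle, TrainConfig, crossvalidated_scores, train_models


class TailAnchorClassifier(BaseEstimator, ClassifierMixin):
    """Tail-anchored protein classifier built from three region HMMs.

    Parameters
    ----------
    tail_state_counts : tuple of int
        TA-model tail variants to train; the TA likelihood is their
        maximum, and decoding always uses the 2-state variant.
    likelihood : {"viterbi", "forward"}
        Which likelihood the score rule uses.
    mode : {"combined", "score", "decode"}
        Decision rule applied by :meth:`predict`.
    negative_context : {"mp", "sp"}
        Which score/threshold pair the score rule uses; ``mp`` is the
        convention for multi-pass, non-membrane and pooled negatives.
    cv : int or None
        If an integer >= 2, thresholds are fitted on k-fold
        cross-validated scores (each sequence's own-model likelihood from
        a model that never saw it); if None, on resubstitution scores.
    tol, max_iter
        Baum-Welch stopping controls.
    random_state : int
        Seed for fold assignment.

    Attributes
    ----------
    bundle_ : ModelBundle
        The trained TA/SP/MP models.
    threshold_sp_, threshold_mp_ : float
        BER-minimising score thresholds fitted on the training data.
    classes_ : ndarray
        ``[False, True]`` (True = tail-anchored).
    """

    def __init__(
        self,
        tail_state_counts=(2, 4),
        likelihood="viterbi",
        mode="combined",
        negative_context="mp",
        cv=None,
        tol=1e-6,
        max_iter=100,
        random_state=0,
    ):
        self.tail_state_counts = tail_state_counts
        self.likelihood = likelihood
        self.mode = mode
        self.negative_context = negative_context
        self.cv = cv
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _config(self) -> TrainConfig:
        return TrainConfig(
            tol=self.tol,
            max_iter=self.max_iter,
            tail_state_counts=tuple(self.tail_state_counts),
            likelihood=self.likelihood,
            seed=self.random_state,
        )

    def fit(self, X, y):
        """Train the three models and fit the score thresholds.

        ``X`` is a sequence of amino-acid strings (or sequence objects),
        ``y`` the class label of each: ``TA``, ``SP``, ``MP`` or ``NO``.
        """
        y = np.asarray(y, dtype=object)
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        by_class: dict[str, list] = {c: [] for c in ("TA", "SP", "MP", "NO")}
        for i, (x, label) in enumerate(zip(X, y)):
            if label not in by_class:
                raise ValueError(f"unknown class label {label!r}")
            by_class[label].append(as_sequence(x, id=f"{label.lower()}_{i:05d}"))
        config = self._config()
        self.bundle_ = train_models(
            by_class["TA"], by_class["SP"], by_class["MP"], config
        )
        if self.cv is not None:
            records = crossvalidated_scores(
                by_class["TA"],
                by_class["SP"],
                by_class["MP"],
                [],
                k=int(self.cv),
                seed=self.random_state,
                config=config,
            )
            scored = [(r.id, r.s_sp, r.s_mp) for r in records]
        else:
            from .prediction import likelihood_scores

            scored = []
            for label in ("TA", "SP", "MP"):
                for seq in by_class[label]:
                    s = likelihood_scores(self.bundle_, seq, self.likelihood)
                    scored.append((seq.id, s.s_sp, s.s_mp))
        label_of = {}
        for label in ("TA", "SP", "MP"):
            for seq in by_class[label]:
                label_of[seq.id] = label
        s_sp_pos = [s for i, s, _ in scored if label_of.get(i) == "TA"]
        s_sp_neg = [s for i, s, _ in scored if label_of.get(i) == "SP"]
        s_mp_pos = [s for i, _, s in scored if label_of.get(i) == "TA"]
        s_mp_neg = [s for i, _, s in scored if label_of.get(i) == "MP"]
        fit_sp = select_threshold(s_sp_pos, s_sp_neg)
        fit_mp = select_threshold(s_mp_pos, s_mp_neg)
        self.threshold_sp_ = fit_sp.threshold
        self.threshold_mp_ = fit_mp.threshold
        self.bundle_.thresholds = {
            "sp": {"threshold": fit_sp.threshold, "ber": fit_sp.ber_at_threshold},
            "mp": {"threshold": fit_mp.threshold, "ber": fit_mp.ber_at_threshold},
        }
        self.classes_ = np.array([False, True])
        return self

    # ------------------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "bundle_"):
            raise AttributeError("this TailAnchorClassifier is not fitted yet")

    def predict_records(self, X):
        """Full per-sequence prediction records (scores, segments,
        verdicts)."""
        self._check_fitted()
        return [
            classify(
                self.bundle_,
                self.threshold_sp_,
                self.threshold_mp_,
                as_sequence(x, id=f"query_{i:05d}"),
                mode=self.mode,
                negative_context=self.negative_context,
                likelihood=self.likelihood,
            )
            for i, x in enumerate(X)
        ]

    def decision_function(self, X):
        """Score margin S - threshold under the configured negative
        context (positive = TA-like)."""
        self._check_fitted()
        recs = self.predict_records(X)
        if self.negative_context == "sp":
            return np.array([r.s_sp - self.threshold_sp_ for r in recs])
        return np.array([r.s_mp - self.threshold_mp_ for r in recs])

    def predict(self, X):
        """Boolean verdict per sequence under the configured rule."""
        return np.array([r.verdict for r in self.predict_records(X)], dtype=bool)

    def score(self, X, y):
        """Accuracy of the boolean verdict against ``y == "TA"``."""
        y = np.asarray(y, dtype=object)
        return float(np.mean(self.predict(X) == (y == "TA")))
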