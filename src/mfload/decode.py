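"""Linear decoding on CSP features and the session-wise training protocol.

A two-class (high vs low) decoder is built from session 1, updated with
the new imagery data after sessions 2 and 3, and a three-class decoder
(high / low / relaxed) is built from sessions 1-4 before the online
session. The classifier is a linear maximum-margin model (linear SVM,
C = 1); multi-class decisions use one-vs-rest argmax with deterministic
lowest-index tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .containers import TrialEpochs, concat_epochs
from .csp import CSPModel, csp_transform, fit_and_transform
from .errors import PredictionError, TrainingError


@dataclass(frozen=True)
class DecoderConfig:
    """CSP + classifier hyperparameters."""

    n_pairs: int = 3
    C: float = 1.0
    shrinkage: float = 0.0
    scheme: str = "ovr"


@dataclass
class Decoder:
    """Fitted CSP feature extractor + linear classifier.

    ``coef``/``intercept`` define per-class decision scores
    ``coef @ f + intercept``; for the binary case there is a single score
    row whose sign selects ``classes[1]`` (positive) or ``classes[0]``.
    ``trained_on`` records the session ids whose data entered training.
    """

    csp_models: list[CSPModel]
    coef: np.ndarray
    intercept: np.ndarray
    classes: tuple[str, ...]
    trained_on: list[int]
    config: DecoderConfig
    train_epochs: TrialEpochs | None = field(default=None, repr=False)

    @property
    def channels(self) -> tuple[str, ...]:
        return self.csp_models[0].channels

    def decision_scores(self, features: np.ndarray) -> np.ndarray:
        return features @ self.coef.T + self.intercept


def _fit(epochs: TrialEpochs, cfg: DecoderConfig,
         sessions: list[int]) -> Decoder:
    models, feats = fit_and_transform(epochs, cfg.n_pairs, cfg.shrinkage,
                                      cfg.scheme)
    classes = epochs.classes()
    y = np.searchsorted(classes, epochs.labels.astype(str))
    clf = LinearSVC(C=cfg.C, random_state=0)
    clf.fit(feats, y)
    return Decoder(models, np.atleast_2d(clf.coef_),
                   np.atleast_1d(clf.intercept_), tuple(classes),
                   sorted(sessions), cfg, epochs)


def train_two_class(epochs: TrialEpochs,
                    cfg: DecoderConfig = DecoderConfig(),
                    sessions: tuple[int, ...] = (1,)) -> Decoder:
    """High-vs-low decoder from motor-imagery epochs of the first session."""
    classes = epochs.classes()
    if len(classes) != 2:
        raise TrainingError(
            f"two-class training needs exactly 2 labels, got {classes}")
    return _fit(epochs, cfg, list(sessions))


def train_three_class(epochs: TrialEpochs,
                      cfg: DecoderConfig = DecoderConfig(),
                      sessions: tuple[int, ...] = (1, 2, 3, 4)) -> Decoder:
    """High/low/relaxed decoder from pooled sessions 1-4 imagery epochs."""
    classes = epochs.classes()
    missing = sorted({"high", "low", "relaxed"} - set(classes)) \
        if set(classes) <= {"high", "low", "relaxed"} else []
    if len(classes) != 3:
        detail = f"missing class(es) {missing}" if missing else f"got {classes}"
        raise TrainingError(f"three-class training needs 3 labels; {detail}")
    return _fit(epochs, cfg, list(sessions))


def update_decoder(old: Decoder, new_epochs: TrialEpochs,
                   session: int | None = None) -> Decoder:
    """Refit CSP filters and classifier on old + new training epochs."""
    if new_epochs.n_trials == 0:
        return Decoder(old.csp_models, old.coef, old.intercept, old.classes,
                       list(old.trained_on), old.config, old.train_epochs)
    unknown = sorted(set(new_epochs.labels) - set(old.classes))
    if unknown:
        raise TrainingError(f"update contains unknown label(s) {unknown}")
    if old.train_epochs is None:
        raise TrainingError("decoder carries no training epochs to extend")
    merged = concat_epochs([old.train_epochs, new_epochs])
    sessions = list(old.trained_on)
    if session is not None and session not in sessions:
        sessions.append(session)
    return _fit(merged, old.config, sessions)


def predict(dec: Decoder, epochs: TrialEpochs) -> np.ndarray:
    """One label per epoch, deterministic for a fitted decoder."""
    if epochs.channels != dec.channels:
        raise PredictionError("epoch channels do not match the decoder")
    feats = csp_transform(dec.csp_models, epochs)
    scores = dec.decision_scores(feats)
    if len(dec.classes) == 2:
        idx = (scores[:, 0] > 0).astype(int)
    else:
        idx = np.argmax(scores, axis=1)  # argmax takes the lowest index on ties
    return np.array([dec.classes[i] for i in idx], dtype=object)


def accuracy(dec: Decoder, epochs: TrialEpochs) -> float:
    """Fraction of epochs whose predicted label matches the true label."""
    return float(np.mean(predict(dec, epochs) == epochs.labels))


def cross_val_accuracy(epochs: TrialEpochs,
                       cfg: DecoderConfig = DecoderConfig(),
                       n_splits: int = 5, seed: int = 0) -> float:
    """Stratified k-fold accuracy with CSP refitted inside each fold."""
    y = epochs.labels.astype(str)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    hits = 0
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        dec = _fit(epochs.subset(train_idx), cfg, sessions=[])
        hits += int(np.sum(predict(dec, epochs.subset(test_idx))
                           == y[test_idx]))
    return hits / len(y)
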