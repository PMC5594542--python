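"""Common spatial patterns: two-class and one-vs-rest multi-class.

CSP learns spatial filters ``w`` that maximize the variance of one class
relative to the other by solving the generalized eigenproblem

    Sigma_a w = lambda (Sigma_a + Sigma_b) w,

where ``Sigma_a`` and ``Sigma_b`` are per-class average covariance
matrices, each trial's covariance normalized by its trace to suppress
inter-trial amplitude scaling. Eigenvalues lie in [0, 1]; filters at both
ends of the spectrum carry the discriminative variance contrast, so
``n_pairs`` filters from each end are retained.

Features are normalized log-variances of the filtered epochs; for the
multi-class case, one-vs-rest models are fitted in a fixed label order and
their features concatenated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .containers import TrialEpochs, concat_epochs
from .errors import CSPError, PredictionError, TrainingError


@dataclass
class CSPModel:
    """Fitted spatial-filter bank for one binary contrast.

    ``unmixing`` holds every filter (rows), ordered by descending
    eigenvalue; ``selected`` indexes the retained ``2 * n_pairs`` rows
    (``n_pairs`` from each end of the spectrum).
    """

    unmixing: np.ndarray          # (n_channels, n_channels), rows = filters
    eigenvalues: np.ndarray       # (n_channels,), descending, in [0, 1]
    n_pairs: int
    class_pair: tuple[str, str]
    channels: tuple[str, ...]
    selected: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.selected is None:
            c = self.unmixing.shape[0]
            p = self.n_pairs
            self.selected = np.r_[np.arange(p), np.arange(c - p, c)]

    @property
    def filters(self) -> np.ndarray:
        """Retained filters, (2 * n_pairs, n_channels)."""
        return self.unmixing[self.selected]


def _class_covariance(data: np.ndarray) -> np.ndarray:
    """Average trace-normalized covariance over trials of (T, C, S) data."""
    covs = np.einsum("tcs,tds->tcd", data, data)
    traces = np.trace(covs, axis1=1, axis2=2)
    return (covs / traces[:, None, None]).mean(axis=0)


def _fix_signs(w: np.ndarray) -> np.ndarray:
    """Scale each filter so its largest-magnitude coefficient is positive."""
    idx = np.argmax(np.abs(w), axis=1)
    signs = np.sign(w[np.arange(w.shape[0]), idx])
    signs[signs == 0] = 1.0
    return w * signs[:, None]


def csp_fit(epochs_a: TrialEpochs, epochs_b: TrialEpochs, n_pairs: int = 3,
            shrinkage: float = 0.0) -> CSPModel:
    """Fit two-class CSP filters from labeled epoch sets.

    ``shrinkage`` mixes each class covariance with a scaled identity
    (gamma in [0, 1]); if the composite covariance is ill-conditioned a
    small shrinkage is applied automatically with a warning.
    """
    if epochs_a.n_trials < 2 or epochs_b.n_trials < 2:
        raise TrainingError("csp_fit needs at least 2 epochs per class")
    if epochs_a.channels != epochs_b.channels:
        raise TrainingError("epoch sets must share the channel montage")
    n_ch = epochs_a.data.shape[1]
    if not 1 <= n_pairs <= n_ch // 2:
        raise TrainingError(f"n_pairs must be in [1, {n_ch // 2}]")
    la = epochs_a.labels[0] if len(set(epochs_a.labels)) == 1 else "a"
    lb = epochs_b.labels[0] if len(set(epochs_b.labels)) == 1 else "b"

    sa = _class_covariance(epochs_a.data)
    sb = _class_covariance(epochs_b.data)

    def shrink(s: np.ndarray, gamma: float) -> np.ndarray:
        mu = np.trace(s) / n_ch
        return (1 - gamma) * s + gamma * mu * np.eye(n_ch)

    gamma = shrinkage
    comp = shrink(sa, gamma) + shrink(sb, gamma)
    if np.linalg.cond(comp) > 1e10 and gamma < 1e-5:
        gamma = 1e-5
        warnings.warn("composite covariance ill-conditioned; applying "
                      f"shrinkage gamma={gamma}", stacklevel=2)
        comp = shrink(sa, gamma) + shrink(sb, gamma)
    try:
        vals, vecs = scipy.linalg.eigh(shrink(sa, gamma), comp)
    except (scipy.linalg.LinAlgError, ValueError):
        gamma = max(gamma, 1e-4)
        warnings.warn("generalized eigendecomposition failed; retrying with "
                      f"shrinkage gamma={gamma}", stacklevel=2)
        try:
            vals, vecs = scipy.linalg.eigh(
                shrink(sa, gamma), shrink(sa, gamma) + shrink(sb, gamma))
        except (scipy.linalg.LinAlgError, ValueError) as exc:
            raise CSPError("covariance decomposition failed") from exc

    order = np.argsort(vals)[::-1]
    eigenvalues = np.clip(vals[order], 0.0, 1.0)
    unmixing = _fix_signs(vecs.T[order])
    return CSPModel(unmixing, eigenvalues, n_pairs, (str(la), str(lb)),
                    epochs_a.channels)


def multi_csp_fit(epochs: TrialEpochs, n_pairs: int = 3,
                  shrinkage: float = 0.0,
                  scheme: str = "ovr") -> list[CSPModel]:
    """One CSP model per class (one-vs-rest) or per pair (pairwise).

    Models are returned in sorted label order, so the feature layout is
    deterministic.
    """
    classes = epochs.classes()
    for c in classes:
        if (epochs.labels == c).sum() < 2:
            raise TrainingError(f"class {c!r} has fewer than 2 epochs")
    models = []
    if scheme == "ovr":
        for c in classes:
            own = epochs.where(c)
            rest = epochs.subset(epochs.labels != c)
            m = csp_fit(own, rest, n_pairs, shrinkage)
            m.class_pair = (c, "rest")
            models.append(m)
    elif scheme == "pairwise":
        for i, ci in enumerate(classes):
            for cj in classes[i + 1:]:
                m = csp_fit(epochs.where(ci), epochs.where(cj),
                            n_pairs, shrinkage)
                m.class_pair = (ci, cj)
                models.append(m)
    else:
        raise TrainingError(f"unknown multi-class scheme {scheme!r}")
    return models


def csp_transform(models: CSPModel | list[CSPModel],
                  epochs: TrialEpochs) -> np.ndarray:
    """Normalized log-variance features, (n_trials, n_features).

    Per model: project each epoch onto the retained filters, take the
    per-component variance, divide by the sum over retained components,
    and take the log. Features from multiple models are concatenated.
    """
    if isinstance(models, CSPModel):
        models = [models]
    feats = []
    for m in models:
        if epochs.channels != m.channels:
            raise PredictionError("epoch channels do not match the CSP model")
        z = np.einsum("fc,tcs->tfs", m.filters, epochs.data)
        v = z.var(axis=2)
        v /= v.sum(axis=1, keepdims=True)
        feats.append(np.log(v))
    return np.concatenate(feats, axis=1)


def fit_and_transform(epochs: TrialEpochs, n_pairs: int = 3,
                      shrinkage: float = 0.0, scheme: str = "ovr",
                      ) -> tuple[list[CSPModel], np.ndarray]:
    """Fit binary or multi-class CSP depending on the label count."""
    classes = epochs.classes()
    if len(classes) < 2:
        raise TrainingError("need at least two classes")
    if len(classes) == 2:
        models = [csp_fit(epochs.where(classes[0]), epochs.where(classes[1]),
                          n_pairs, shrinkage)]
        models[0].class_pair = (classes[0], classes[1])
    else:
        models = multi_csp_fit(epochs, n_pairs, shrinkage, scheme)
    return models, csp_transform(models, epochs)


__all__ = ["CSPModel", "csp_fit", "multi_csp_fit", "csp_transform",
           "fit_and_transform", "concat_epochs"]
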