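"""Simulated online session and cohort-level summaries.

``run_online`` replays the session-5 protocol trial by trial: the
motor-imagery window of each trial is epoched, classified with the frozen
three-class decoder, and a feedback event (predicted label + correctness)
is logged. The online path adds no stochasticity: its accuracy equals
offline prediction on the same epochs.

``run_subject`` executes the whole five-session protocol for one simulated
subject; ``simulate_cohort`` repeats it over seeds to emulate a subject
cohort, and ``summarize_sessions`` aggregates accuracies with paired
between-session comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Recording, TrialEpochs, concat_epochs
from .decode import (Decoder, DecoderConfig, cross_val_accuracy, predict,
                     train_three_class, train_two_class, update_decoder)
from .errors import ConfigError, ProtocolError
from .preprocess import PreprocessConfig, mi_epochs
from .simulate import (GeneratorConfig, jittered_config, plan_sessions,
                       synthesize_recording)


def chance_level(n_classes: int) -> float:
    """Expected accuracy of uniform guessing on balanced classes."""
    if n_classes < 2:
        raise ConfigError("n_classes must be at least 2")
    return 1.0 / n_classes


@dataclass
class SessionResult:
    """Per-trial outcomes of one classified session.

    ``confusion`` is the row-normalized output distribution: rows are the
    intended class, columns the decoder output, in ``classes`` order.
    """

    records: pd.DataFrame            # true, pred, block, trial
    classes: tuple[str, ...]
    feedback: list[dict] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.records["true"] == self.records["pred"]))

    @property
    def counts(self) -> np.ndarray:
        k = len(self.classes)
        idx = {c: i for i, c in enumerate(self.classes)}
        m = np.zeros((k, k))
        for t, p in zip(self.records["true"], self.records["pred"]):
            m[idx[t], idx[p]] += 1
        return m

    @property
    def confusion(self) -> np.ndarray:
        m = self.counts
        sums = m.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            out = np.where(sums > 0, m / sums, 0.0)
        return out


def run_online(dec: Decoder, session5: Recording,
               cfg: PreprocessConfig = PreprocessConfig()) -> SessionResult:
    """Trial-by-trial classification of the online session with feedback log."""
    if len(dec.classes) != 3:
        raise ProtocolError("the online session requires a three-class decoder")
    epochs = mi_epochs(session5, cfg)
    unknown = sorted(set(epochs.labels) - set(dec.classes))
    if unknown:
        raise ProtocolError(f"recording contains labels {unknown} the "
                            "decoder does not score")
    mi_events = session5.events[session5.events["segment"] == "MI"]
    preds = predict(dec, epochs)
    rows, feedback = [], []
    for (_, ev), true, pred in zip(mi_events.iterrows(),
                                   epochs.labels, preds):
        rows.append({"true": true, "pred": pred,
                     "block": int(ev["block"]), "trial": int(ev["trial"])})
        feedback.append({"trial": int(ev["trial"]), "predicted": pred,
                         "correct": bool(pred == true)})
    return SessionResult(pd.DataFrame(rows), dec.classes, feedback)


@dataclass
class SubjectRun:
    """Outcome of the full five-session protocol for one simulated subject."""

    seed: int
    accuracies: dict[int, float]     # session id -> accuracy
    session5: SessionResult
    decoder: Decoder                 # final three-class decoder


def run_subject(gen_cfg: GeneratorConfig = GeneratorConfig(),
                seed: int | None = None,
                pp_cfg: PreprocessConfig = PreprocessConfig(),
                dec_cfg: DecoderConfig = DecoderConfig()) -> SubjectRun:
    """Simulate one subject and run the complete classifier protocol.

    Session 1 accuracy is cross-validated (that session is offline);
    sessions 2 and 3 are decoded with the decoder available at the time
    (trained on the preceding sessions), mirroring the feedback protocol;
    session 5 is the online three-class evaluation.
    """
    if seed is None:
        seed = gen_cfg.seed
    plans = {p.session_id: p for p in plan_sessions(seed)}

    def session_epochs(sid: int) -> TrialEpochs:
        rec = synthesize_recording(plans[sid], gen_cfg, seed)
        return mi_epochs(rec, pp_cfg)

    ep1, ep2, ep3 = (session_epochs(s) for s in (1, 2, 3))
    acc = {1: cross_val_accuracy(ep1, dec_cfg, seed=seed)}
    dec12 = train_two_class(ep1, dec_cfg, sessions=(1,))
    acc[2] = float(np.mean(predict(dec12, ep2) == ep2.labels))
    dec12 = update_decoder(dec12, ep2, session=2)
    acc[3] = float(np.mean(predict(dec12, ep3) == ep3.labels))

    ep4 = session_epochs(4)
    dec3 = train_three_class(concat_epochs([ep1, ep2, ep3, ep4]), dec_cfg,
                             sessions=(1, 2, 3, 4))
    rec5 = synthesize_recording(plans[5], gen_cfg, seed)
    res5 = run_online(dec3, rec5, pp_cfg)
    acc[5] = res5.accuracy
    return SubjectRun(int(seed), acc, res5, dec3)


def simulate_cohort(n_subjects: int = 20,
                    gen_cfg: GeneratorConfig = GeneratorConfig(),
                    pp_cfg: PreprocessConfig = PreprocessConfig(),
                    dec_cfg: DecoderConfig = DecoderConfig(),
                    first_seed: int = 0,
                    depth_jitter_sd: float = 0.0,
                    ) -> tuple[pd.DataFrame, list[SubjectRun]]:
    """Run the full protocol for ``n_subjects`` independent seeds.

    ``depth_jitter_sd`` > 0 perturbs each subject's ERD depths to emulate
    between-subject variability. Returns a (subject x session) accuracy
    table and the per-subject run objects.
    """
    runs = []
    for i in range(n_subjects):
        seed = first_seed + i
        cfg_i = jittered_config(gen_cfg, seed, depth_jitter_sd)
        runs.append(run_subject(cfg_i, seed, pp_cfg, dec_cfg))
    table = pd.DataFrame(
        [{"subject": r.seed, **{f"session{k}": v
                                for k, v in sorted(r.accuracies.items())}}
         for r in runs]).set_index("subject")
    return table, runs


def summarize_sessions(table: pd.DataFrame,
                       runs: list[SubjectRun] | None = None) -> dict:
    """Cohort summary: per-session stats and paired between-session tests.

    ``table`` is a (subject x session) accuracy DataFrame as produced by
    :func:`simulate_cohort`. Paired t-tests compare every session column
    pair across subjects; with ``runs`` given, session-5 confusion
    matrices are aggregated (pooled trial counts, then row-normalized).
    """
    if len(table) == 0:
        raise ConfigError("summary needs at least one subject")
    out: dict = {
        "per_session": {
            col: {"mean": float(table[col].mean()),
                  "min": float(table[col].min()),
                  "max": float(table[col].max())}
            for col in table.columns
        },
        "paired_tests": {},
    }
    cols = list(table.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            d = table[a] - table[b]
            if np.allclose(d, 0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(table[a], table[b])
            out["paired_tests"][f"{a}_vs_{b}"] = {"t": float(t),
                                                  "p": float(p)}
    if runs:
        counts = np.sum([r.session5.counts for r in runs], axis=0)
        sums = counts.sum(axis=1, keepdims=True)
        out["confusion"] = np.where(sums > 0, counts / sums, 0.0).tolist()
        out["classes"] = list(runs[0].session5.classes)
    return out
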