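"""EMG screening: verify that motor imagery is free of muscle activity.

The EMG channel is conditioned with a 50 Hz notch and a 5-500 Hz band-pass
(upper edge clipped below Nyquist when the sampling rate is exactly
1 kHz), and summarized per trial by the integrated EMG

    IEMG = sum_i |x_i|,

the sum of rectified samples over the trial. Motor-execution trials must
show significantly larger IEMG than relaxed trials, while motor-imagery
trials must not — the evidence that imagery was performed without
contraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal, stats

from .containers import Recording
from .errors import ConfigError, PairingError
from .montage import EMG_LABEL

#: segment/label -> reported task condition
CONDITION_MAP = {
    ("ME", "high"): "MEH", ("ME", "low"): "MEL",
    ("MI", "high"): "MIH", ("MI", "low"): "MIL",
    ("MI", "relaxed"): "RX",
}


def emg_preprocess(x: np.ndarray, fs: float,
                   notch_hz: float = 50.0,
                   band: tuple[float, float] = (5.0, 500.0),
                   order: int = 4) -> np.ndarray:
    """50 Hz notch followed by a 5-500 Hz band-pass (zero phase)."""
    lo, hi = band
    hi_eff = min(hi, 0.49 * fs)
    if fs < 1000.0 or hi_eff <= lo:
        raise ConfigError(
            f"sampling rate {fs} Hz is too low for the {band} Hz EMG band")
    x = np.asarray(x, dtype=float)
    b, a = signal.iirnotch(notch_hz, Q=30.0, fs=fs)
    y = signal.filtfilt(b, a, x)
    sos = signal.butter(order, (lo, hi_eff), btype="bandpass", fs=fs,
                        output="sos")
    return signal.sosfiltfilt(sos, y)


def iemg(x: np.ndarray) -> float:
    """Integrated EMG of one trial: sum of rectified samples."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ConfigError("iemg of an empty trace is undefined")
    return float(np.abs(x).sum())


def iemg_table(rec: Recording, emg_label: str = EMG_LABEL,
               preprocess: bool = True) -> pd.DataFrame:
    """Per-trial IEMG for every task segment of a session recording.

    Returns a DataFrame with columns (session, block, trial, condition,
    iemg), conditions named MEH/MEL/MIH/MIL/RX.
    """
    trace = rec.channel(emg_label)
    if preprocess:
        trace = emg_preprocess(trace, rec.fs)
    rows = []
    for _, ev in rec.events.iterrows():
        key = (ev["segment"], ev["label"])
        if key not in CONDITION_MAP:
            continue
        i0 = int(round(ev["onset_s"] * rec.fs))
        i1 = int(round((ev["onset_s"] + ev["duration_s"]) * rec.fs))
        rows.append({"session": int(ev["session"]), "block": int(ev["block"]),
                     "trial": int(ev["trial"]),
                     "condition": CONDITION_MAP[key],
                     "iemg": iemg(trace[i0:i1])})
    return pd.DataFrame(rows)


def compare_iemg(task_values, rx_values, alpha: float = 0.05) -> dict:
    """Paired t-test of one task condition's IEMG against relaxed trials.

    Lists are paired by position; unequal lengths are truncated to the
    shorter one. A zero difference everywhere reports t = 0, p = 1.
    """
    a = np.asarray(task_values, dtype=float)
    b = np.asarray(rx_values, dtype=float)
    n = min(len(a), len(b))
    if n < 2:
        raise PairingError("paired comparison needs at least 2 trials per side")
    a, b = a[:n], b[:n]
    if np.allclose(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "n": int(n),
            "mean_task": float(a.mean()), "mean_rx": float(b.mean()),
            "significant": bool(p < alpha)}


def emg_report(tables: pd.DataFrame | list[pd.DataFrame],
               alpha: float = 0.05) -> dict:
    """ME/MI-vs-RX comparison report over pooled per-trial IEMG tables.

    ``mi_clean`` is True when no motor-imagery condition differs
    significantly from relaxed — the screen for covert muscle activity.
    """
    if isinstance(tables, list):
        tables = pd.concat(tables, ignore_index=True)
    rx = tables.loc[tables["condition"] == "RX", "iemg"].to_numpy()
    if rx.size < 2:
        raise PairingError("report needs at least 2 relaxed trials")
    out: dict = {"comparisons": {}, "mean_iemg": {
        c: float(g["iemg"].mean()) for c, g in tables.groupby("condition")}}
    for cond in ("MEH", "MEL", "MIH", "MIL"):
        vals = tables.loc[tables["condition"] == cond, "iemg"].to_numpy()
        if vals.size >= 2:
            out["comparisons"][cond] = compare_iemg(vals, rx, alpha)
    mi = [out["comparisons"][c] for c in ("MIH", "MIL")
          if c in out["comparisons"]]
    out["mi_clean"] = bool(mi) and all(not c["significant"] for c in mi)
    return out
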