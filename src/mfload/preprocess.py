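"""EEG conditioning: channel selection, resampling, filtering, CAR, epoching.

The decoding path mirrors the acquisition/analysis chain: select the 60
scalp channels (dropping mastoids M1/M2 and ocular leads HEO/VEO),
downsample 1000 -> 200 Hz, band-pass 8-30 Hz with a zero-phase Butterworth
filter, re-reference to the common average, then cut task epochs.

All filters are applied forward-backward (zero phase), so ERD onset
latencies are not smeared by filter delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import ChannelMatrix, Recording, TrialEpochs
from .errors import ChannelSelectionError, ConfigError, EpochingError
from .montage import EMG_LABEL, EXCLUDED


@dataclass(frozen=True)
class PreprocessConfig:
    """Decoding-path preprocessing parameters."""

    fs_out: float = 200.0
    band: tuple[float, float] = (8.0, 30.0)
    order: int = 4
    window: tuple[float, float] = (0.0, 6.0)  # classification epoch, s from MI onset
    car: bool = True


def select_channels(rec: Recording,
                    exclude: tuple[str, ...] = EXCLUDED + (EMG_LABEL,),
                    require: tuple[str, ...] | None = None) -> ChannelMatrix:
    """Analysis channels of a recording, preserving input order.

    Drops ``exclude`` labels where present. If ``require`` is given, every
    listed label must survive selection; missing ones raise
    :class:`ChannelSelectionError` naming the absences.
    """
    keep = [i for i, lb in enumerate(rec.labels) if lb not in exclude]
    labels = tuple(rec.labels[i] for i in keep)
    if require is not None:
        missing = [lb for lb in require if lb not in labels]
        if missing:
            raise ChannelSelectionError(
                f"recording is missing expected channels: {missing}")
    if not keep:
        raise ChannelSelectionError("no channels left after exclusion")
    return ChannelMatrix(rec.data[keep], rec.fs, labels)


def downsample(x: ChannelMatrix, fs_out: float) -> ChannelMatrix:
    """Anti-alias filter and decimate to ``fs_out``.

    The decimation ratio must be an integer; the output holds
    ``floor(n_in * fs_out / fs_in)`` samples.
    """
    ratio = x.fs / fs_out
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ConfigError(
            f"fs_out={fs_out} must integer-divide fs={x.fs}")
    if q == 1:
        return x.copy_with(x.data.copy())
    # polyphase FIR anti-alias + decimation; line padding tames edge
    # transients on non-zero-mean signals
    y = signal.resample_poly(x.data, up=1, down=q, axis=1, padtype="line")
    n_out = (x.data.shape[1] * int(round(fs_out))) // int(round(x.fs))
    return ChannelMatrix(y[:, :n_out], fs_out, x.labels, x.t0)


def bandpass_eeg(x: ChannelMatrix, lo: float = 8.0, hi: float = 30.0,
                 order: int = 4) -> ChannelMatrix:
    """Zero-phase Butterworth band-pass, per channel."""
    if not 0 < lo < hi < x.fs / 2:
        raise ConfigError(f"band ({lo}, {hi}) must satisfy 0 < lo < hi < fs/2")
    sos = signal.butter(order, (lo, hi), btype="bandpass", fs=x.fs,
                        output="sos")
    return x.copy_with(signal.sosfiltfilt(sos, x.data, axis=1))


def notch(x: ChannelMatrix, f0: float = 50.0, q: float = 30.0) -> ChannelMatrix:
    """Zero-phase narrow band-stop at ``f0`` (power-line interference)."""
    if not 0 < f0 < x.fs / 2:
        raise ConfigError(f"notch frequency {f0} must lie in (0, fs/2)")
    b, a = signal.iirnotch(f0, Q=q, fs=x.fs)
    return x.copy_with(signal.filtfilt(b, a, x.data, axis=1))


def common_average_reference(x: ChannelMatrix) -> ChannelMatrix:
    """Subtract the instantaneous cross-channel mean from every channel.

    After re-referencing, the channel sum is zero at every sample.
    """
    if x.data.shape[0] < 2:
        raise ConfigError("CAR requires at least 2 channels")
    return x.copy_with(x.data - x.data.mean(axis=0, keepdims=True))


def epoch(x: ChannelMatrix, events: pd.DataFrame,
          window: tuple[float, float], which: str = "MI") -> TrialEpochs:
    """Cut one epoch per event of segment ``which``.

    ``window`` is (t_start, t_end) in seconds relative to segment onset,
    half-open: samples cover ``[onset + t_start, onset + t_end)``. Trial
    labels are copied from the event table.
    """
    t_start, t_end = window
    if not t_end > t_start:
        raise EpochingError(f"empty epoch window {window}")
    sel = events[events["segment"] == which]
    if len(sel) == 0:
        raise EpochingError(f"no events with segment {which!r}")
    n_len = int(round((t_end - t_start) * x.fs))
    n_total = x.data.shape[1]
    chunks, labels = [], []
    for _, ev in sel.iterrows():
        i0 = int(round((ev["onset_s"] + t_start - x.t0) * x.fs))
        i1 = i0 + n_len
        if i0 < 0 or i1 > n_total:
            raise EpochingError(
                f"window {window} for trial {ev['trial']} "
                f"(session {ev['session']}) exceeds recording bounds")
        chunks.append(x.data[:, i0:i1])
        labels.append(ev["label"])
    data = np.stack(chunks, axis=0)
    return TrialEpochs(data, x.fs, np.array(labels, dtype=object),
                       x.labels, tmin=float(t_start))


def preprocess_recording(rec: Recording, cfg: PreprocessConfig = PreprocessConfig(),
                         require: tuple[str, ...] | None = None) -> ChannelMatrix:
    """Full decoding-path conditioning: select, downsample, band-pass, CAR."""
    x = select_channels(rec, require=require)
    x = downsample(x, cfg.fs_out)
    x = bandpass_eeg(x, *cfg.band, order=cfg.order)
    if cfg.car:
        x = common_average_reference(x)
    return x


def mi_epochs(rec: Recording, cfg: PreprocessConfig = PreprocessConfig(),
              window: tuple[float, float] | None = None) -> TrialEpochs:
    """Conditioned motor-imagery epochs of one recording."""
    x = preprocess_recording(rec, cfg)
    return epoch(x, rec.events, window or cfg.window, "MI")
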