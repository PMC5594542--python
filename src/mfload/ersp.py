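"""Event-related spectral perturbation (ERSP) analysis.

Per trial, power is estimated with a short-time Fourier transform using a
256-sample Hanning window; trial powers are averaged first, then converted
to dB and baseline-normalized by subtracting, per frequency, the mean dB
level over the pre-onset baseline window. A multiplicative amplitude
attenuation ``a`` of an oscillation therefore maps to ``20*log10(a)`` dB.

Baseline columns are those STFT frames whose window lies entirely inside
the baseline interval, so post-onset samples cannot leak into the
reference level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .containers import TrialEpochs
from .errors import ConfigError, PairingError, RangeError
from .montage import positions

_EPS = 1e-300


@dataclass(frozen=True)
class ERSPConfig:
    """STFT and normalization parameters."""

    n_fft: int = 256
    overlap: float = 0.75
    baseline: tuple[float, float] = (-2.0, 0.0)


@dataclass
class ERSPMap:
    """Baseline-normalized time-frequency map (dB) for one channel."""

    values: np.ndarray            # (n_freqs, n_times), dB
    freqs: np.ndarray             # Hz
    times: np.ndarray             # s relative to task onset (frame centers)
    channel: str
    baseline: tuple[float, float]
    n_trials: int
    baseline_mask: np.ndarray     # frames used as the 0 dB reference

    def band_freq_mask(self, band: tuple[float, float]) -> np.ndarray:
        return (self.freqs >= band[0]) & (self.freqs <= band[1])


def _trial_power(data: np.ndarray, fs: float, cfg: ERSPConfig):
    """Trial-averaged STFT power: (freqs, frame times rel. epoch start, P)."""
    win = signal.get_window("hann", cfg.n_fft)
    noverlap = int(round(cfg.n_fft * cfg.overlap))
    freqs, t, spec = signal.spectrogram(
        data, fs=fs, window=win, noverlap=noverlap, nfft=cfg.n_fft,
        detrend=False, mode="psd", axis=-1)
    return freqs, t, spec.mean(axis=0)


def ersp_compute(epochs: TrialEpochs, channel: str,
                 cfg: ERSPConfig = ERSPConfig()) -> ERSPMap:
    """ERSP map of one channel from epochs spanning the baseline and task."""
    if channel not in epochs.channels:
        raise ConfigError(f"channel {channel!r} not in epochs")
    if epochs.n_samples < cfg.n_fft:
        raise ConfigError(
            f"epochs ({epochs.n_samples} samples) shorter than the "
            f"{cfg.n_fft}-sample STFT window")
    x = epochs.data[:, epochs.channels.index(channel), :]
    freqs, t, power = _trial_power(x, epochs.fs, cfg)
    times = t + epochs.tmin
    half = (cfg.n_fft / 2) / epochs.fs
    b0, b1 = cfg.baseline
    mask = (times - half >= b0 - 1e-9) & (times + half <= b1 + 1e-9)
    if not mask.any():
        raise ConfigError(
            f"no STFT frame lies fully inside the baseline {cfg.baseline}")
    db = 10.0 * np.log10(power + _EPS)
    db -= db[:, mask].mean(axis=1, keepdims=True)
    return ERSPMap(db, freqs, times, channel, (b0, b1),
                   epochs.n_trials, mask)


def band_mean(ersp: ERSPMap, band: tuple[float, float],
              window: tuple[float, float]) -> float:
    """Mean dB over a frequency band x time window rectangle (inclusive)."""
    fm = ersp.band_freq_mask(band)
    tm = (ersp.times >= window[0]) & (ersp.times <= window[1])
    if not fm.any() or not tm.any():
        raise RangeError(f"band {band} x window {window} does not intersect "
                         "the ERSP grid")
    return float(ersp.values[np.ix_(fm, tm)].mean())


def band_topography(epochs: TrialEpochs, band: tuple[float, float],
                    window: tuple[float, float],
                    cfg: ERSPConfig = ERSPConfig()) -> np.ndarray:
    """Per-channel band-mean ERSP (dB), one value per epoch channel."""
    freqs, t, _ = _trial_power(epochs.data[:1, 0], epochs.fs, cfg)
    times = t + epochs.tmin
    half = (cfg.n_fft / 2) / epochs.fs
    b0, b1 = cfg.baseline
    bmask = (times - half >= b0 - 1e-9) & (times + half <= b1 + 1e-9)
    if not bmask.any():
        raise ConfigError("no STFT frame lies fully inside the baseline")
    fm = (freqs >= band[0]) & (freqs <= band[1])
    tm = (times >= window[0]) & (times <= window[1])
    if not fm.any() or not tm.any():
        raise RangeError("band/window does not intersect the ERSP grid")
    win = signal.get_window("hann", cfg.n_fft)
    noverlap = int(round(cfg.n_fft * cfg.overlap))
    _, _, spec = signal.spectrogram(
        epochs.data, fs=epochs.fs, window=win, noverlap=noverlap,
        nfft=cfg.n_fft, detrend=False, mode="psd", axis=-1)
    power = spec.mean(axis=0)                       # (channels, freqs, times)
    db = 10.0 * np.log10(power + _EPS)
    db -= db[:, :, bmask].mean(axis=2, keepdims=True)
    return db[:, fm][:, :, tm].mean(axis=(1, 2))


def ersp_topography(band_means: dict[str, np.ndarray],
                    labels: tuple[str, ...]) -> pd.DataFrame:
    """Condition-wise channel vectors arranged for topographic rendering.

    ``band_means`` maps condition name -> per-channel dB vector aligned
    with ``labels``. Channel layout positions must exist for every label.
    """
    positions(labels)  # raises ConfigError if any label has no position
    df = pd.DataFrame(index=list(labels))
    for cond, vals in band_means.items():
        vals = np.asarray(vals, dtype=float)
        if vals.shape != (len(labels),):
            raise ConfigError(
                f"condition {cond!r} has {vals.shape} values for "
                f"{len(labels)} channels")
        df[cond] = vals
    return df


def paired_difference_map(cond_a: np.ndarray, cond_b: np.ndarray,
                          alpha: float = 0.05) -> dict:
    """Channel-wise paired t-test between two conditions across subjects.

    ``cond_a`` and ``cond_b`` are (n_subjects, n_channels) matrices with
    matching subject rows. Returns the mean difference map with entries
    masked (NaN) where the paired test is not significant at ``alpha``.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise PairingError("conditions must be matching (subjects, channels) "
                           "matrices")
    if a.shape[0] < 3:
        raise PairingError("paired map needs at least 3 subjects")
    diff = a - b
    t = np.zeros(a.shape[1])
    p = np.ones(a.shape[1])
    varying = diff.std(axis=0) > 0
    if varying.any():
        t_v, p_v = stats.ttest_rel(a[:, varying], b[:, varying], axis=0)
        t[varying], p[varying] = t_v, p_v
    mean_diff = diff.mean(axis=0)
    masked = np.where(p < alpha, mean_diff, np.nan)
    return {"difference": mean_diff, "t": t, "p": p,
            "significant": p < alpha, "masked": masked}


def plot_ersp(ersp: ERSPMap, ax=None, vlim: float | None = None):
    """Render an ERSP map (time x frequency, dB color scale)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if vlim is None:
        vlim = float(np.nanmax(np.abs(ersp.values))) or 1.0
    mesh = ax.pcolormesh(ersp.times, ersp.freqs, ersp.values,
                         cmap="RdBu_r", vmin=-vlim, vmax=vlim,
                         shading="nearest")
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set(xlabel="time (s)", ylabel="frequency (Hz)",
           title=f"ERSP at {ersp.channel} (n={ersp.n_trials})")
    ax.figure.colorbar(mesh, ax=ax, label="dB")
    return ax


def plot_topography(values: np.ndarray, labels: tuple[str, ...], ax=None,
                    title: str = ""):
    """Scatter-style scalp map of per-channel values on layout positions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pos = positions(labels)
    vals = np.asarray(values, dtype=float)
    vlim = np.nanmax(np.abs(vals)) or 1.0
    sc = ax.scatter(pos[:, 0], pos[:, 1], c=vals, s=180, cmap="RdBu_r",
                    vmin=-vlim, vmax=vlim, edgecolors="k")
    for (x, y), lb in zip(pos, labels):
        ax.annotate(lb, (x, y), fontsize=5, ha="center", va="center")
    ax.set(aspect="equal", title=title)
    ax.axis("off")
    ax.figure.colorbar(sc, ax=ax, label="dB")
    return ax
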