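"""In-memory containers shared by all pipeline stages.

Amplitudes are in microvolts throughout; times are seconds relative to the
start of the recording (continuous data) or to task onset (epochs), with
0-based sample indexing and half-open windows ``[t_start, t_end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

#: Columns of the event table attached to every recording.
EVENT_COLUMNS = ("onset_s", "duration_s", "segment", "label",
                 "session", "block", "trial")


@dataclass
class Recording:
    """Continuous multichannel recording with an event table.

    data : (n_channels, n_samples) float array, microvolts
    fs : sampling rate in Hz
    labels : channel labels, same order as rows of ``data``
    events : DataFrame with :data:`EVENT_COLUMNS`; onsets in seconds from
        the first sample
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    events: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = tuple(self.labels)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ConfigError("data must be (n_channels, n_samples) matching labels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Single-channel trace by label."""
        try:
            return self.data[self.labels.index(label)]
        except ValueError:
            raise ConfigError(f"channel {label!r} not in recording") from None


@dataclass
class ChannelMatrix:
    """Channels x samples block of continuous data (one processing stage)."""

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    t0: float = 0.0

    def __post_init__(self):
        self.labels = tuple(self.labels)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ConfigError("data must be (n_channels, n_samples) matching labels")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")

    def copy_with(self, data: np.ndarray) -> "ChannelMatrix":
        return ChannelMatrix(data, self.fs, self.labels, self.t0)


@dataclass
class TrialEpochs:
    """Stack of equally shaped trials.

    data : (n_trials, n_channels, n_samples)
    labels : per-trial task label ('high' / 'low' / 'relaxed', or the
        segment-qualified names MEH, MEL, ... in EMG analysis)
    tmin : time of the first sample relative to task onset (s)
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    channels: tuple[str, ...]
    tmin: float = 0.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        self.channels = tuple(self.channels)
        if self.data.ndim != 3:
            raise ConfigError("epoch data must be 3-D (trials, channels, samples)")
        if self.data.shape[0] != len(self.labels):
            raise ConfigError("one label per trial required")
        if self.data.shape[1] != len(self.channels):
            raise ConfigError("channel labels must match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.fs

    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def subset(self, index) -> "TrialEpochs":
        """Epochs restricted to a boolean mask or index array over trials."""
        index = np.asarray(index)
        if index.size == 0:
            index = index.astype(int)
        return TrialEpochs(self.data[index], self.fs, self.labels[index],
                           self.channels, self.tmin)

    def where(self, label: str) -> "TrialEpochs":
        return self.subset(self.labels == label)


def concat_epochs(parts: list[TrialEpochs]) -> TrialEpochs:
    """Stack epoch sets that share channels, rate and window."""
    if not parts:
        raise ConfigError("nothing to concatenate")
    first = parts[0]
    for p in parts[1:]:
        if p.channels != first.channels or p.fs != first.fs:
            raise ConfigError("epochs to concatenate must share channels and fs")
        if p.n_samples != first.n_samples or abs(p.tmin - first.tmin) > 1e-9:
            raise ConfigError("epochs to concatenate must share the time window")
    return TrialEpochs(
        np.concatenate([p.data for p in parts], axis=0),
        first.fs,
        np.concatenate([p.labels for p in parts]),
        first.channels,
        first.tmin,
    )
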