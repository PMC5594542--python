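"""Electrode montage for the 64-channel 10-20 layout plus one forearm EMG lead.

The recording montage holds 60 scalp channels used for analysis, two
mastoid channels (M1, M2) and two ocular channels (HEO, VEO) that are
excluded before decoding, and a single surface-EMG channel on the right
extensor carpi radialis longus.

Channel positions are generated from the 10-20 naming grammar (row letter
gives the anterior-posterior coordinate, the digit gives the lateral
coordinate, odd = left) rather than loaded from a digitized montage file.
The positions are unitless 2-D layout coordinates: they are only used for
spatial-decay ranking in the simulator and for topographic rendering, where
ordinal structure is what matters.
"""

from __future__ import annotations

import re

import numpy as np

from .errors import ConfigError

#: 60 scalp channels retained for EEG analysis (10-20 names, front to back).
SCALP_60: tuple[str, ...] = (
    "FP1", "FPZ", "FP2",
    "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "O1", "OZ", "O2",
)

#: Channels recorded but dropped before EEG analysis.
EXCLUDED: tuple[str, ...] = ("M1", "M2", "HEO", "VEO")

#: Full 64-channel EEG cap.
FULL_64: tuple[str, ...] = SCALP_60 + EXCLUDED

EMG_LABEL = "EMG"

#: Compact sensorimotor montage for fast simulations.
SMALL_19: tuple[str, ...] = (
    "F3", "FZ", "F4",
    "FC3", "FCZ", "FC4",
    "C5", "C3", "C1", "CZ", "C2", "C4", "C6",
    "CP3", "CPZ", "CP4",
    "P3", "PZ", "P4",
)

_ROW_Y = {
    "FP": 4.0, "AF": 3.0, "F": 2.0, "FT": 1.0, "FC": 1.0,
    "T": 0.0, "C": 0.0, "TP": -1.0, "CP": -1.0,
    "P": -2.0, "PO": -3.0, "O": -4.0,
}

# Off-grid channels (mastoids, ocular leads) get fixed coordinates.
_SPECIAL = {
    "M1": (-4.6, -1.5), "M2": (4.6, -1.5),
    "HEO": (-4.5, 4.5), "VEO": (0.0, 5.0),
}

_LABEL_RE = re.compile(r"^([A-Z]+?)(Z|\d+)$")


def position(label: str) -> tuple[float, float]:
    """2-D layout coordinate (x: left negative, y: anterior positive)."""
    label = label.upper()
    if label in _SPECIAL:
        return _SPECIAL[label]
    m = _LABEL_RE.match(label)
    if m is None or m.group(1) not in _ROW_Y:
        raise ConfigError(f"no layout position for channel label {label!r}")
    row, num = m.groups()
    y = _ROW_Y[row]
    if num == "Z":
        x = 0.0
    else:
        k = int(num)
        mag = (k + 1) / 2 if k % 2 else k / 2
        x = -mag if k % 2 else mag
    return x, y


def positions(labels) -> np.ndarray:
    """(n, 2) array of layout coordinates for ``labels``."""
    return np.array([position(lb) for lb in labels], dtype=float)


def rank_distance(labels, focus: str) -> np.ndarray:
    """Rank of each channel by Euclidean layout distance from ``focus``.

    The focus channel has rank 0, its nearest neighbour rank 1, and so on.
    Ties are broken by label order, which keeps the ranking deterministic.
    """
    labels = list(labels)
    if focus not in labels:
        raise ConfigError(f"focus channel {focus!r} not in montage")
    pos = positions(labels)
    d = np.linalg.norm(pos - pos[labels.index(focus)], axis=1)
    order = np.argsort(d, kind="stable")
    ranks = np.empty(len(labels), dtype=int)
    ranks[order] = np.arange(len(labels))
    return ranks
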