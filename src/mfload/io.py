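"""Serialization of recordings, epochs and decoder bundles.

Recordings are stored as an uncompressed ``.npz`` array container next to
a CSV event sidecar (``<stem>.events.csv``) and a JSON metadata file
(``<stem>.json``). EDF files are read through :mod:`mne` when available;
writing EDF is not supported.
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EVENT_COLUMNS, Recording, TrialEpochs
from .csp import CSPModel
from .decode import Decoder, DecoderConfig
from .errors import ParseError


def write_recording(rec: Recording, stem: str | Path) -> Path:
    """Write ``<stem>.npz`` + ``<stem>.events.csv`` + ``<stem>.json``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.savez(stem.with_suffix(".npz"), data=rec.data, fs=rec.fs,
             labels=np.array(rec.labels, dtype=object))
    rec.events.to_csv(stem.parent / f"{stem.name}.events.csv", index=False)
    (stem.with_suffix(".json")).write_text(json.dumps(
        {"fs": rec.fs, "labels": list(rec.labels), "meta": rec.meta},
        indent=1))
    return stem.with_suffix(".npz")


def _read_npz_recording(path: Path) -> Recording:
    try:
        with np.load(path, allow_pickle=True) as z:
            data = z["data"]
            fs = float(z["fs"])
            labels = tuple(str(s) for s in z["labels"])
    except (zipfile.BadZipFile, KeyError, ValueError, OSError) as exc:
        raise ParseError(f"cannot read recording container {path}: {exc}") \
            from exc
    stem = path.with_suffix("")
    ev_path = path.parent / f"{stem.name}.events.csv"
    if ev_path.exists():
        events = pd.read_csv(ev_path)
    else:
        events = pd.DataFrame(columns=list(EVENT_COLUMNS))
        import warnings
        warnings.warn(f"no event sidecar found for {path}", stacklevel=2)
    meta_path = stem.with_suffix(".json")
    meta = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text()).get("meta", {})
    return Recording(data, fs, labels, events, meta)


def _read_edf_recording(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ParseError("reading EDF requires the 'edf' extra (mne)") from exc
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise ParseError(f"cannot parse EDF file {path}: {exc}") from exc
    events = pd.DataFrame(
        [{"onset_s": on, "duration_s": du, "segment": desc, "label": "",
          "session": 0, "block": 0, "trial": i}
         for i, (on, du, desc) in enumerate(
             zip(raw.annotations.onset, raw.annotations.duration,
                 raw.annotations.description))],
        columns=list(EVENT_COLUMNS))
    return Recording(raw.get_data() * 1e6, float(raw.info["sfreq"]),
                     tuple(raw.ch_names), events, {"source": str(path)})


def read_recording(path: str | Path) -> Recording:
    """Load a recording from the npz container or an EDF file."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf_recording(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    if not path.exists():
        raise ParseError(f"no recording at {path}")
    return _read_npz_recording(path)


def write_epochs(epochs: TrialEpochs, path: str | Path) -> Path:
    path = Path(path).with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, data=epochs.data, fs=epochs.fs,
             labels=np.array(epochs.labels, dtype=object),
             channels=np.array(epochs.channels, dtype=object),
             tmin=epochs.tmin)
    return path


def read_epochs(path: str | Path) -> TrialEpochs:
    path = Path(path).with_suffix(".npz")
    try:
        with np.load(path, allow_pickle=True) as z:
            return TrialEpochs(z["data"], float(z["fs"]),
                               z["labels"].astype(object),
                               tuple(str(s) for s in z["channels"]),
                               float(z["tmin"]))
    except (zipfile.BadZipFile, KeyError, ValueError, OSError) as exc:
        raise ParseError(f"cannot read epochs container {path}: {exc}") from exc


def write_decoder(dec: Decoder, directory: str | Path) -> Path:
    """Decoder bundle: JSON metadata + one npz of arrays."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "classes": list(dec.classes),
        "trained_on": list(dec.trained_on),
        "config": vars(dec.config) | {},
        "models": [{"class_pair": list(m.class_pair),
                    "n_pairs": m.n_pairs,
                    "channels": list(m.channels)}
                   for m in dec.csp_models],
    }
    (directory / "decoder.json").write_text(json.dumps(meta, indent=1))
    arrays = {"coef": dec.coef, "intercept": dec.intercept}
    for i, m in enumerate(dec.csp_models):
        arrays[f"unmixing_{i}"] = m.unmixing
        arrays[f"eigenvalues_{i}"] = m.eigenvalues
        arrays[f"selected_{i}"] = m.selected
    np.savez(directory / "decoder_arrays.npz", **arrays)
    return directory


def read_decoder(directory: str | Path) -> Decoder:
    directory = Path(directory)
    try:
        meta = json.loads((directory / "decoder.json").read_text())
        z = np.load(directory / "decoder_arrays.npz")
    except (OSError, json.JSONDecodeError, zipfile.BadZipFile) as exc:
        raise ParseError(f"cannot read decoder bundle in {directory}: {exc}") \
            from exc
    models = [
        CSPModel(z[f"unmixing_{i}"], z[f"eigenvalues_{i}"], m["n_pairs"],
                 tuple(m["class_pair"]), tuple(m["channels"]),
                 selected=z[f"selected_{i}"])
        for i, m in enumerate(meta["models"])
    ]
    return Decoder(models, z["coef"], z["intercept"],
                   tuple(meta["classes"]), list(meta["trained_on"]),
                   DecoderConfig(**meta["config"]))
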