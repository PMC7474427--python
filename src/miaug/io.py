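"""Serialization and EEG file readers.

Trial sets and image sets are written as compressed ``.npz`` containers with a
JSON sidecar carrying the metadata (sampling rate, labels, channel names),
which keeps the arrays language-neutral and the metadata human-readable.
Continuous recordings in EDF/GDF (the distribution formats of the public
motor-imagery benchmarks) are read through MNE when it is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import ContinuousRecording, ImageSet
from .simulate import TrialSet

__all__ = [
    "save_trialset",
    "load_trialset",
    "save_imageset",
    "load_imageset",
    "read_recording",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_trialset(trials: TrialSet, path) -> None:
    path = Path(path)
    np.savez_compressed(path, data=trials.data)
    meta = {
        "fs": trials.fs,
        "labels": [str(l) for l in trials.labels],
        "channel_names": list(trials.channel_names),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_trialset(path) -> TrialSet:
    path = Path(path)
    with np.load(path) as archive:
        data = archive["data"]
    meta = json.loads(_sidecar(path).read_text())
    return TrialSet(data, np.array(meta["labels"]), meta["fs"],
                    tuple(meta["channel_names"]))


def save_imageset(images: ImageSet, path) -> None:
    path = Path(path)
    np.savez_compressed(path, pixels=images.pixels.astype(np.float32))
    meta = {
        "labels": [str(l) for l in images.labels],
        "provenance": [str(p) for p in images.provenance],
        "subject_id": images.subject_id,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_imageset(path) -> ImageSet:
    path = Path(path)
    with np.load(path) as archive:
        pixels = archive["pixels"].astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return ImageSet(pixels, np.array(meta["labels"]),
                    np.array(meta["provenance"]), meta.get("subject_id", ""))


def read_recording(path, channels=("C3", "Cz", "C4")) -> ContinuousRecording:
    """Read a continuous EDF/GDF recording (via MNE) restricted to ``channels``.

    Event markers are taken from the file's annotations; their descriptions
    become the trial labels unchanged.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npz":
        trials = load_trialset(path)
        raise ValueError(
            "npz containers hold epoched trials; use load_trialset instead"
        )
    if suffix not in (".edf", ".gdf"):
        raise ValueError(f"unsupported recording format {suffix!r} "
                         "(expected .edf or .gdf)")
    try:
        import mne
    except ImportError as err:  # pragma: no cover - mne is an optional extra
        raise ImportError(
            "reading EDF/GDF recordings requires the optional 'mne' dependency"
        ) from err
    reader = mne.io.read_raw_edf if suffix == ".edf" else mne.io.read_raw_gdf
    raw = reader(path, preload=True, verbose="error")
    picks = [ch for ch in channels if ch in raw.ch_names]
    if len(picks) != len(channels):
        missing = set(channels) - set(picks)
        raise ValueError(f"recording lacks channels {sorted(missing)}")
    raw.pick(picks)
    events = [
        (int(round(onset * raw.info["sfreq"])), str(desc))
        for onset, desc in zip(raw.annotations.onset,
                               raw.annotations.description)
    ]
    return ContinuousRecording(raw.get_data(), float(raw.info["sfreq"]), events,
                               tuple(picks))
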