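"""Recording I/O, band-pass filtering and stimulus segmentation.

On-disk format: a TSV with one row per sample and one column per channel,
plus a JSON sidecar (same stem, ``.json``) carrying the sampling rate,
channel labels, group label and stimulus annotations.  A minimal SNIRF
(HDF5) reader is provided as an optional extra; it is never required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Annotation",
    "Recording",
    "StimulusSegment",
    "read_recording",
    "write_recording",
    "read_snirf",
    "bandpass",
    "segment",
    "STIMULUS_LABELS",
    "CATEGORIES",
]

STIMULUS_LABELS = ("happy", "calm", "fear", "noise")
CATEGORIES = ("happy", "calm", "fear", "full")


@dataclass
class Annotation:
    onset: float      # seconds, 0-based
    duration: float   # seconds; interval is [onset, onset + duration)
    label: str

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"annotation {self.label!r}: duration must be > 0")
        if self.onset < 0:
            raise ValueError(f"annotation {self.label!r}: onset must be >= 0")


@dataclass
class Recording:
    """One participant's continuous multichannel recording."""

    subject_id: str
    group: str                       # "MDD" or "HC"
    channel_ids: list[str]
    fs: float                        # Hz
    signal: np.ndarray               # (time, channels)
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal.ndim != 2 or self.signal.shape[0] < 1 or self.signal.shape[1] < 1:
            raise ValueError("signal must be a non-empty (time, channels) matrix")
        if len(self.channel_ids) != self.signal.shape[1]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.signal.shape[1]} signal columns"
            )
        end = self.signal.shape[0] / self.fs
        for ann in self.annotations:
            if ann.onset + ann.duration > end + 0.5 / self.fs:
                raise ValueError(
                    f"annotation ({ann.label!r} at {ann.onset}s for "
                    f"{ann.duration}s) extends beyond the recording end ({end:.2f}s)"
                )

    @property
    def duration(self) -> float:
        return self.signal.shape[0] / self.fs

    def trials(self, label: str) -> list[Annotation]:
        return [a for a in self.annotations if a.label == label]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path) -> None:
    """Write the signal as TSV and the metadata as a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(rec.signal, columns=rec.channel_ids)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "fs": rec.fs,
        "channel_ids": rec.channel_ids,
        "annotations": [asdict(a) for a in rec.annotations],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_recording(path) -> Recording:
    """Read a TSV + JSON sidecar pair written by :func:`write_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed sidecar {sidecar}: {exc}") from exc
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(frame.columns) != list(meta["channel_ids"]):
        raise ValueError(
            f"{path}: TSV columns {list(frame.columns)} do not match sidecar "
            f"channel_ids {meta['channel_ids']}"
        )
    return Recording(
        subject_id=meta["subject_id"],
        group=meta["group"],
        channel_ids=list(meta["channel_ids"]),
        fs=float(meta["fs"]),
        signal=frame.to_numpy(dtype=float),
        annotations=[Annotation(**a) for a in meta["annotations"]],
    )


def read_snirf(path, subject_id: str = "", group: str = "") -> Recording:
    """Minimal SNIRF reader (optional; requires h5py).

    Reads ``/nirs/data1`` time series and ``/nirs/stim*`` annotation blocks.
    The sampling rate is inferred from the time vector.
    """
    import h5py  # optional dependency

    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        data = nirs["data1"]
        sig = np.asarray(data["dataTimeSeries"], dtype=float)
        t = np.asarray(data["time"], dtype=float).ravel()
        if t.size >= 2:
            fs = 1.0 / np.median(np.diff(t))
        else:
            fs = float(t[0]) if t.size else 1.0
        annotations = []
        for key in sorted(k for k in nirs.keys() if k.startswith("stim")):
            stim = nirs[key]
            name = stim["name"][()]
            if isinstance(name, bytes):
                name = name.decode()
            arr = np.atleast_2d(np.asarray(stim["data"], dtype=float))
            for row in arr:
                annotations.append(Annotation(onset=row[0], duration=row[1], label=str(name)))
        annotations.sort(key=lambda a: a.onset)
    channels = [f"ch{i + 1}" for i in range(sig.shape[1])]
    return Recording(
        subject_id=subject_id,
        group=group,
        channel_ids=channels,
        fs=float(fs),
        signal=sig,
        annotations=annotations,
    )


def bandpass(rec: Recording, low: float = 0.01, high: float = 0.2, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of every channel.

    Forward-backward filtering leaves no group delay; the default 0.01–0.2 Hz
    band removes drift, respiration (0.2–0.5 Hz) and cardiac (>1 Hz) components.
    """
    if not 0 < low < high:
        raise ValueError(f"band edges must satisfy 0 < low < high; got ({low}, {high})")
    if high >= rec.fs / 2:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist ({rec.fs / 2} Hz)")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=0)
    return Recording(
        subject_id=rec.subject_id,
        group=rec.group,
        channel_ids=list(rec.channel_ids),
        fs=rec.fs,
        signal=filtered,
        annotations=list(rec.annotations),
    )


@dataclass
class StimulusSegment:
    """All trials of one stimulus category, concatenated in temporal order."""

    category: str
    signal: np.ndarray               # (time, channels)
    trial_indices: list[int]         # positions in the recording's annotation list
    trial_lengths: list[int]         # samples contributed by each trial
    channel_ids: list[str] = field(default_factory=list)


def segment(
    rec: Recording, category: str, full_excludes_noise: bool = False
) -> StimulusSegment:
    """Concatenate the trials of one category ('full' = every stimulus trial).

    Each trial contributes ``round(duration * fs)`` samples starting at
    ``round(onset * fs)``.  Rest periods are never included.
    """
    if category not in CATEGORIES:
        raise ValueError(f"category must be one of {CATEGORIES}; got {category!r}")
    if category == "full":
        wanted = set(STIMULUS_LABELS) - ({"noise"} if full_excludes_noise else set())
    else:
        wanted = {category}
    chunks, idxs, lengths = [], [], []
    for i, ann in enumerate(rec.annotations):
        if ann.label not in wanted:
            continue
        start = int(round(ann.onset * rec.fs))
        n = int(round(ann.duration * rec.fs))
        chunks.append(rec.signal[start : start + n])
        idxs.append(i)
        lengths.append(n)
    if not chunks:
        raise ValueError(
            f"no trials of category {category!r} in recording {rec.subject_id!r}"
        )
    return StimulusSegment(
        category=category,
        signal=np.concatenate(chunks, axis=0),
        trial_indices=idxs,
        trial_lengths=lengths,
        channel_ids=list(rec.channel_ids),
    )
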