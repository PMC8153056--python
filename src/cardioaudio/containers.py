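"""Lightweight in-memory containers shared by all pipeline stages.

Continuous data are stored channels x samples; epoched data epochs x
channels x samples.  EEG amplitudes are in microvolts, ECG in millivolts,
all time axes in seconds.  Event tables are plain :class:`pandas.DataFrame`
objects using the column dialect documented in :data:`EVENT_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Canonical column order of the events table dialect.
EVENT_COLUMNS = [
    "sample", "onset_s", "kind", "trial", "block",
    "attention", "delay", "omission_trial",
]

EVENT_KINDS = {"rpeak", "cue", "tone", "omission", "response"}


@dataclass
class ContinuousRecording:
    """Multichannel continuous time series with per-channel kind labels."""

    data: np.ndarray          # channels x samples
    fs: float                 # Hz
    ch_names: list[str]
    ch_kinds: list[str]       # "eeg" | "ecg" | "mastoid"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel name count does not match data")
        if len(self.ch_kinds) != self.data.shape[0]:
            raise ValueError("channel kind count does not match data")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def pick(self, kind: str) -> "ContinuousRecording":
        """Sub-recording containing only channels of the given kind."""
        idx = [i for i, k in enumerate(self.ch_kinds) if k == kind]
        if not idx:
            raise ValueError(f"no channels of kind {kind!r}")
        return ContinuousRecording(
            self.data[idx], self.fs,
            [self.ch_names[i] for i in idx],
            [self.ch_kinds[i] for i in idx],
        )

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            self.data.copy(), self.fs, list(self.ch_names), list(self.ch_kinds))


@dataclass
class SensorLayout:
    """2-D sensor layout on (a subset of) the unit disc.

    Coordinates follow the head-schematic convention: +y anterior (front),
    +x right, origin at the vertex.
    """

    ch_names: list[str]
    pos: np.ndarray           # n_channels x 2

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (len(self.ch_names), 2):
            raise ValueError("pos must be n_channels x 2")
        if not np.all(np.isfinite(self.pos)):
            raise ValueError("layout coordinates must be finite")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("duplicate channel labels in layout")

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)

    def subset(self, names: Sequence[str]) -> "SensorLayout":
        idx = [self.ch_names.index(n) for n in names]
        return SensorLayout([self.ch_names[i] for i in idx], self.pos[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"channel": self.ch_names, "x": self.pos[:, 0], "y": self.pos[:, 1]})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SensorLayout":
        return cls(list(df["channel"]), df[["x", "y"]].to_numpy(float))


@dataclass
class EpochSet:
    """Epochs x channels x samples locked to a reference event.

    ``metadata`` has one row per epoch; the ``rpeak_latencies`` column holds,
    for each epoch, the list of R-peak times (s) relative to the lock event
    that fall inside the epoch window (needed for heartbeat-locked artifact
    correction).
    """

    data: np.ndarray          # epochs x channels x samples, µV
    times: np.ndarray         # seconds relative to lock
    fs: float
    ch_names: list[str]
    lock: str                 # "rpeak" | "omission" | "tone"
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time vector length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time vector must be strictly increasing")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel count mismatch")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata rows must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.times.copy(), self.fs,
                        list(self.ch_names), self.lock,
                        self.metadata.reset_index(drop=True).copy())

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(self.data[mask], self.times.copy(), self.fs,
                        list(self.ch_names), self.lock,
                        self.metadata.loc[mask].reset_index(drop=True))

    def drop_channels(self, names: Sequence[str]) -> "EpochSet":
        keep = [i for i, n in enumerate(self.ch_names) if n not in set(names)]
        return EpochSet(self.data[:, keep], self.times.copy(), self.fs,
                        [self.ch_names[i] for i in keep], self.lock,
                        self.metadata.reset_index(drop=True).copy())


@dataclass
class Evoked:
    """Condition-wise average (channels x samples, µV)."""

    data: np.ndarray
    times: np.ndarray
    fs: float
    ch_names: list[str]
    condition: str
    n_epochs: int
    weights: Optional[np.ndarray] = None   # epochs x channels x samples

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.shape != (len(self.ch_names), self.times.size):
            raise ValueError("evoked shape mismatch")

    def copy(self) -> "Evoked":
        return Evoked(self.data.copy(), self.times.copy(), self.fs,
                      list(self.ch_names), self.condition, self.n_epochs,
                      None if self.weights is None else self.weights.copy())


@dataclass
class ArtifactReport:
    """Outcome of one artifact-scanning stage."""

    stage: str                        # "channels_raw" | "trials" | "channels_erp"
    labels: list                      # channel names or trial indices scanned
    metrics: pd.DataFrame             # one row per label, one column per metric
    zscores: pd.DataFrame             # same shape, z across the scanned axis
    flagged: list                     # subset of labels with any |z| > threshold
    threshold: float = 3.0

    def __post_init__(self) -> None:
        if not set(self.flagged) <= set(self.labels):
            raise ValueError("flagged entries must be among scanned labels")


def validate_events(df: pd.DataFrame, fs: Optional[float] = None) -> pd.DataFrame:
    """Check the events-table dialect; returns the frame sorted by sample."""
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    bad_kinds = set(df["kind"]) - EVENT_KINDS
    if bad_kinds:
        raise ValueError(f"unknown event kinds: {sorted(bad_kinds)}")
    out = df.sort_values("sample", kind="stable").reset_index(drop=True)
    if fs is not None:
        resid = np.abs(out["sample"] - np.round(out["onset_s"] * fs))
        if np.any(resid > 1):
            raise ValueError("sample/onset inconsistency beyond one sample")
    return out
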