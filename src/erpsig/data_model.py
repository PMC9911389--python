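"""Core EEG data containers, event handling, epoch extraction and container I/O.

Conventions used throughout the package:

* sample indices are 0-based;
* epoch windows are half-open in samples: trial ``t`` of an epoch extraction
  covers samples ``onset + round(tmin*srate) .. onset + round(tmax*srate) - 1``;
* time 0 of an :class:`EpochSet` is the event sample;
* all voltages are in microvolts (µV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("erpsig")

__all__ = [
    "ContinuousRecording",
    "EventTable",
    "EpochSet",
    "extract_epochs",
    "read_container",
    "write_container",
    "read_events_tsv",
]


def _check_positions(positions: np.ndarray | None, n_channels: int) -> np.ndarray | None:
    if positions is None:
        return None
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (n_channels, 3):
        raise ValueError(
            f"channel_positions must be ({n_channels}, 3), got {positions.shape}"
        )
    norms = np.linalg.norm(positions, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("channel_positions must lie on the unit sphere (|x| == 1 within 1e-6)")
    return positions


@dataclass
class ContinuousRecording:
    """A continuous multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in µV.
    srate : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        One label per data row.
    channel_positions : ndarray, shape (n_channels, 3), optional
        Unit-sphere electrode coordinates (needed for spherical-spline
        interpolation).
    subject_id : str
    """

    data: np.ndarray
    srate: float
    channel_labels: Sequence[str]
    channel_positions: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one channel label required per data row")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or Inf")
        self.channel_positions = _check_positions(self.channel_positions, self.data.shape[0])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.srate

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            self.data.copy(),
            self.srate,
            list(self.channel_labels),
            None if self.channel_positions is None else self.channel_positions.copy(),
            self.subject_id,
        )


@dataclass
class EventTable:
    """Event markers: 0-based sample onsets plus a condition label per event."""

    onsets: np.ndarray
    labels: Sequence[str]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        self.labels = list(self.labels)
        if self.onsets.ndim != 1 or len(self.labels) != self.onsets.size:
            raise ValueError("onsets and labels must be aligned 1-D sequences")
        if self.onsets.size > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")
        if self.onsets.size and self.onsets[0] < 0:
            raise ValueError("event onsets must be non-negative")

    def __len__(self) -> int:
        return self.onsets.size

    def select(self, label: str) -> np.ndarray:
        """Onsets of all events carrying ``label``."""
        mask = np.array([lab == label for lab in self.labels], dtype=bool)
        return self.onsets[mask]


@dataclass
class EpochSet:
    """One subject x one condition block of trials (channels x time x trials)."""

    data: np.ndarray
    times: np.ndarray
    srate: float
    condition: str
    subject_id: str = ""
    channel_labels: Sequence[str] = field(default_factory=list)
    channel_positions: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (channels x timepoints x trials)")
        if self.times.size != self.data.shape[1]:
            raise ValueError("len(times) must equal the number of timepoints")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, 1.0 / self.srate, atol=1e-9):
                raise ValueError("times must be uniformly spaced at 1/srate")
        if self.data.shape[2] < 1:
            raise ValueError("at least one trial required")
        if not self.condition:
            raise ValueError("condition must be non-empty")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one channel label required per data row")
        self.channel_positions = _check_positions(self.channel_positions, self.data.shape[0])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(),
            self.times.copy(),
            self.srate,
            self.condition,
            self.subject_id,
            list(self.channel_labels),
            None if self.channel_positions is None else self.channel_positions.copy(),
            self.n_dropped,
        )

    def time_mask(self, start: float, end: float) -> np.ndarray:
        """Boolean mask over the time axis for the half-open window [start, end)."""
        return (self.times >= start - 1e-12) & (self.times < end - 1e-12)


def extract_epochs(
    rec: ContinuousRecording,
    events: EventTable,
    condition: str,
    tmin: float = -0.3,
    tmax: float = 0.7,
) -> EpochSet:
    """Cut fixed-length trials around every event labelled ``condition``.

    Trial ``t`` covers samples ``onset + round(tmin*srate)`` up to (excluding)
    ``onset + round(tmax*srate)``. Events whose window does not fit inside the
    recording are dropped and counted in :attr:`EpochSet.n_dropped`.
    """
    if tmin >= tmax:
        raise ValueError("invalid window: tmin must be < tmax")
    onsets = events.select(condition)
    if onsets.size == 0:
        raise ValueError(f"empty condition: no events labelled {condition!r}")

    off0 = int(round(tmin * rec.srate))
    off1 = int(round(tmax * rec.srate))
    n_per_trial = off1 - off0
    if n_per_trial < 1:
        raise ValueError("invalid window: empty after rounding to samples")

    starts = onsets + off0
    keep = (starts >= 0) & (starts + n_per_trial <= rec.n_samples)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "extract_epochs: dropped %d/%d %r events whose window exceeds recording bounds",
            n_dropped, onsets.size, condition,
        )
    starts = starts[keep]
    if starts.size == 0:
        raise ValueError(f"empty condition: no {condition!r} event window fits the recording")

    idx = starts[:, None] + np.arange(n_per_trial)[None, :]
    data = rec.data[:, idx].transpose(0, 2, 1)  # channels x time x trials
    times = (off0 + np.arange(n_per_trial)) / rec.srate
    return EpochSet(
        data=data,
        times=times,
        srate=rec.srate,
        condition=condition,
        subject_id=rec.subject_id,
        channel_labels=list(rec.channel_labels),
        channel_positions=None
        if rec.channel_positions is None
        else rec.channel_positions.copy(),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# container I/O (HDF5 with fixed dataset names)
# ---------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def _require(f: h5py.File, name: str):
    if name not in f:
        raise ValueError(f"missing field: {name.lstrip('/')}")
    return f[name]


def write_container(obj: ContinuousRecording | EpochSet, path) -> None:
    """Write a recording or epoch set to a single-file HDF5 container.

    Dataset names are fixed: ``/data``, ``/srate``, ``/labels``, ``/positions``
    (optional), ``/subject_id`` and, for epoch sets, ``/times`` and
    ``/condition``. The round trip is lossless and bit-exact for the arrays.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=obj.data)
        f.create_dataset("srate", data=float(obj.srate))
        f.create_dataset("labels", data=np.array(list(obj.channel_labels), dtype=_STR))
        f.create_dataset("subject_id", data=obj.subject_id, dtype=_STR)
        if obj.channel_positions is not None:
            f.create_dataset("positions", data=obj.channel_positions)
        if isinstance(obj, EpochSet):
            f.create_dataset("times", data=obj.times)
            f.create_dataset("condition", data=obj.condition, dtype=_STR)
            f.create_dataset("n_dropped", data=int(obj.n_dropped))


def read_container(path) -> ContinuousRecording | EpochSet:
    """Read a container written by :func:`write_container`.

    The object kind is inferred from the presence of ``/times``. A container
    lacking a required dataset raises ``ValueError('missing field: ...')``.
    """
    with h5py.File(path, "r") as f:
        data = np.asarray(_require(f, "data"))
        srate = float(np.asarray(_require(f, "srate")))
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in _require(f, "labels")[()]]
        positions = np.asarray(f["positions"]) if "positions" in f else None
        subject_id = f["subject_id"][()] if "subject_id" in f else ""
        if isinstance(subject_id, bytes):
            subject_id = subject_id.decode()
        if "times" in f:
            condition = _require(f, "condition")[()]
            if isinstance(condition, bytes):
                condition = condition.decode()
            n_dropped = int(np.asarray(f["n_dropped"])) if "n_dropped" in f else 0
            return EpochSet(
                data=data,
                times=np.asarray(f["times"]),
                srate=srate,
                condition=condition,
                subject_id=subject_id,
                channel_labels=labels,
                channel_positions=positions,
                n_dropped=n_dropped,
            )
        return ContinuousRecording(
            data=data,
            srate=srate,
            channel_labels=labels,
            channel_positions=positions,
            subject_id=subject_id,
        )


def read_events_tsv(path, srate: float) -> EventTable:
    """Read a BIDS-style ``*_events.tsv`` (columns ``onset`` seconds,
    ``trial_type``) and convert onsets to sample indices by
    ``round(onset * srate)``.
    """
    if srate is None or srate <= 0:
        raise ValueError("unknown srate: a positive sampling rate is required")
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return EventTable(np.empty(0, dtype=np.int64), [])
    if df.empty:
        return EventTable(np.empty(0, dtype=np.int64), [])
    for col in ("onset", "trial_type"):
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    onsets_s = df["onset"].to_numpy(dtype=float)
    if onsets_s.size > 1 and not np.all(np.diff(onsets_s) > 0):
        raise ValueError("event onsets must be strictly increasing")
    onsets = np.round(onsets_s * srate).astype(np.int64)
    return EventTable(onsets, [str(x) for x in df["trial_type"]])
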