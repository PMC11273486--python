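"""Reading, windowing and splitting of multichannel NIRS recordings.

A recording is a channels-by-time matrix of concentration changes (O2Hb/HHb
from two photodetector separations) sampled at 120 Hz. Recordings are cropped
into fixed-length windows (384 samples, ~3.2 s) which are the unit of input to
the classifiers, and datasets are split by *participant* so that no person
contributes windows to both the training and the test side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "CLASS_NAMES",
    "CLASS_IDS",
    "NIRSRecording",
    "WindowedSample",
    "DatasetSplit",
    "load_recording",
    "write_recording",
    "window_recording",
    "split_by_participant",
    "save_dataset",
    "load_dataset",
]

logger = logging.getLogger(__name__)

#: Canonical channel order: both photodetectors' oxy- and deoxyhemoglobin.
CHANNELS: tuple[str, ...] = ("PD1-O2Hb", "PD1-HHb", "PD2-O2Hb", "PD2-HHb")

#: Class order used in every report: normal, breath-hold, slow, rapid.
CLASS_NAMES: tuple[str, ...] = ("normal", "hold", "slow", "rapid")
CLASS_IDS: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}

DEFAULT_SAMPLING_RATE = 120.0
DEFAULT_WINDOW_LENGTH = 384
#: Dense-but-tractable window overlap; the source protocol does not pin a stride.
DEFAULT_STRIDE = 32


class FormatError(ValueError):
    """Raised when a tabular recording file does not match the expected layout."""


@dataclass
class NIRSRecording:
    """A continuous multichannel concentration-change series.

    Parameters
    ----------
    values
        Array of shape ``(n_channels, n_samples)`` with finite entries, in
        concentration-change units (ΔµM-like).
    channels
        Channel names, one per row of ``values``.
    sampling_rate
        Samples per second (Hz); metadata only, no resampling is performed.
    participant_id
        Opaque identifier used for participant-level splitting.
    task_label
        One of :data:`CLASS_NAMES`, or ``None`` for unlabelled data.
    """

    values: np.ndarray
    channels: Sequence[str] = CHANNELS
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    participant_id: str = ""
    task_label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a (channels, time) matrix")
        if self.values.shape[0] != len(self.channels):
            raise ValueError(
                f"got {self.values.shape[0]} rows for {len(self.channels)} channels"
            )
        if self.values.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("recording contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.task_label is not None and self.task_label not in CLASS_IDS:
            raise ValueError(f"unknown task label {self.task_label!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class WindowedSample:
    """A fixed-length labelled crop of a recording; the model's input unit."""

    data: np.ndarray  # (n_channels, window_length)
    label: int | None
    participant_id: str = ""
    start_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("window data must be a (channels, time) matrix")
        if self.label is not None and self.label not in range(len(CLASS_NAMES)):
            raise ValueError(f"label must be in 0..{len(CLASS_NAMES) - 1}")

    @property
    def origin(self) -> tuple[str, int]:
        return (self.participant_id, self.start_index)


@dataclass
class DatasetSplit:
    """Participant-disjoint train/test partition of windowed samples."""

    train: list[WindowedSample]
    test: list[WindowedSample]
    train_participants: set[str] = field(default_factory=set)
    test_participants: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.train_participants & self.test_participants
        if overlap:
            raise ValueError(f"participants in both train and test: {sorted(overlap)}")


def load_recording(
    path: str | Path,
    fmt: str | None = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    channels: Sequence[str] = CHANNELS,
    participant_id: str = "",
    task_label: str | None = None,
) -> NIRSRecording:
    """Read a recording from a headered CSV/TSV file, one row per sample tick.

    The file must contain one column per declared channel; a ``time`` column is
    permitted and ignored. ``fmt`` may be ``"csv"`` or ``"tsv"``; when omitted
    it is inferred from the suffix.
    """
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = {"csv": ",", "tsv": "\t"}.get(fmt)
    if sep is None:
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty") from exc
    missing = [c for c in channels if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing channel column(s) {missing}")
    if len(frame) == 0:
        raise FormatError(f"{path}: no data rows")
    values = frame.loc[:, list(channels)].to_numpy(dtype=float).T
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: non-finite cells in channel columns")
    return NIRSRecording(
        values=values,
        channels=tuple(channels),
        sampling_rate=sampling_rate,
        participant_id=participant_id,
        task_label=task_label,
    )


def write_recording(rec: NIRSRecording, path: str | Path, fmt: str | None = None,
                    include_time: bool = True) -> Path:
    """Write a recording as headered CSV/TSV (inverse of :func:`load_recording`)."""
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    frame = pd.DataFrame(rec.values.T, columns=list(rec.channels))
    if include_time:
        frame.insert(0, "time", np.arange(rec.n_samples) / rec.sampling_rate)
    # %.17g guarantees bit-exact float round trips through the text format
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


def window_recording(
    rec: NIRSRecording,
    length: int = DEFAULT_WINDOW_LENGTH,
    stride: int = DEFAULT_STRIDE,
) -> list[WindowedSample]:
    """Crop a recording into fixed-length windows at a regular stride.

    Window starts cover ``0 .. n_samples - length`` inclusive; any trailing
    remainder shorter than ``length`` is dropped. Each window inherits the
    recording's label and participant id. A recording shorter than ``length``
    yields an empty list (with a warning).
    """
    if length < 1:
        raise ValueError("window length must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = rec.n_samples
    if n < length:
        logger.warning(
            "recording of length %d shorter than window %d: no windows", n, length
        )
        return []
    label = None if rec.task_label is None else CLASS_IDS[rec.task_label]
    out = []
    for start in range(0, n - length + 1, stride):
        out.append(
            WindowedSample(
                data=rec.values[:, start : start + length].copy(),
                label=label,
                participant_id=rec.participant_id,
                start_index=start,
            )
        )
    return out


def split_by_participant(
    samples: Sequence[WindowedSample],
    test_fraction: float | None = None,
    test_participants: Iterable[str] | None = None,
    n_test: int | None = None,
    seed: int | None = None,
) -> DatasetSplit:
    """Partition windows into train/test by participant, never by window.

    Exactly one of ``test_fraction``, ``n_test`` or an explicit
    ``test_participants`` set selects the held-out participants; random
    selection is deterministic under ``seed``. The study design held out
    3 of 14 participants, i.e. ``n_test=3``.
    """
    ids = sorted({s.participant_id for s in samples})
    if len(ids) < 2:
        raise ValueError("cannot split: need at least 2 participants")
    if test_participants is not None:
        test_ids = set(test_participants)
        unknown = test_ids - set(ids)
        if unknown:
            raise ValueError(f"unknown test participants {sorted(unknown)}")
    else:
        if n_test is None:
            if test_fraction is None:
                raise ValueError(
                    "one of test_fraction, n_test or test_participants is required"
                )
            n_test = int(round(test_fraction * len(ids)))
        n_test = max(1, min(n_test, len(ids) - 1))
        rng = np.random.default_rng(seed)
        test_ids = set(rng.choice(ids, size=n_test, replace=False).tolist())
    train_ids = set(ids) - test_ids
    train = [s for s in samples if s.participant_id in train_ids]
    test = [s for s in samples if s.participant_id in test_ids]
    return DatasetSplit(
        train=train,
        test=test,
        train_participants=train_ids,
        test_participants=test_ids,
    )


def stack_windows(samples: Sequence[WindowedSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into ``(X, y)`` arrays of shape (N, C, L) and (N,)."""
    if not samples:
        raise ValueError("no samples to stack")
    X = np.stack([s.data for s in samples]).astype(np.float64)
    y = np.array([-1 if s.label is None else s.label for s in samples], dtype=int)
    return X, y


def save_dataset(split: DatasetSplit, path: str | Path) -> Path:
    """Cache a split in a single HDF5 file keyed by part (train/test)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        for part in ("train", "test"):
            samples = getattr(split, part)
            grp = f.create_group(part)
            if samples:
                X, y = stack_windows(samples)
                grp.create_dataset("data", data=X)
                grp.create_dataset("label", data=y)
                grp.create_dataset(
                    "participant",
                    data=np.array([s.participant_id for s in samples], dtype="S"),
                )
                grp.create_dataset(
                    "start", data=np.array([s.start_index for s in samples])
                )
    return path


def load_dataset(path: str | Path) -> DatasetSplit:
    """Inverse of :func:`save_dataset`."""
    import h5py

    parts: dict[str, list[WindowedSample]] = {}
    with h5py.File(path, "r") as f:
        for part in ("train", "test"):
            samples: list[WindowedSample] = []
            if part in f and "data" in f[part]:
                grp = f[part]
                X = grp["data"][()]
                y = grp["label"][()]
                pid = [p.decode() for p in grp["participant"][()]]
                start = grp["start"][()]
                for i in range(X.shape[0]):
                    samples.append(
                        WindowedSample(
                            data=X[i],
                            label=None if y[i] < 0 else int(y[i]),
                            participant_id=pid[i],
                            start_index=int(start[i]),
                        )
                    )
            parts[part] = samples
    return DatasetSplit(
        train=parts["train"],
        test=parts["test"],
        train_participants={s.participant_id for s in parts["train"]},
        test_participants={s.participant_id for s in parts["test"]},
    )
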