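"""Core data containers shared across the pipeline.

A :class:`Recording` is a continuous multichannel EEG segment with one class
label.  Segmentation turns recordings into a :class:`WindowedDataset` (stack
of fixed-length windows with binary labels), and feature extraction turns
that into a :class:`FeatureMatrix` whose columns are ``<Feature>_<Channel>``
attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The 19-electrode 10-20 montage used throughout (Cz and Pz are absent by
#: design: the source dataset has missing records for them).
MONTAGE_19: tuple[str, ...] = (
    "Fp2", "Fp1", "F8", "F4", "Fz", "F3", "F7", "A2", "T4", "C4",
    "C3", "T3", "A1", "T6", "P4", "P3", "T5", "O2", "O1",
)

INTERICTAL = "interictal"
ICTAL = "ictal"


class FormatError(ValueError):
    """Raised when an input file or array does not match the declared layout."""


@dataclass
class Recording:
    """A named-channel x sample matrix with a sampling rate and class label.

    Parameters
    ----------
    channel_names
        Ordered montage labels, one per row of ``data``.
    fs
        Sampling rate in Hz, strictly positive.
    data
        Real-valued array of shape ``(n_channels, n_samples)`` on the
        microvolt scale (or z-scored).
    label
        Class tag: ``"interictal"`` or an ictal subtype.
    source_id
        Free-text provenance (file name, generator config, ...).
    """

    channel_names: tuple[str, ...]
    fs: float
    data: np.ndarray
    label: str = INTERICTAL
    source_id: str = ""

    def __post_init__(self) -> None:
        self.channel_names = tuple(str(c) for c in self.channel_names)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise FormatError(f"data must be 2-D, got shape {self.data.shape}")
        if self.data.shape[0] != len(self.channel_names):
            raise FormatError(
                f"{self.data.shape[0]} rows but {len(self.channel_names)} "
                "channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            seen: set[str] = set()
            dups = [c for c in self.channel_names if c in seen or seen.add(c)]
            raise FormatError(f"duplicated channel names: {sorted(set(dups))}")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("non-finite values in signal data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs


@dataclass
class DatasetSplit:
    """Train/test lists of recordings, as delivered by the source dataset."""

    train: list[Recording] = field(default_factory=list)
    test: list[Recording] = field(default_factory=list)

    def labels(self) -> set[str]:
        return {r.label for r in self.train} | {r.label for r in self.test}


@dataclass
class WindowedDataset:
    """Fixed-length windows with binary labels.

    ``windows`` has shape ``(n_windows, n_channels, window_len)``; ``labels``
    is a vector of 0 (interictal) / 1 (ictal).
    """

    windows: np.ndarray
    labels: np.ndarray
    channel_names: tuple[str, ...]
    fs: float

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.channel_names = tuple(self.channel_names)
        if self.windows.ndim != 3:
            raise ValueError(f"windows must be 3-D, got {self.windows.shape}")
        if self.windows.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must equal number of windows")
        if self.windows.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if self.labels.size and not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0=interictal, 1=ictal)")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def window_len(self) -> int:
        return self.windows.shape[2]


def concat_windowed(parts: Iterable[WindowedDataset]) -> WindowedDataset:
    """Stack windowed datasets that share montage, fs and window length."""
    parts = list(parts)
    if not parts:
        raise ValueError("nothing to concatenate")
    ref = parts[0]
    for p in parts[1:]:
        if p.channel_names != ref.channel_names:
            raise ValueError("channel montages differ")
        if p.fs != ref.fs or p.window_len != ref.window_len:
            raise ValueError("sampling rate or window length differ")
    return WindowedDataset(
        windows=np.concatenate([p.windows for p in parts], axis=0),
        labels=np.concatenate([p.labels for p in parts]),
        channel_names=ref.channel_names,
        fs=ref.fs,
    )


@dataclass
class FeatureMatrix:
    """Windows x attributes table; columns are named ``<Feature>_<Channel>``."""

    attribute_names: tuple[str, ...]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.attribute_names = tuple(self.attribute_names)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.attribute_names):
            raise ValueError("column count does not match attribute_names")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must equal number of rows")
        if len(set(self.attribute_names)) != len(self.attribute_names):
            raise ValueError("attribute names must be unique")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def to_frame(self, with_label: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.attribute_names))
        if with_label:
            df["label"] = self.labels
        return df

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset in the requested order."""
        missing = [n for n in names if n not in self.attribute_names]
        if missing:
            raise KeyError(f"attributes not present: {missing}")
        idx = [self.attribute_names.index(n) for n in names]
        return FeatureMatrix(tuple(names), self.values[:, idx], self.labels)

    def dropna(self) -> tuple["FeatureMatrix", int]:
        """Drop rows with any undefined attribute; return (matrix, n_dropped)."""
        keep = np.all(np.isfinite(self.values), axis=1)
        dropped = int((~keep).sum())
        return (
            FeatureMatrix(self.attribute_names, self.values[keep], self.labels[keep]),
            dropped,
        )
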