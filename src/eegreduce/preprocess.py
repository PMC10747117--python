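"""Per-channel z-score normalisation, windowing and label binarisation.

Normalisation is applied per continuous recording (never pooled across the
train/test split, so no statistics leak between them), then the signal is cut
into non-overlapping fixed-length windows and ictal subtypes are merged into
a single positive class.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np

from .types import (
    ICTAL,
    INTERICTAL,
    DatasetSplit,
    Recording,
    WindowedDataset,
    concat_windowed,
)

log = logging.getLogger(__name__)


class ConstantChannelError(ValueError):
    """A channel has zero sample variance and cannot be z-scored."""


def zscore_channels(rec: Recording) -> Recording:
    """Z-score each channel of a recording independently.

    Uses the sample standard deviation (N-1 denominator).  Output channels
    have mean 0 and standard deviation 1.

    Raises
    ------
    ConstantChannelError
        Naming the offending channel(s) if any has zero variance.
    """
    mu = rec.data.mean(axis=1, keepdims=True)
    sd = rec.data.std(axis=1, ddof=1, keepdims=True)
    flat = np.where(sd[:, 0] == 0)[0]
    if flat.size:
        names = [rec.channel_names[i] for i in flat]
        raise ConstantChannelError(
            f"constant channel(s) cannot be z-scored: {names}"
        )
    return Recording(
        channel_names=rec.channel_names,
        fs=rec.fs,
        data=(rec.data - mu) / sd,
        label=rec.label,
        source_id=rec.source_id,
    )


def window_length(fs: float, window_seconds: float) -> int:
    """Samples per window; ``fs * window_seconds`` must be a positive integer."""
    n = fs * window_seconds
    if n <= 0 or abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"fs*window_seconds must be a positive integer, got {n}"
        )
    n = int(round(n))
    if n < 2:
        raise ValueError("windows must hold at least 2 samples")
    return n


def segment(rec: Recording, window_seconds: float = 1.0) -> WindowedDataset:
    """Cut a recording into non-overlapping windows of ``window_seconds``.

    The trailing remainder shorter than one window is discarded; the window
    count is exactly ``floor(n_samples / window_len)``.  Every window carries
    the recording's binarised label (interictal -> 0, anything else -> 1).
    """
    n = window_length(rec.fs, window_seconds)
    n_windows = rec.n_samples // n
    if n_windows == 0:
        log.warning(
            "recording %s (%d samples) shorter than one %d-sample window",
            rec.source_id, rec.n_samples, n,
        )
    discarded = rec.n_samples - n_windows * n
    if discarded:
        log.debug("%s: %d trailing samples discarded", rec.source_id, discarded)
    windows = (
        rec.data[:, : n_windows * n]
        .reshape(rec.n_channels, n_windows, n)
        .transpose(1, 0, 2)
    )
    label = 0 if rec.label == INTERICTAL else 1
    return WindowedDataset(
        windows=windows,
        labels=np.full(n_windows, label, dtype=np.int64),
        channel_names=rec.channel_names,
        fs=rec.fs,
    )


def binarize_labels(
    split: DatasetSplit,
    window_seconds: float = 1.0,
    *,
    label_map: Mapping[str, str] | None = None,
    zscore: bool = True,
    per_window: bool = False,
) -> tuple[WindowedDataset, WindowedDataset]:
    """Normalise, window and binarise a train/test split.

    Each recording is z-scored on its own (unless ``zscore=False``), windowed,
    and its label collapsed to 0 (interictal) / 1 (ictal subtype).  With
    ``per_window=True`` normalisation is instead applied inside each window
    (sensitivity-analysis variant).

    Raises
    ------
    KeyError
        If a recording carries a label outside the declared label set.
    """
    declared = set(label_map) if label_map is not None else None
    out = []
    for name, recs in (("train", split.train), ("test", split.test)):
        if not recs:
            raise ValueError(f"{name} split is empty")
        parts = []
        for rec in recs:
            tag = rec.label
            if label_map is not None:
                if tag not in label_map:
                    raise KeyError(f"unknown label tag {tag!r} in {name} split")
                tag = label_map[tag]
                if tag not in (INTERICTAL, ICTAL):
                    raise KeyError(f"label_map must target interictal/ictal, got {tag!r}")
                rec = Recording(rec.channel_names, rec.fs, rec.data, tag, rec.source_id)
            if zscore and not per_window:
                rec = zscore_channels(rec)
            ws = segment(rec, window_seconds)
            if per_window and zscore:
                mu = ws.windows.mean(axis=2, keepdims=True)
                sd = ws.windows.std(axis=2, ddof=1, keepdims=True)
                if np.any(sd == 0):
                    raise ConstantChannelError("constant window under per-window scaling")
                ws = WindowedDataset(
                    (ws.windows - mu) / sd, ws.labels, ws.channel_names, ws.fs
                )
            parts.append(ws)
        merged = concat_windowed(parts)
        counts = np.bincount(merged.labels, minlength=2)
        log.info(
            "%s split: %d windows (%d interictal, %d ictal)",
            name, merged.n_windows, counts[0], counts[1],
        )
        out.append(merged)
    return out[0], out[1]


def expected_window_count(n_samples: int, fs: float, window_seconds: float = 1.0) -> int:
    """Window accounting helper: ``floor(n_samples / (fs*window_seconds))``."""
    return math.floor(n_samples / window_length(fs, window_seconds))
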