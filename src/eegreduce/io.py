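"""Readers and writers: MAT-file dataset layout, delimited signals, tables.

The MAT layout mirrors the public epileptic-EEG release this pipeline was
designed around: MATLAB Level-5 files holding pre-split train/test arrays of
19-channel scalp EEG sampled at 500 Hz, one array per class segment.  Array
names are discovered with a configurable regular expression because the
release does not document them; the default pattern accepts names such as
``train_interictal_01`` or ``test_complex_partial``.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io as sio

from .types import (
    ICTAL,
    INTERICTAL,
    MONTAGE_19,
    DatasetSplit,
    FormatError,
    FeatureMatrix,
    Recording,
)

log = logging.getLogger(__name__)

#: Default mapping of stored class tags onto the binary label set.  Ictal
#: subtypes (complex partial, electrographic, video-detected) all collapse
#: onto "ictal".
DEFAULT_LABEL_MAP: dict[str, str] = {
    "interictal": INTERICTAL,
    "complex_partial": ICTAL,
    "electrographic": ICTAL,
    "video_detected": ICTAL,
    "ictal": ICTAL,
}

#: Named groups ``split`` and ``label`` locate each array in the MAT files.
DEFAULT_VAR_PATTERN = r"^(?P<split>train|test)_(?P<label>[A-Za-z_]+?)(?:_\d+)?$"


def _validate_montage(names: Sequence[str], expected: Sequence[str]) -> None:
    names, expected = list(names), list(expected)
    if names == expected:
        return
    missing = [c for c in expected if c not in names]
    extra = [c for c in names if c not in expected]
    if missing or extra:
        raise FormatError(
            f"channel mismatch: missing {missing or 'none'}, "
            f"unexpected {extra or 'none'}"
        )
    raise FormatError("channel order does not match the declared montage")


def load_ubmc_dataset(
    path: str | Path,
    label_map: Mapping[str, str] | None = None,
    *,
    channel_names: Sequence[str] = MONTAGE_19,
    fs: float = 500.0,
    var_pattern: str = DEFAULT_VAR_PATTERN,
    transpose: bool = False,
) -> DatasetSplit:
    """Read a directory (or single file) of MAT-files into a train/test split.

    Each matching array must be a numeric ``channels x samples`` matrix
    (``samples x channels`` with ``transpose=True``) over the full declared
    montage.  Stored class tags are mapped through ``label_map``; unknown
    tags raise.

    Raises
    ------
    FormatError
        Missing files, undiscovered arrays, wrong channel count or
        non-numeric payloads.
    """
    label_map = dict(DEFAULT_LABEL_MAP if label_map is None else label_map)
    p = Path(path)
    files = sorted(p.glob("*.mat")) if p.is_dir() else [p]
    files = [f for f in files if f.exists()]
    if not files:
        raise FormatError(f"no dataset files found under {path}")

    pattern = re.compile(var_pattern)
    split = DatasetSplit()
    n_found = 0
    for f in files:
        try:
            payload = sio.loadmat(f)
        except Exception as exc:  # corrupt / non-MAT content
            raise FormatError(f"{f}: not a readable MAT-file ({exc})") from exc
        for name, arr in payload.items():
            m = pattern.match(name)
            if m is None:
                continue
            n_found += 1
            arr = np.asarray(arr)
            if not np.issubdtype(arr.dtype, np.number):
                raise FormatError(f"{f}:{name}: non-numeric payload")
            arr = arr.astype(np.float64)
            if transpose:
                arr = arr.T
            if arr.ndim != 2 or arr.shape[0] != len(channel_names):
                raise FormatError(
                    f"{f}:{name}: expected {len(channel_names)} channel rows, "
                    f"got shape {arr.shape}"
                )
            tag = m.group("label").lower()
            if tag not in label_map:
                raise FormatError(
                    f"{f}:{name}: unknown class tag {tag!r} "
                    f"(declared: {sorted(label_map)})"
                )
            rec = Recording(
                channel_names=tuple(channel_names),
                fs=fs,
                data=arr,
                label=tag,
                source_id=f"{f.name}:{name}",
            )
            (split.train if m.group("split") == "train" else split.test).append(rec)
    if n_found == 0:
        raise FormatError(
            f"no arrays matching pattern {var_pattern!r} in {len(files)} file(s)"
        )
    log.info(
        "loaded %d train / %d test recordings from %s",
        len(split.train), len(split.test), path,
    )
    return split


def save_ubmc_dataset(split: DatasetSplit, path: str | Path) -> Path:
    """Write a split back into the MAT layout (one file, one array per segment).

    Inverse of :func:`load_ubmc_dataset` under the default name pattern; used
    to materialise synthetic fixtures in the on-disk format the loader expects.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload: dict[str, np.ndarray] = {}
    for split_name, recs in (("train", split.train), ("test", split.test)):
        for i, rec in enumerate(recs):
            payload[f"{split_name}_{rec.label}_{i:02d}"] = rec.data
    sio.savemat(path, payload)
    return path


def load_delimited(
    path: str | Path,
    fs: float,
    channel_names: Sequence[str] | None = None,
    *,
    label: str = INTERICTAL,
    channels_as: str = "columns",
) -> Recording:
    """Read a delimited text signal file into a :class:`Recording`.

    With ``channels_as="columns"`` (default) the file has a header row of
    channel names and one sample per row; ``channels_as="rows"`` reads a
    headerless channels x samples matrix and requires ``channel_names``.
    """
    path = Path(path)
    if channels_as == "columns":
        df = _read_csv(path)
        names = tuple(df.columns) if channel_names is None else tuple(channel_names)
        if channel_names is not None:
            _validate_montage(df.columns, channel_names)
        values = df.to_numpy().T
    elif channels_as == "rows":
        if channel_names is None:
            raise ValueError("channel_names required when channels_as='rows'")
        df = _read_csv(path, header=None)
        names = tuple(channel_names)
        values = df.to_numpy()
    else:
        raise ValueError(f"channels_as must be 'columns' or 'rows', got {channels_as!r}")
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise FormatError(f"{path}: non-numeric cells in columns {list(bad)}")
    try:
        return Recording(names, fs, values, label=label, source_id=str(path))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _read_csv(path: Path, **kw) -> pd.DataFrame:
    """CSV read with exact float round-tripping and format errors wrapped."""
    try:
        return pd.read_csv(path, float_precision="round_trip", **kw)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def save_delimited(rec: Recording, path: str | Path, *, float_format: str = "%.10g") -> Path:
    """Write a recording as CSV with a header row of channel names."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rec.data.T, columns=list(rec.channel_names)).to_csv(
        path, index=False, float_format=float_format
    )
    return path


def write_table(
    rows: FeatureMatrix | pd.DataFrame | Mapping | Sequence[Mapping],
    path: str | Path,
    format: str | None = None,
) -> Path:
    """Persist a feature matrix, data frame or report as CSV or JSON.

    Column order is preserved.  ``format`` defaults to the path suffix.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"csv", "json"}:
        raise ValueError(f"unsupported table format {fmt!r}")

    if isinstance(rows, FeatureMatrix):
        df = rows.to_frame(with_label=True)
    elif isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = None

    if fmt == "json":
        if df is not None:
            payload = df.to_dict(orient="list")
        else:
            payload = rows
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_jsonable)
    else:
        if df is None:
            df = pd.DataFrame(rows)
        df.to_csv(path, index=False)
    return path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def read_feature_table(path: str | Path) -> FeatureMatrix:
    """Read back a feature matrix written by :func:`write_table` (CSV)."""
    df = _read_csv(Path(path))
    if "label" not in df.columns:
        raise FormatError(f"{path}: feature table lacks a 'label' column")
    labels = df.pop("label").to_numpy()
    return FeatureMatrix(tuple(df.columns), df.to_numpy(), labels)
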