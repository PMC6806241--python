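"""CSV readers/writers for recordings, feature tables and confusion
matrices.

All on-disk formats are plain comma-delimited text with a header row and
'.' decimals; floats are written with 17 significant digits so write→read
round trips are lossless.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd

from .evaluate import ConfusionMatrix
from .features import FeatureTable
from .synthetic import RECORDING_COLUMNS, LabeledRecording

__all__ = [
    "SchemaError",
    "read_recording",
    "write_recording",
    "read_features",
    "write_features",
    "read_matrix",
    "write_matrix",
    "recording_filename",
]

FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """A file does not match the expected column schema."""


def recording_filename(subject: int, location: str) -> str:
    return f"S{int(subject):02d}_{location}.csv"


_FNAME_RE = re.compile(r"S(?P<subject>\d+)_(?P<location>[A-Z]+)\.csv$")


def write_recording(rec: LabeledRecording, path: str | Path) -> Path:
    """Write one recording; returns the written path.

    If ``path`` is a directory, the canonical ``S<subject>_<location>.csv``
    name is used inside it.
    """
    path = Path(path)
    if path.is_dir():
        path = path / recording_filename(rec.subject, rec.location)
    rec.data[RECORDING_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def read_recording(
    path: str | Path,
    subject: int | None = None,
    location: str | None = None,
    sample_rate: float = 50.0,
) -> LabeledRecording:
    """Read a recording CSV; subject/location default to the filename's
    ``S<subject>_<location>.csv`` pattern."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    m = _FNAME_RE.search(path.name)
    if subject is None:
        subject = int(m.group("subject")) if m else 0
    if location is None:
        location = m.group("location") if m else "LB"
    df = _read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column {missing[0]!r}")
    df["marker"] = df["marker"].astype(bool)
    return LabeledRecording(subject, location, df[RECORDING_COLUMNS], sample_rate)


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as err:
        m = re.search(r"line (\d+)", str(err))
        row = f" at row {m.group(1)}" if m else ""
        raise SchemaError(f"{path.name}: malformed row{row}: {err}") from err


def write_features(table: FeatureTable, path: str | Path) -> Path:
    """Write a feature table plus a ``<stem>.meta.json`` sidecar with the
    feature-set tag."""
    path = Path(path)
    table.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps({"tag": table.tag, "columns": table.columns}))
    return path


def read_features(path: str | Path) -> FeatureTable:
    path = Path(path)
    df = _read_csv(path)
    for col in ("label", "subject"):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing column {col!r}")
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        tag, columns = meta["tag"], meta["columns"]
    else:
        columns = [c for c in df.columns if c not in ("label", "subject")]
        tag = "raw6" if len(columns) == 6 else "unknown"
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column {missing[0]!r}")
    return FeatureTable(
        df[columns].to_numpy(float),
        list(columns),
        df["label"].to_numpy(),
        df["subject"].to_numpy(),
        tag,
    )


def write_matrix(cm: ConfusionMatrix, path: str | Path) -> Path:
    path = Path(path)
    cm.to_frame().to_csv(path)
    return path


def read_matrix(path: str | Path) -> ConfusionMatrix:
    path = Path(path)
    df = _read_csv(path).set_index("predicted")
    return ConfusionMatrix(df.to_numpy(dtype=int), list(df.columns))
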