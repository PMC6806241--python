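"""Per-sample feature tables for the raw-data and attitude-based recognition
paths.

Classification here is strictly per 50 Hz tick: no windowing, no scaling,
no filtering.  Raw feature sets feed sensor axes directly to the
classifier; attitude feature sets replace them with the estimated
orientation (Euler angles or quaternion components), which is lower
dimensional and carries the posture information explicitly.

Feature sets (``tag``):

========  ====================================================  ==========
tag       columns                                               dimension
========  ====================================================  ==========
acc3      acc_x, acc_y, acc_z                                   3
raw6      acc3 + gyr_x, gyr_y, gyr_z                            6
norm      ‖acc‖, ‖gyr‖                                          2
euler3    roll, pitch, yaw (rad)                                3
quat4     qw, qx, qy, qz                                        4
========  ====================================================  ==========
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FEATURE_TAGS = ("acc3", "raw6", "norm", "euler3", "quat4")

_TAG_COLUMNS = {
    "acc3": ["acc_x", "acc_y", "acc_z"],
    "raw6": ["acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"],
    "norm": ["acc_norm", "gyr_norm"],
    "euler3": ["roll", "pitch", "yaw"],
    "quat4": ["qw", "qx", "qy", "qz"],
}

#: tags that require an attitude stream
ATTITUDE_TAGS = ("euler3", "quat4")


@dataclass
class FeatureTable:
    """Feature matrix with aligned labels and subject ids."""

    X: np.ndarray
    columns: list[str]
    labels: np.ndarray
    subjects: np.ndarray
    tag: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        if not (len(self.X) == len(self.labels) == len(self.subjects)):
            raise ValueError("feature matrix, labels and subject ids must align")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column names must match matrix width")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df["label"] = self.labels
        df["subject"] = self.subjects
        return df

    @classmethod
    def concat(cls, tables: list["FeatureTable"]) -> "FeatureTable":
        tags = {t.tag for t in tables}
        if len(tags) != 1:
            raise ValueError("cannot concatenate tables with different tags")
        return cls(
            np.vstack([t.X for t in tables]),
            tables[0].columns,
            np.concatenate([t.labels for t in tables]),
            np.concatenate([t.subjects for t in tables]),
            tables[0].tag,
        )


def extract_features(rec, attitude: np.ndarray | None = None, tag: str = "raw6") -> FeatureTable:
    """Build the per-sample feature table for one recording.

    Parameters
    ----------
    rec : LabeledRecording
    attitude : ndarray (N, 4), optional
        Estimated quaternion stream, one row per sample; required for the
        ``euler3`` and ``quat4`` tags.
    tag : str
        Feature-set identifier, one of :data:`FEATURE_TAGS`.
    """
    if tag not in _TAG_COLUMNS:
        raise ValueError(f"unknown feature tag {tag!r}; expected one of {FEATURE_TAGS}")
    df = rec.data
    labels = df["label"].to_numpy()
    subjects = np.full(len(df), rec.subject)
    if tag in ("acc3", "raw6"):
        X = df[_TAG_COLUMNS[tag]].to_numpy()
    elif tag == "norm":
        acc = df[["acc_x", "acc_y", "acc_z"]].to_numpy()
        gyr = df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy()
        X = np.column_stack(
            [np.linalg.norm(acc, axis=1), np.linalg.norm(gyr, axis=1)]
        )
    else:
        if attitude is None:
            raise ValueError(f"feature tag {tag!r} requires an attitude stream")
        attitude = np.asarray(attitude, dtype=float)
        if len(attitude) != len(df):
            raise ValueError("attitude stream must align with the recording")
        if tag == "quat4":
            X = attitude.copy()
        else:
            from .quaternion import quat_normalize, quat_to_euler

            X = quat_to_euler(quat_normalize(attitude))
    return FeatureTable(X, list(_TAG_COLUMNS[tag]), labels, subjects, tag)
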