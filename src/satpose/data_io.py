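"""Reading and writing labels, predictions, frames and sequence manifests.

Label/prediction CSV schema: one header row with ``frame_index`` followed by
26 coordinate columns ``<feature>_x, <feature>_y`` in canonical landmark
order, plus an optional trailing ``source`` column.  Comma-separated, UTF-8,
'.' decimal.  Sparse manual annotations (every 4th frame in the study design)
are expanded to dense per-frame labels by linear interpolation.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .landmarks import (
    POINT_FEATURES,
    AnnotationTable,
    FrameSequence,
    KeypointSet,
)

__all__ = [
    "LabelFormatError",
    "coordinate_columns",
    "read_labels",
    "write_labels",
    "densify_labels",
    "write_predictions",
    "read_frame",
    "write_frame",
    "read_manifest",
    "write_manifest",
]


class LabelFormatError(ValueError):
    """Raised when a label CSV violates the schema."""


def coordinate_columns() -> list:
    """The 26 coordinate column names in canonical order."""
    cols = []
    for f in POINT_FEATURES:
        cols.append(f"{f.value}_x")
        cols.append(f"{f.value}_y")
    return cols


def read_labels(path) -> AnnotationTable:
    """Read a label CSV into an :class:`AnnotationTable`.

    Rows missing any coordinate cell are rejected; a malformed header raises
    :class:`LabelFormatError` naming the offending column; a non-monotone
    ``frame_index`` raises ``ValueError``.  Rows lacking a ``source`` column
    are treated as manual annotations.
    """
    df = pd.read_csv(path)
    required = ["frame_index"] + coordinate_columns()
    for col in required:
        if col not in df.columns:
            raise LabelFormatError(f"label CSV {path} is missing column {col!r}")
    if df[required].isna().any().any():
        bad = int(df.index[df[required].isna().any(axis=1)][0])
        raise LabelFormatError(f"label CSV {path} has missing cells in row {bad}")
    frames = df["frame_index"].to_numpy()
    if np.any(np.diff(frames) <= 0):
        raise ValueError(f"frame_index in {path} must be strictly increasing")
    has_source = "source" in df.columns
    coords = df[coordinate_columns()].to_numpy(dtype=float)
    rows = {}
    for k, fi in enumerate(frames):
        src = str(df["source"].iloc[k]) if has_source else "manual"
        rows[int(fi)] = KeypointSet(
            coords[k].reshape(-1, 2), frame_index=int(fi), source=src
        )
    return AnnotationTable(rows=rows)


def _table_to_frame(table: AnnotationTable) -> pd.DataFrame:
    idx = table.frame_indices()
    data = {"frame_index": idx}
    arr = np.stack([table[i].coords.reshape(-1) for i in idx])
    for j, col in enumerate(coordinate_columns()):
        data[col] = arr[:, j]
    data["source"] = [table[i].source for i in idx]
    return pd.DataFrame(data)


def write_labels(table: AnnotationTable, path) -> None:
    """Write an :class:`AnnotationTable` to CSV (schema of :func:`read_labels`)."""
    _table_to_frame(table).to_csv(path, index=False, float_format="%.6f")


def densify_labels(table: AnnotationTable) -> AnnotationTable:
    """Expand sparse manual annotations to one label per frame.

    Each unannotated frame between the first and last manual row receives a
    per-coordinate linear interpolation between its two bracketing manual
    rows (``source="interpolated"``); manual rows pass through unchanged.
    """
    manual = table.manual_indices()
    if len(manual) < 2:
        raise ValueError("densify_labels needs at least 2 manual rows")
    xs = np.array(manual, dtype=float)
    ys = np.stack([table[i].coords.reshape(-1) for i in manual])  # (M, 26)
    rows = {}
    for fi in range(manual[0], manual[-1] + 1):
        if fi in table.rows and table[fi].source == "manual":
            rows[fi] = table[fi]
        else:
            vec = np.array(
                [np.interp(fi, xs, ys[:, j]) for j in range(ys.shape[1])]
            )
            rows[fi] = KeypointSet(
                vec.reshape(-1, 2), frame_index=fi, source="interpolated"
            )
    return AnnotationTable(rows=rows, annotation_stride=table.annotation_stride)


def write_predictions(seq: FrameSequence, preds: list, path) -> None:
    """Write per-frame network predictions as a label-schema CSV.

    Requires exactly one :class:`KeypointSet` per frame of ``seq``; the
    ``source`` column is forced to ``"predicted"``.
    """
    if len(preds) != len(seq):
        raise ValueError(
            f"got {len(preds)} predictions for {len(seq)} frames"
        )
    rows = {}
    for i, kp in enumerate(preds):
        rows[i] = KeypointSet(kp.coords, frame_index=i, source="predicted")
    write_labels(AnnotationTable(rows=rows), path)


# -- frames ------------------------------------------------------------------

def read_frame(path) -> np.ndarray:
    """Load one RGB frame as a float32 array (H, W, 3) in [0, 255]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float32)


def write_frame(image: np.ndarray, path) -> None:
    arr = np.clip(np.asarray(image), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


# -- sequence manifests ------------------------------------------------------

def write_manifest(seq: FrameSequence, path) -> None:
    doc = {
        "frame_paths": [str(p) for p in seq.frame_paths],
        "fps": float(seq.fps),
        "roi": list(seq.roi) if seq.roi is not None else None,
        "subject_id": seq.subject_id,
        "session_id": seq.session_id,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_manifest(path) -> FrameSequence:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    root = Path(path).parent
    paths = [
        p if os.path.isabs(p) else str(root / p) for p in doc["frame_paths"]
    ]
    roi = tuple(doc["roi"]) if doc.get("roi") else None
    return FrameSequence(
        frame_paths=paths,
        fps=doc.get("fps", 25.0),
        roi=roi,
        subject_id=doc.get("subject_id", ""),
        session_id=doc.get("session_id", ""),
    )
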