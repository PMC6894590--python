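"""Segment angles from landmarks, and pixel/angle error scoring.

Ten body segments are each defined by a (proximal, distal) landmark pair;
the segment angle is the orientation of the distal->proximal vector measured
from the upward vertical in y-down image coordinates:

    angle = atan2(dx, -dy) in degrees,  d = proximal - distal

so 0 deg means the proximal point sits vertically above the distal one, and
positive angles lean toward image-right.  Clinical classifications depend
only on angle *differences*, which this convention leaves invariant.
Differences between angles are always taken circularly (wrapped to
(-180, 180]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import POINT_FEATURES, KeypointSet, PointFeatureName

__all__ = [
    "SEGMENTS",
    "SEGMENT_NAMES",
    "HEAD_TRUNK_SEGMENTS",
    "SegmentAngleFrame",
    "compute_angles",
    "angles_to_frame",
    "circular_difference",
    "angle_error",
    "pixel_error",
]

P = PointFeatureName

#: segment name -> (proximal landmark, distal landmark)
SEGMENTS: dict = {
    "head": (P.TEMPORAL_FOSSA, P.EAR_TRAGUS),
    "neck": (P.EAR_TRAGUS, P.C7),
    "UT": (P.C7, P.T3),
    "MT": (P.T3, P.T7),
    "LT": (P.T7, P.T11),
    "UL": (P.T11, P.L3),
    "LL": (P.L3, P.S1),
    "pelvis": (P.ASIS, P.GREATER_TROCHANTER),
    "upper_arm": (P.SHOULDER, P.ELBOW),
    "forearm": (P.ELBOW, P.WRIST),
}

SEGMENT_NAMES: tuple = tuple(SEGMENTS)

#: the eight segments entering the alignment classification (no arm)
HEAD_TRUNK_SEGMENTS: tuple = ("head", "neck", "UT", "MT", "LT", "UL", "LL", "pelvis")

#: groupings used when summarizing angle error
SEGMENT_GROUPS: dict = {
    "arm": ("upper_arm", "forearm"),
    "trunk": ("UT", "MT", "LT", "UL", "LL"),
    "reference": ("head", "neck", "UT", "MT", "LT", "UL", "LL"),
    "all": SEGMENT_NAMES,
}


@dataclass
class SegmentAngleFrame:
    """The 10 segment angles (degrees from vertical) of one frame."""

    angles: dict
    frame_index: int = 0
    source: str = "manual"

    def __post_init__(self) -> None:
        missing = set(SEGMENT_NAMES) - set(self.angles)
        if missing:
            raise ValueError(f"missing segment angles: {sorted(missing)}")

    def __getitem__(self, name: str) -> float:
        return self.angles[name]

    def as_vector(self) -> np.ndarray:
        return np.array([self.angles[s] for s in SEGMENT_NAMES])


def segment_angle(proximal: np.ndarray, distal: np.ndarray) -> float:
    d = np.asarray(proximal, float) - np.asarray(distal, float)
    if np.hypot(d[0], d[1]) == 0:
        raise ValueError("coincident endpoints")
    return float(np.degrees(np.arctan2(d[0], -d[1])))


def compute_angles(kp: KeypointSet) -> SegmentAngleFrame:
    """All 10 segment angles of one frame (degrees in (-180, 180])."""
    angles = {}
    for name, (prox, dist) in SEGMENTS.items():
        try:
            angles[name] = segment_angle(kp[prox], kp[dist])
        except ValueError:
            raise ValueError(
                f"segment {name!r} has coincident endpoints "
                f"({prox.value}, {dist.value}) in frame {kp.frame_index}"
            )
    return SegmentAngleFrame(angles, frame_index=kp.frame_index, source=kp.source)


def angles_to_frame(stream) -> np.ndarray:
    """Stack a SegmentAngleFrame stream into an (n_frames, 10) array."""
    return np.stack([f.as_vector() for f in stream])


def circular_difference(a, b):
    """Signed angular difference a - b wrapped into (-180, 180] degrees."""
    d = np.mod(np.asarray(a, float) - np.asarray(b, float) + 180.0, 360.0) - 180.0
    return np.where(d == -180.0, 180.0, d) if np.ndim(d) else (
        180.0 if d == -180.0 else float(d)
    )


def angle_error(pred, ref) -> "pd.DataFrame":
    """Per-segment MAE +/- SD of the circular angle difference, in degrees.

    ``pred`` and ``ref`` are equal-length SegmentAngleFrame streams.  Beside
    the 10 individual segments, the combined groups are reported: arm
    (upper arm + forearm), trunk (UT..LL), reference (head + neck + trunk)
    and all segments; group statistics pool the per-frame absolute errors of
    their member segments.
    """
    import pandas as pd

    pa = angles_to_frame(pred)
    ra = angles_to_frame(ref)
    if pa.shape[0] == 0:
        raise ValueError("empty angle stream")
    if pa.shape != ra.shape:
        raise ValueError("pred and ref must have equal frame counts")
    abserr = np.abs(circular_difference(pa, ra))  # (n, 10)
    rows = []
    for j, name in enumerate(SEGMENT_NAMES):
        rows.append((name, abserr[:, j].mean(), abserr[:, j].std()))
    for gname, members in SEGMENT_GROUPS.items():
        cols = [SEGMENT_NAMES.index(m) for m in members]
        pooled = abserr[:, cols].reshape(-1)
        rows.append((gname, pooled.mean(), pooled.std()))
    return pd.DataFrame(rows, columns=["segment", "mae_deg", "sd_deg"])


def pixel_error(pred, ref) -> "pd.DataFrame":
    """Per-landmark and overall localization error statistics.

    ``pred`` and ``ref`` are equal-length KeypointSet streams in a common
    pixel space (conventionally the network's input resolution).  Reports the
    Euclidean point distance (mean +/- SD) and, as a secondary column, the
    mean per-coordinate absolute difference.
    """
    import pandas as pd

    pa = np.stack([k.coords for k in pred])  # (n, 13, 2)
    ra = np.stack([k.coords for k in ref])
    if pa.shape != ra.shape:
        raise ValueError("pred and ref must have equal frame counts")
    diff = pa - ra
    dist = np.hypot(diff[..., 0], diff[..., 1])  # (n, 13)
    absco = np.abs(diff).mean(axis=-1)  # mean of |dx|, |dy|
    rows = []
    for j, f in enumerate(POINT_FEATURES):
        rows.append((f.value, dist[:, j].mean(), dist[:, j].std(), absco[:, j].mean()))
    rows.append(("overall", dist.mean(), dist.std(), absco.mean()))
    return pd.DataFrame(
        rows, columns=["feature", "mean_px", "sd_px", "mean_abs_coord_px"]
    )
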