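"""Anatomical point-features and per-frame containers.

The sagittal-view posture model tracks 13 anatomical landmarks: two on the
head (temporal fossa, ear tragus), six along the spine (C7, T3, T7, T11, L3,
S1), two on the pelvis (ASIS, greater trochanter) and three on the right arm
(shoulder, elbow, wrist).  Their fixed ordering defines the 26-unit network
output layout: for each point in order, x precedes y.

Coordinate convention (used by every module): 0-based pixel coordinates with
the origin at the top-left pixel center, x increasing rightward and y
increasing downward.  Coordinates are floats and may lie outside the image —
annotators legitimately infer occluded landmarks past the frame border.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PointFeatureName",
    "POINT_FEATURES",
    "KeypointSet",
    "FrameSequence",
    "AnnotationTable",
]


class PointFeatureName(str, enum.Enum):
    """The 13 tracked landmarks, in canonical output order."""

    TEMPORAL_FOSSA = "temporal_fossa"
    EAR_TRAGUS = "ear_tragus"
    C7 = "C7"
    T3 = "T3"
    T7 = "T7"
    T11 = "T11"
    L3 = "L3"
    S1 = "S1"
    ASIS = "ASIS"
    GREATER_TROCHANTER = "greater_trochanter"
    SHOULDER = "shoulder"
    ELBOW = "elbow"
    WRIST = "wrist"


#: Canonical landmark order; index i occupies output units (2i, 2i+1) = (x, y).
POINT_FEATURES: tuple[PointFeatureName, ...] = tuple(PointFeatureName)

N_POINTS = len(POINT_FEATURES)
N_OUTPUTS = 2 * N_POINTS  # 26


@dataclass
class KeypointSet:
    """All 13 landmark coordinates for one frame.

    Parameters
    ----------
    coords
        Array of shape (13, 2) in canonical order, columns (x, y), pixels.
    frame_index
        Index of the frame within its sequence.
    source
        Provenance: ``"manual"``, ``"interpolated"`` or ``"predicted"``.
    """

    coords: np.ndarray
    frame_index: int = 0
    source: str = "manual"

    VALID_SOURCES = ("manual", "interpolated", "predicted")

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_POINTS, 2):
            raise ValueError(
                f"coords must have shape ({N_POINTS}, 2), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("all 13 landmark coordinates must be finite")
        if self.source not in self.VALID_SOURCES:
            raise ValueError(f"source must be one of {self.VALID_SOURCES}")

    def __getitem__(self, name: PointFeatureName | str) -> np.ndarray:
        name = PointFeatureName(name)
        return self.coords[POINT_FEATURES.index(name)]

    def as_vector(self) -> np.ndarray:
        """Flatten to the 26-unit layout (x before y per point)."""
        return self.coords.reshape(-1).copy()

    @classmethod
    def from_vector(
        cls, vec: np.ndarray, frame_index: int = 0, source: str = "predicted"
    ) -> "KeypointSet":
        vec = np.asarray(vec, dtype=float).reshape(N_POINTS, 2)
        return cls(vec, frame_index=frame_index, source=source)

    def translated(self, dx: float, dy: float) -> "KeypointSet":
        return KeypointSet(
            self.coords + np.array([dx, dy]),
            frame_index=self.frame_index,
            source=self.source,
        )


@dataclass
class FrameSequence:
    """Ordered RGB frames of one video plus acquisition metadata.

    ``roi`` is ``(x0, y0, width, height)`` in original-image pixels; the crop
    is static over the whole sequence, mirroring a fixed tripod camera.
    """

    frame_paths: list
    fps: float = 25.0
    roi: tuple | None = None
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        if len(self.frame_paths) < 1:
            raise ValueError("a FrameSequence needs at least one frame")
        if self.roi is not None:
            x0, y0, w, h = self.roi
            if w <= 0 or h <= 0:
                raise ValueError("roi width and height must be positive")

    def __len__(self) -> int:
        return len(self.frame_paths)


@dataclass
class AnnotationTable:
    """Per-frame keypoint labels, sparse (manual) or dense (after interpolation).

    Manual annotation marks every ``annotation_stride``-th frame (4 in
    practice); `satpose.data_io.densify_labels` fills the gaps linearly.
    """

    rows: dict = field(default_factory=dict)  # frame_index -> KeypointSet
    annotation_stride: int = 4

    def frame_indices(self) -> list:
        return sorted(self.rows)

    def manual_indices(self) -> list:
        return sorted(i for i, kp in self.rows.items() if kp.source == "manual")

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, frame_index: int) -> KeypointSet:
        return self.rows[frame_index]

    def stride_consistent(self) -> bool:
        """True when manual rows sit at stride multiples (a final off-stride
        frame, annotated to close the sequence, is tolerated)."""
        idx = self.manual_indices()
        if not idx:
            return True
        first = idx[0]
        offsets = [i - first for i in idx]
        body, last = offsets[:-1], offsets[-1]
        ok_body = all(o % self.annotation_stride == 0 for o in body)
        ok_last = last % self.annotation_stride == 0 or last == max(offsets)
        return ok_body and ok_last
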