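"""Clinical classifications and their confusion-matrix evaluation.

Two per-frame classifications underpin the seated-trunk-control (SATCo)
analysis:

``alignment``
    A head/trunk segment is *misaligned* (positive) when its angle deviates
    from the child's reference posture by strictly more than a threshold
    (clinically +/-20 deg; evaluated here over a +/-1..40 deg sweep).  The
    reference posture is the per-child mean of label-derived segment angles
    over all sessions — never of network output.

``contact``
    The upper limb is *in contact* with support (positive) when the elbow
    lies on the front side of the label-derived ASIS marker (strictly, in x)
    or the wrist lies strictly below it (in y, image-down).  With the camera
    on the child's right and the child facing image-left, "front" means
    smaller x; a facing flag flips the elbow rule.

Both rules use strict inequalities; ties classify as negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import (
    HEAD_TRUNK_SEGMENTS,
    SEGMENT_NAMES,
    circular_difference,
)
from .landmarks import KeypointSet, PointFeatureName

__all__ = [
    "ReferencePosture",
    "reference_posture",
    "classify_alignment",
    "classify_contact",
    "contact_stream",
    "ConfusionSummary",
    "confusion",
    "f1_from_precision_recall",
    "sweep_thresholds",
    "sweep_to_frame",
]


@dataclass
class ReferencePosture:
    """Per-child reference ("neutral") posture: one angle per segment, the
    arithmetic mean of label-derived angles over every labelled frame."""

    subject_id: str
    angles: dict

    def __getitem__(self, segment: str) -> float:
        return self.angles[segment]


def reference_posture(label_angles, subject_id: str = "") -> ReferencePosture:
    """Mean label-derived posture of one child over all levels and sessions.

    ``label_angles`` is a stream of SegmentAngleFrame computed from labels.
    Arithmetic (non-circular) means are used: seated postures live far from
    the +/-180 deg wrap.
    """
    from .kinematics import angles_to_frame

    arr = angles_to_frame(label_angles)
    if arr.shape[0] == 0:
        raise ValueError("cannot build a reference posture from an empty stream")
    means = arr.mean(axis=0)
    return ReferencePosture(
        subject_id=subject_id,
        angles={s: float(means[i]) for i, s in enumerate(SEGMENT_NAMES)},
    )


def classify_alignment(
    angles, ref: ReferencePosture, threshold: float, segments=HEAD_TRUNK_SEGMENTS
) -> np.ndarray:
    """Per-frame, per-segment misalignment calls.

    Positive (True) iff the absolute circular deviation from the reference
    exceeds ``threshold`` strictly.  Returns a boolean array of shape
    (n_frames, len(segments)).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    from .kinematics import angles_to_frame

    arr = angles_to_frame(angles)
    cols = [SEGMENT_NAMES.index(s) for s in segments]
    refvec = np.array([ref[s] for s in segments])
    dev = np.abs(circular_difference(arr[:, cols], refvec))
    return dev > threshold


def classify_contact(
    kp: KeypointSet, asis_ref, facing: str = "left"
) -> tuple[bool, bool, bool]:
    """Upper-limb contact calls for one frame.

    ``asis_ref`` is the label-derived ASIS (x, y) for this frame (a dynamic,
    pelvis-linked threshold).  Elbow contact: elbow strictly on the front
    side of the ASIS in x.  Wrist contact: wrist strictly below the ASIS in
    y.  ``facing`` gives the direction the child faces in the image and
    flips the elbow rule for a mirrored camera setup.
    """
    if facing not in ("left", "right"):
        raise ValueError("facing must be 'left' or 'right'")
    ax, ay = float(asis_ref[0]), float(asis_ref[1])
    ex = float(kp[PointFeatureName.ELBOW][0])
    wy = float(kp[PointFeatureName.WRIST][1])
    elbow = ex < ax if facing == "left" else ex > ax
    wrist = wy > ay
    return elbow, wrist, elbow or wrist


def contact_stream(kps, asis_refs, facing: str = "left") -> np.ndarray:
    """Vectorized contact calls: (n_frames, 3) booleans for
    (elbow, wrist, any)."""
    out = np.zeros((len(kps), 3), dtype=bool)
    for i, (kp, asis) in enumerate(zip(kps, asis_refs, strict=True)):
        out[i] = classify_contact(kp, asis, facing=facing)
    return out


@dataclass
class ConfusionSummary:
    """Binary confusion counts and the derived rates, as percentages.

    When no positive predictions exist, precision is undefined; it is
    reported as 0 with ``precision_defined`` False rather than silently
    dropped (and likewise recall / F1 for degenerate truth sets).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    precision_defined: bool = field(init=False, default=True)
    recall_defined: bool = field(init=False, default=True)

    def __post_init__(self) -> None:
        self.precision_defined = (self.tp + self.fp) > 0
        self.recall_defined = (self.tp + self.fn) > 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        """Number of positive cases in the truth."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def tpr(self) -> float:
        """True positive rate == recall."""
        return 100.0 * self.tp / (self.tp + self.fn) if self.recall_defined else 0.0

    recall = tpr

    @property
    def fnr(self) -> float:
        return 100.0 - self.tpr if self.recall_defined else 0.0

    @property
    def fpr(self) -> float:
        return 100.0 * self.fp / (self.fp + self.tn) if self.n_negative else 0.0

    @property
    def tnr(self) -> float:
        return 100.0 - self.fpr if self.n_negative else 0.0

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.precision_defined else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return f1_from_precision_recall(p, r)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "n_positive": self.n_positive, "n_negative": self.n_negative,
            "accuracy": self.accuracy, "tpr": self.tpr, "fpr": self.fpr,
            "tnr": self.tnr, "fnr": self.fnr, "precision": self.precision,
            "f1": self.f1, "precision_defined": self.precision_defined,
        }


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def confusion(pred, truth) -> ConfusionSummary:
    """Confusion summary of boolean prediction vs truth arrays."""
    pred = np.asarray(pred, dtype=bool).reshape(-1)
    truth = np.asarray(truth, dtype=bool).reshape(-1)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have the same length")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def sweep_thresholds(
    pred_angles,
    label_angles,
    ref: ReferencePosture,
    thresholds=range(1, 41),
    segments=HEAD_TRUNK_SEGMENTS,
) -> dict:
    """Agreement of network- vs label-derived misalignment over thresholds.

    For each segment and integer threshold (degrees), classify both angle
    streams against the same reference and threshold, then summarize their
    agreement (label-derived calls are the truth).  Returns
    {segment: {threshold: ConfusionSummary}} — the data behind the
    F1-vs-threshold curves.
    """
    out: dict = {s: {} for s in segments}
    for thr in thresholds:
        pred_cls = classify_alignment(pred_angles, ref, thr, segments=segments)
        true_cls = classify_alignment(label_angles, ref, thr, segments=segments)
        for j, s in enumerate(segments):
            out[s][int(thr)] = confusion(pred_cls[:, j], true_cls[:, j])
    return out


def sweep_to_frame(sweep: dict) -> pd.DataFrame:
    """Flatten a threshold sweep into a tidy DataFrame (one row per
    segment x threshold), in the layout of the per-segment report."""
    rows = []
    for segment, by_thr in sweep.items():
        for thr, cs in by_thr.items():
            row = {"segment": segment, "threshold": thr}
            row.update(cs.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)
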