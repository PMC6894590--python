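"""Synthetic sagittal seated-child sequences with exact ground truth.

The clinical videos behind this pipeline are ethics-restricted, so every
downstream stage is exercised on rendered stand-ins: a side-profile seated
child, articulated by the same 10 segments the kinematics module measures,
with small coloured square markers on the 10 head/trunk/pelvis landmarks
(the arm carries none, as in the clinical setup), a bench, an optional
far-side-arm confuser, skin-toned occluding rectangles standing in for
therapist hands, and per-frame brightness/contrast jitter.

Geometry is exact: the returned keypoints are the forward-kinematics floats,
never pixel-quantized, so segment angles recomputed from them invert the
generating pose to numerical precision.  Occlusion affects pixels only.
Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, ImageDraw

from . import assess
from .data_io import write_labels
from .kinematics import HEAD_TRUNK_SEGMENTS, SEGMENT_NAMES, circular_difference
from .landmarks import POINT_FEATURES, AnnotationTable, KeypointSet, PointFeatureName

__all__ = [
    "FigureModel",
    "PoseTrajectory",
    "SynthConfig",
    "forward_kinematics",
    "sample_trajectory",
    "render_frame",
    "synthesize_subject",
    "generate_dataset",
]

P = PointFeatureName

#: landmarks carrying a physical marker block (everything but the arm)
MARKED_FEATURES: tuple = tuple(
    f for f in POINT_FEATURES if f not in (P.SHOULDER, P.ELBOW, P.WRIST)
)

_DEFAULT_MARKER_COLORS = {
    P.TEMPORAL_FOSSA: (220, 40, 40),
    P.EAR_TRAGUS: (40, 120, 220),
    P.C7: (240, 200, 40),
    P.T3: (40, 200, 80),
    P.T7: (200, 60, 200),
    P.T11: (60, 220, 220),
    P.L3: (240, 140, 40),
    P.S1: (140, 80, 220),
    P.ASIS: (245, 245, 245),
    P.GREATER_TROCHANTER: (35, 35, 35),
}

# base pose, degrees from vertical: near-vertical spine with a gentle
# physiological curve, pelvis segment close to horizontal (ASIS forward of
# the greater trochanter), arm hanging slightly forward
_DEFAULT_BASE_POSE = {
    "head": 0.0,
    "neck": -15.0,
    "UT": -5.0,
    "MT": -3.0,
    "LT": 0.0,
    "UL": 3.0,
    "LL": 5.0,
    "pelvis": -75.0,
    "upper_arm": 15.0,
    "forearm": -10.0,
}

# bone lengths at the canonical 64-px canvas, proportioned after a seated
# child filling most of the frame; scaled linearly with image size
_BASE_LENGTHS_64 = {
    "head": 6.0,
    "neck": 6.0,
    "UT": 7.0,
    "MT": 7.0,
    "LT": 7.0,
    "UL": 7.0,
    "LL": 7.0,
    "pelvis": 10.0,
    "upper_arm": 18.0,
    "forearm": 16.0,
}

# default per-segment bounded-random-walk half-ranges (degrees about base)
_DEFAULT_BOUNDS = {
    "head": 25.0,
    "neck": 20.0,
    "UT": 18.0,
    "MT": 18.0,
    "LT": 18.0,
    "UL": 18.0,
    "LL": 18.0,
    "pelvis": 12.0,
    "upper_arm": 30.0,
    "forearm": 30.0,
}


@dataclass
class FigureModel:
    """Anthropometry and appearance of one rendered child."""

    bone_lengths: dict
    base_pose: dict = field(default_factory=lambda: dict(_DEFAULT_BASE_POSE))
    marker_size: float = 3.0  # square side, pixels
    marker_colors: dict = field(default_factory=lambda: dict(_DEFAULT_MARKER_COLORS))
    torso_width: float = 10.0
    arm_width: float = 4.0
    head_radius: float = 7.0
    anchor: tuple = (36.0, 52.0)  # S1 position, pixels
    gt_offset: tuple = (1.0, 6.0)  # greater trochanter relative to S1
    shoulder_offset: tuple = (-3.0, 3.0)  # shoulder relative to C7
    skin_color: tuple = (224, 172, 132)
    shirt_color: tuple = (90, 110, 160)
    far_arm_color: tuple = (190, 140, 105)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.bone_lengths.values()):
            raise ValueError("bone lengths must be positive")
        if self.marker_size < 1:
            raise ValueError("marker_size must be >= 1 pixel")

    @classmethod
    def default(cls, image_size: int = 64, variant_seed: int | None = None
                ) -> "FigureModel":
        """Default figure scaled to ``image_size``.

        ``variant_seed`` perturbs anthropometry (+/-10% bone lengths, torso
        width, anchor) to emulate a different child; None gives the
        canonical figure.
        """
        s = image_size / 64.0
        lengths = {k: v * s for k, v in _BASE_LENGTHS_64.items()}
        torso_w, head_r = 10.0 * s, 7.0 * s
        anchor = (36.0 * s, 52.0 * s)
        if variant_seed is not None:
            rng = np.random.default_rng(variant_seed)
            lengths = {
                k: v * rng.uniform(0.9, 1.1) for k, v in lengths.items()
            }
            torso_w *= rng.uniform(0.85, 1.15)
            head_r *= rng.uniform(0.9, 1.1)
            anchor = (
                anchor[0] + rng.uniform(-2.0, 2.0) * s,
                anchor[1] + rng.uniform(-2.0, 2.0) * s,
            )
        return cls(
            bone_lengths=lengths,
            marker_size=max(1.0, 3.0 * s),
            torso_width=torso_w,
            arm_width=4.0 * s,
            head_radius=head_r,
            anchor=anchor,
            gt_offset=(1.0 * s, 6.0 * s),
            shoulder_offset=(-3.0 * s, 3.0 * s),
        )


@dataclass
class SynthConfig:
    """Generation parameters; ``seed`` fully determines the output."""

    image_size: int = 64
    n_frames: int = 300
    seed: int = 0
    fps: float = 25.0
    occluder_rate: float = 0.15  # probability per frame
    occluder_size_range: tuple = (6.0, 12.0)  # pixels at image_size 64
    brightness_jitter: float = 12.0  # additive, 0-255 units
    contrast_jitter: float = 0.15  # multiplicative half-range
    angle_step_sd: float = 1.2  # random-walk step SD, deg/frame
    max_step: float = 4.0  # hard per-frame angular velocity cap, deg
    angle_bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    alignment_threshold: float = 15.0  # deg, for the misalignment truth
    render_far_arm: bool = True
    facing: str = "left"
    supersample: int = 4
    subject_id: str = "synth-000"
    session_id: str = "s01"

    def __post_init__(self) -> None:
        lo, hi = self.occluder_size_range
        if not (0 < lo < hi):
            raise ValueError("occluder_size_range must be a non-degenerate range")
        if self.facing not in ("left", "right"):
            raise ValueError("facing must be 'left' or 'right'")


@dataclass
class PoseTrajectory:
    """Per-frame generating angles plus the derived truth channels."""

    angles: np.ndarray  # (n_frames, 10), ordered by SEGMENT_NAMES, degrees
    contact_truth: np.ndarray  # (n_frames, 3) bool: elbow, wrist, any
    misalignment_truth: np.ndarray  # (n_frames, 8) bool over HEAD_TRUNK_SEGMENTS
    alignment_threshold: float
    reference: np.ndarray  # (10,) per-segment mean angle of this trajectory
    seed: int

    def __len__(self) -> int:
        return self.angles.shape[0]


def forward_kinematics(model: FigureModel, pose) -> KeypointSet:
    """Place the 13 landmarks for one pose (dict or 10-vector of degrees).

    The trunk chain runs S1 -> L3 -> T11 -> T7 -> T3 -> C7 -> ear tragus ->
    temporal fossa; the pelvis hangs off S1, the shoulder off C7.  Each
    segment advances from its distal to its proximal point by
    ``length * (sin a, -cos a)``, so a segment at 0 deg is vertical with the
    proximal point on top — exactly the convention the kinematics module
    inverts.
    """
    if not isinstance(pose, dict):
        pose = {s: float(v) for s, v in zip(SEGMENT_NAMES, pose, strict=True)}
    L = model.bone_lengths

    def step(origin, seg):
        a = np.radians(pose[seg])
        return origin + L[seg] * np.array([np.sin(a), -np.cos(a)])

    pts = {}
    pts[P.S1] = np.array(model.anchor, dtype=float)
    pts[P.L3] = step(pts[P.S1], "LL")
    pts[P.T11] = step(pts[P.L3], "UL")
    pts[P.T7] = step(pts[P.T11], "LT")
    pts[P.T3] = step(pts[P.T7], "MT")
    pts[P.C7] = step(pts[P.T3], "UT")
    pts[P.EAR_TRAGUS] = step(pts[P.C7], "neck")
    pts[P.TEMPORAL_FOSSA] = step(pts[P.EAR_TRAGUS], "head")
    pts[P.GREATER_TROCHANTER] = pts[P.S1] + np.asarray(model.gt_offset, float)
    pts[P.ASIS] = step(pts[P.GREATER_TROCHANTER], "pelvis")
    pts[P.SHOULDER] = pts[P.C7] + np.asarray(model.shoulder_offset, float)
    # the arm hangs: distal = proximal - length * direction
    a = np.radians(pose["upper_arm"])
    pts[P.ELBOW] = pts[P.SHOULDER] - L["upper_arm"] * np.array(
        [np.sin(a), -np.cos(a)]
    )
    a = np.radians(pose["forearm"])
    pts[P.WRIST] = pts[P.ELBOW] - L["forearm"] * np.array([np.sin(a), -np.cos(a)])

    coords = np.stack([pts[f] for f in POINT_FEATURES])
    return KeypointSet(coords, frame_index=0, source="manual")


def sample_trajectory(cfg: SynthConfig, model: FigureModel) -> PoseTrajectory:
    """Bounded random-walk angle sequences and the derived truth channels.

    Each segment performs an independent Gaussian random walk about its base
    pose, with steps capped at ``cfg.max_step`` degrees/frame (continuity)
    and excursions clipped to ``cfg.angle_bounds``.  Contact truth is
    computed by forward kinematics and the *same* contact rule the
    assessment module applies; misalignment truth uses the same deviation
    rule against this trajectory's own mean posture.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    base = np.array([model.base_pose[s] for s in SEGMENT_NAMES])
    bounds = np.array([cfg.angle_bounds[s] for s in SEGMENT_NAMES])
    steps = rng.normal(0.0, cfg.angle_step_sd, size=(n, len(SEGMENT_NAMES)))
    steps = np.clip(steps, -cfg.max_step, cfg.max_step)
    angles = np.empty((n, len(SEGMENT_NAMES)))
    cur = base.copy()
    for t in range(n):
        cur = np.clip(cur + steps[t], base - bounds, base + bounds)
        angles[t] = cur

    contact = np.zeros((n, 3), dtype=bool)
    for t in range(n):
        kp = forward_kinematics(model, angles[t])
        asis = kp[P.ASIS]
        contact[t] = assess.classify_contact(kp, asis, facing="left")

    reference = angles.mean(axis=0)
    cols = [SEGMENT_NAMES.index(s) for s in HEAD_TRUNK_SEGMENTS]
    dev = np.abs(circular_difference(angles[:, cols], reference[cols]))
    misaligned = dev > cfg.alignment_threshold
    return PoseTrajectory(
        angles=angles,
        contact_truth=contact,
        misalignment_truth=misaligned,
        alignment_threshold=cfg.alignment_threshold,
        reference=reference,
        seed=cfg.seed,
    )


def _t(xy, ss):
    """Final-space coordinate -> supersampled drawing coordinate."""
    return tuple(ss * np.asarray(xy, float) + (ss - 1) / 2.0)


def render_frame(
    model: FigureModel,
    pose,
    cfg: SynthConfig,
    frame_seed: int,
    frame_index: int = 0,
) -> tuple[np.ndarray, KeypointSet]:
    """Render one frame; returns (uint8 RGB image, exact-geometry keypoints).

    Drawing happens on a ``cfg.supersample``-times-larger canvas and is
    box-downsampled, so edges and markers are anti-aliased and carry
    sub-pixel position.  ``frame_seed`` drives the stochastic nuisances
    (occluder, photometric jitter, far-arm offset); identical arguments give
    identical pixel buffers.
    """
    rng = np.random.default_rng(frame_seed)
    kp = forward_kinematics(model, pose)
    size, ss = cfg.image_size, cfg.supersample
    canvas = size * ss
    img = Image.new("RGB", (canvas, canvas), (180, 185, 190))
    draw = ImageDraw.Draw(img)

    # bench under the child
    bench_y = int((model.anchor[1] + model.gt_offset[1] + 3) * ss)
    draw.rectangle([0, bench_y, canvas, canvas], fill=(120, 95, 70))

    pts = {f: kp[f] for f in POINT_FEATURES}

    # far-side arm confuser: unlabeled, behind the body, offset pose
    if cfg.render_far_arm:
        if not isinstance(pose, dict):
            posed = {s: float(v) for s, v in zip(SEGMENT_NAMES, pose, strict=True)}
        else:
            posed = dict(pose)
        off = rng.uniform(-20.0, 20.0, size=2)
        sh = pts[P.SHOULDER] + np.array([1.5, 1.0]) * (size / 64.0)
        a1 = np.radians(posed["upper_arm"] + off[0])
        el = sh - model.bone_lengths["upper_arm"] * np.array(
            [np.sin(a1), -np.cos(a1)]
        )
        a2 = np.radians(posed["forearm"] + off[1])
        wr = el - model.bone_lengths["forearm"] * np.array([np.sin(a2), -np.cos(a2)])
        w = int(max(1, model.arm_width * ss))
        draw.line([_t(sh, ss), _t(el, ss)], fill=model.far_arm_color, width=w)
        draw.line([_t(el, ss), _t(wr, ss)], fill=model.far_arm_color, width=w)

    # torso: thick capsule through the spinal chain, offset half a width
    # toward the front so the spine markers sit on the back edge
    front = -1.0 if cfg.facing == "left" else 1.0
    toff = np.array([front * model.torso_width / 2.0, 0.0])
    chain = [P.S1, P.L3, P.T11, P.T7, P.T3, P.C7]
    tw = int(max(1, model.torso_width * ss))
    torso_pts = [_t(pts[f] + toff, ss) for f in chain]
    draw.line(torso_pts, fill=model.shirt_color, width=tw, joint="curve")

    # pelvis/hip mass
    hip = pts[P.GREATER_TROCHANTER]
    hr = model.torso_width * 0.75
    draw.ellipse(
        [_t(hip - hr, ss), _t(hip + hr, ss)], fill=(70, 85, 125)
    )

    # neck and head
    nw = int(max(1, model.arm_width * ss))
    draw.line([_t(pts[P.C7], ss), _t(pts[P.EAR_TRAGUS], ss)],
              fill=model.skin_color, width=nw)
    hc = (pts[P.EAR_TRAGUS] + pts[P.TEMPORAL_FOSSA]) / 2.0
    r = model.head_radius
    draw.ellipse([_t(hc - r, ss), _t(hc + r, ss)], fill=model.skin_color)

    # right (near-side) arm — no markers on it
    aw = int(max(1, model.arm_width * ss))
    draw.line([_t(pts[P.SHOULDER], ss), _t(pts[P.ELBOW], ss)],
              fill=model.skin_color, width=aw)
    draw.line([_t(pts[P.ELBOW], ss), _t(pts[P.WRIST], ss)],
              fill=model.skin_color, width=aw)

    # marker blocks on head/trunk/pelvis landmarks
    half = model.marker_size / 2.0
    for f in MARKED_FEATURES:
        c = pts[f]
        draw.rectangle(
            [_t(c - half, ss), _t(c + half, ss)], fill=model.marker_colors[f]
        )

    # therapist-hand occluder over a random landmark
    if rng.uniform() < cfg.occluder_rate:
        target = pts[POINT_FEATURES[rng.integers(len(POINT_FEATURES))]]
        osz = rng.uniform(*cfg.occluder_size_range) * (size / 64.0)
        jitter = rng.uniform(-2.0, 2.0, size=2)
        c = np.asarray(target, float) + jitter
        draw.rectangle(
            [_t(c - osz / 2, ss), _t(c + osz / 2, ss)], fill=(210, 160, 120)
        )

    out = img.resize((size, size), Image.BOX)
    arr = np.asarray(out, dtype=np.float32)

    # photometric jitter: global contrast scale + brightness offset
    gain = 1.0 + rng.uniform(-cfg.contrast_jitter, cfg.contrast_jitter)
    offset = rng.uniform(-cfg.brightness_jitter, cfg.brightness_jitter)
    arr = np.clip((arr - 128.0) * gain + 128.0 + offset, 0, 255)
    arr = arr.astype(np.uint8)

    coords = kp.coords
    if cfg.facing == "right":
        arr = arr[:, ::-1].copy()
        coords = coords.copy()
        coords[:, 0] = (size - 1) - coords[:, 0]
    return arr, KeypointSet(coords, frame_index=frame_index, source="manual")


def synthesize_subject(
    cfg: SynthConfig, model: FigureModel | None = None
) -> tuple[np.ndarray, np.ndarray, PoseTrajectory]:
    """Generate one sequence fully in memory.

    Returns (images uint8 (n, H, W, 3), keypoints float (n, 13, 2),
    trajectory).  Frame seeds are derived deterministically from
    ``cfg.seed``.
    """
    model = model or FigureModel.default(cfg.image_size)
    traj = sample_trajectory(cfg, model)
    n = len(traj)
    images = np.empty((n, cfg.image_size, cfg.image_size, 3), dtype=np.uint8)
    coords = np.empty((n, len(POINT_FEATURES), 2))
    frame_seeds = np.random.default_rng(cfg.seed).integers(0, 2**31, size=n)
    for t in range(n):
        img, kp = render_frame(model, traj.angles[t], cfg, int(frame_seeds[t]),
                               frame_index=t)
        images[t] = img
        coords[t] = kp.coords
    return images, coords, traj


def generate_dataset(cfg: SynthConfig, model: FigureModel | None = None,
                     out_dir=None) -> dict:
    """Write a complete synthetic dataset to ``out_dir`` and return its
    manifest.

    Layout: ``frames/%06d.png``, ``labels_dense.csv`` (every frame),
    ``labels_stride4.csv`` (manual rows at stride 4 plus the final frame),
    ``truth_alignment.csv``, ``truth_contact.csv`` and ``manifest.yaml``.
    """
    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    model = model or FigureModel.default(cfg.image_size)
    images, coords, traj = synthesize_subject(cfg, model)
    n = len(traj)

    frame_paths = []
    for t in range(n):
        p = out / "frames" / f"{t:06d}.png"
        Image.fromarray(images[t]).save(p)
        frame_paths.append(f"frames/{t:06d}.png")

    dense = AnnotationTable(
        rows={
            t: KeypointSet(coords[t], frame_index=t, source="manual")
            for t in range(n)
        }
    )
    write_labels(dense, out / "labels_dense.csv")

    manual_idx = sorted(set(range(0, n, 4)) | {n - 1})
    sparse = AnnotationTable(
        rows={
            t: KeypointSet(coords[t], frame_index=t, source="manual")
            for t in manual_idx
        },
        annotation_stride=4,
    )
    write_labels(sparse, out / "labels_stride4.csv")

    import pandas as pd

    pd.DataFrame(
        traj.misalignment_truth, columns=list(HEAD_TRUNK_SEGMENTS)
    ).assign(frame_index=np.arange(n))[
        ["frame_index", *HEAD_TRUNK_SEGMENTS]
    ].to_csv(out / "truth_alignment.csv", index=False)
    pd.DataFrame(
        traj.contact_truth, columns=["elbow", "wrist", "any"]
    ).assign(frame_index=np.arange(n))[
        ["frame_index", "elbow", "wrist", "any"]
    ].to_csv(out / "truth_contact.csv", index=False)

    manifest = {
        "frame_paths": frame_paths,
        "fps": cfg.fps,
        "roi": [0, 0, cfg.image_size, cfg.image_size],
        "subject_id": cfg.subject_id,
        "session_id": cfg.session_id,
        "seed": cfg.seed,
        "labels_dense": "labels_dense.csv",
        "labels_stride4": "labels_stride4.csv",
        "truth_alignment": "truth_alignment.csv",
        "truth_contact": "truth_contact.csv",
        "alignment_threshold": cfg.alignment_threshold,
        "reference_angles": {
            s: float(traj.reference[i]) for i, s in enumerate(SEGMENT_NAMES)
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
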