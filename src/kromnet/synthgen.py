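"""Synthetic single-knee image generator with known flexion angles.

Emulates the clinical acquisition setting the classifier is meant for: a
supine patient photographed side-on, the operated leg isolated, thigh and
shank idealized as two thick linked segments (capsules) hinged at the knee.
The knee flexion angle — 0° for a fully straight leg, up to 150° — is the
ground truth every downstream stage is evaluated against.  Nuisance
variation (limb thickness, scale, translation, global rotation, background
and foreground intensity, blur, sensor noise, partial occlusion) stands in
for handheld-camera variability.

Labels follow the clinical grading used after total knee arthroplasty:

* four-class (per maximal-effort attempt): standard flexion (ROM >= 125°),
  substandard flexion (< 125°), standard extension (ROM = 0°), substandard
  extension (> 0°), coded 0-3;
* six-class: nearest of the nominal recovery milestones
  0°, 25°, 50°, 75°, 100°, 125°.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "LimbPose",
    "ImageRecord",
    "DatasetManifest",
    "FOUR_CLASS_NAMES",
    "SIX_CLASS_NOMINALS",
    "PUBLISHED_FOUR_CLASS_COUNTS",
    "PUBLISHED_SIX_CLASS_COUNTS",
    "sample_pose",
    "render_limb",
    "assign_four_class",
    "assign_six_class",
    "generate_dataset",
    "MANIFEST_COLUMNS",
]

PoseType = Literal["flexion", "extension"]

FOUR_CLASS_NAMES = (
    "standard_flexion",
    "substandard_flexion",
    "standard_extension",
    "substandard_extension",
)

#: Nominal angles (degrees) of the six recovery-milestone classes.
SIX_CLASS_NOMINALS = (0.0, 25.0, 50.0, 75.0, 100.0, 125.0)

#: Published four-class composition of the clinical dataset (labels 0-3).
PUBLISHED_FOUR_CLASS_COUNTS = (300, 243, 272, 288)

#: Published six-class composition (0°, 25°, 50°, 75°, 100°, 125°).
PUBLISHED_SIX_CLASS_COUNTS = (139, 206, 219, 221, 204, 165)

#: Tolerance (degrees) within which a continuous angle counts as "ROM = 0°".
ZERO_EXTENSION_TOL = 0.5

MANIFEST_COLUMNS = ["id", "path", "pose_type", "angle_deg", "label4", "label6", "split"]

DEFAULT_CANVAS = 240

# Angle-sampling ranges per label.  Flexion attempts draw from [60, 150],
# extension attempts from [0, 40] (clinically plausible maximal-effort
# ranges).  Small margins keep sampled angles away from label boundaries so
# that a label re-derived from the 3-decimal stored angle never flips.
_FOUR_CLASS_ANGLE_RANGES = {
    0: (125.0, 150.0),
    1: (60.0, 124.9),
    2: (0.0, 0.45),
    3: (1.0, 40.0),
}
# Six-class bins have midpoint edges at 12.5, 37.5, ..., 112.5.
_SIX_CLASS_ANGLE_RANGES = {
    0: (0.0, 12.0),
    1: (13.0, 37.0),
    2: (38.0, 62.0),
    3: (63.0, 87.0),
    4: (88.0, 112.0),
    5: (113.0, 150.0),
}


@dataclass(frozen=True)
class LimbPose:
    """Geometric ground truth for one synthetic knee image.

    Coordinates are image-plane ``(x, y)`` pixels.  ``flexion_angle`` is the
    knee flexion in degrees: 180° minus the interior angle at ``knee_xy``
    formed by ``hip_xy`` and ``ankle_xy``.
    """

    hip_xy: tuple[float, float]
    knee_xy: tuple[float, float]
    ankle_xy: tuple[float, float]
    flexion_angle: float
    pose_type: str
    thigh_len: float
    shank_len: float
    limb_halfwidth: float
    global_rotation: float
    translation: tuple[float, float]
    background_level: int
    foreground_level: int
    noise_sd: float
    blur_radius: float
    occlusion_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.flexion_angle <= 150.0:
            raise ValueError(f"flexion_angle {self.flexion_angle} outside [0, 150]")
        if self.pose_type not in ("flexion", "extension"):
            raise ValueError(f"unknown pose_type {self.pose_type!r}")
        if self.thigh_len <= 0 or self.shank_len <= 0:
            raise ValueError("segment lengths must be positive")
        if abs(self.foreground_level - self.background_level) < 40:
            raise ValueError(
                "foreground/background gap "
                f"{abs(self.foreground_level - self.background_level)} < 40 "
                "breaks threshold separability"
            )
        if not 0.0 <= self.occlusion_fraction <= 0.3:
            raise ValueError(f"occlusion_fraction {self.occlusion_fraction} outside [0, 0.3]")
        stored = interior_angle_deg(self.hip_xy, self.knee_xy, self.ankle_xy)
        if abs((180.0 - stored) - self.flexion_angle) > 1e-6:
            raise ValueError(
                f"flexion_angle {self.flexion_angle} inconsistent with joint "
                f"coordinates (geometric value {180.0 - stored:.8f})"
            )


def interior_angle_deg(
    a: Sequence[float], vertex: Sequence[float], b: Sequence[float]
) -> float:
    """Interior angle at ``vertex`` formed by points ``a`` and ``b``, degrees."""
    u = np.asarray(a, dtype=float) - np.asarray(vertex, dtype=float)
    v = np.asarray(b, dtype=float) - np.asarray(vertex, dtype=float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


@dataclass
class ImageRecord:
    """One image plus metadata: true angle and labels under both schemes."""

    id: str
    path: str
    pose_type: str
    angle_deg: float
    label4: int
    label6: int
    split: str = ""


@dataclass
class DatasetManifest:
    """Ordered record collection with its label scheme and composition."""

    records: list[ImageRecord]
    scheme: str
    class_counts: tuple[int, ...]
    global_seed: int

    def __post_init__(self) -> None:
        if self.scheme not in ("four_class", "six_class"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record ids are not unique")
        if sum(self.class_counts) != len(self.records):
            raise ValueError("class_counts do not sum to the number of records")
        k = len(self.class_counts)
        for r in self.records:
            if not 0 <= self.label_of(r) < k:
                raise ValueError(f"record {r.id} label outside [0, {k - 1}]")

    def label_of(self, record: ImageRecord) -> int:
        return record.label4 if self.scheme == "four_class" else record.label6

    @property
    def labels(self) -> np.ndarray:
        return np.array([self.label_of(r) for r in self.records], dtype=int)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [
                {
                    "id": r.id,
                    "path": r.path,
                    "pose_type": r.pose_type,
                    "angle_deg": f"{r.angle_deg:.3f}",
                    "label4": r.label4,
                    "label6": r.label6,
                    "split": r.split,
                }
                for r in self.records
            ],
            columns=MANIFEST_COLUMNS,
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, scheme: str, global_seed: int = 0
    ) -> "DatasetManifest":
        df = pd.read_csv(path, dtype={"split": str}, keep_default_na=False)
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
        records = [
            ImageRecord(
                id=str(row.id),
                path=str(row.path),
                pose_type=str(row.pose_type),
                angle_deg=float(row.angle_deg),
                label4=int(row.label4),
                label6=int(row.label6),
                split=str(row.split),
            )
            for row in df.itertuples(index=False)
        ]
        k = 4 if scheme == "four_class" else 6
        key = "label4" if scheme == "four_class" else "label6"
        counts = tuple(int((df[key] == c).sum()) for c in range(k))
        return cls(records=records, scheme=scheme, class_counts=counts, global_seed=global_seed)

    def subset(self, indices: Sequence[int], split_value: str | None = None) -> "DatasetManifest":
        recs = []
        for i in indices:
            r = self.records[i]
            recs.append(
                ImageRecord(r.id, r.path, r.pose_type, r.angle_deg, r.label4, r.label6,
                            split_value if split_value is not None else r.split)
            )
        k = len(self.class_counts)
        counts = tuple(sum(1 for r in recs if self.label_of(r) == c) for c in range(k))
        return DatasetManifest(recs, self.scheme, counts, self.global_seed)


def assign_four_class(flexion_angle: float, pose_type: str) -> int:
    """Four-class clinical label from angle and attempt type.

    Flexion attempt: 0 (standard) iff angle >= 125°, else 1.  Extension
    attempt: 2 (standard) iff angle is 0° within ``ZERO_EXTENSION_TOL``,
    else 3.  Coding 0-3.
    """
    if not 0.0 <= flexion_angle <= 150.0:
        raise ValueError(f"flexion_angle {flexion_angle} outside [0, 150]")
    if pose_type == "flexion":
        return 0 if flexion_angle >= 125.0 else 1
    if pose_type == "extension":
        return 2 if flexion_angle <= ZERO_EXTENSION_TOL else 3
    raise ValueError(f"unknown pose_type {pose_type!r}")


def assign_six_class(flexion_angle: float) -> int:
    """Index of the nearest nominal milestone among 0°, 25°, ..., 125°.

    Bin edges fall at the midpoints (12.5°, 37.5°, ..., 112.5°); angles
    above 125° map to the 125° class.  Ties go to the lower milestone.
    """
    if not 0.0 <= flexion_angle <= 150.0:
        raise ValueError(f"flexion_angle {flexion_angle} outside [0, 150]")
    dists = [abs(flexion_angle - nom) for nom in SIX_CLASS_NOMINALS]
    return int(np.argmin(dists))


def _pose_type_for(scheme: str, target_label: int, angle: float) -> str:
    if scheme == "four_class":
        return "flexion" if target_label in (0, 1) else "extension"
    # Six-class images come from both attempt types; low milestones arise
    # from extension attempts, high ones from flexion attempts.
    return "extension" if angle <= 37.0 else "flexion"


def sample_pose(
    scheme: str,
    target_label: int,
    rng_seed: int,
    canvas: int = DEFAULT_CANVAS,
) -> LimbPose:
    """Draw a limb pose whose flexion angle maps to ``target_label``.

    All nuisance parameters are drawn from fixed distributions seeded by
    ``rng_seed``; identical arguments always return identical poses.
    """
    if scheme == "four_class":
        ranges = _FOUR_CLASS_ANGLE_RANGES
    elif scheme == "six_class":
        ranges = _SIX_CLASS_ANGLE_RANGES
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if target_label not in ranges:
        raise ValueError(f"label {target_label} invalid for scheme {scheme!r}")

    rng = np.random.default_rng(np.random.SeedSequence([rng_seed & 0x7FFFFFFF]))
    lo, hi = ranges[target_label]
    angle = float(rng.uniform(lo, hi))
    pose_type = _pose_type_for(scheme, target_label, angle)

    thigh_len = float(rng.uniform(0.28, 0.375) * canvas)
    shank_len = float(rng.uniform(0.26, 0.35) * canvas)
    halfwidth = float(rng.uniform(0.030, 0.048) * canvas)
    global_rotation = float(rng.uniform(-15.0, 15.0))
    translation = (float(rng.uniform(-8.0, 8.0)), float(rng.uniform(-8.0, 8.0)))
    background = int(rng.integers(10, 81))
    foreground = int(min(255, background + int(rng.integers(60, 151))))
    noise_sd = float(rng.uniform(0.0, 8.0))
    blur_radius = float(rng.uniform(0.0, 1.5))
    occlusion = float(rng.uniform(0.0, 0.25))

    knee = (canvas / 2.0 + translation[0], canvas / 2.0 + translation[1])
    interior = 180.0 - angle
    base = math.radians(global_rotation)
    half = math.radians(interior) / 2.0
    u_thigh = (math.cos(base + half), math.sin(base + half))
    u_shank = (math.cos(base - half), math.sin(base - half))
    hip = (knee[0] + thigh_len * u_thigh[0], knee[1] + thigh_len * u_thigh[1])
    ankle = (knee[0] + shank_len * u_shank[0], knee[1] + shank_len * u_shank[1])
    # Store the exact geometric angle so the coordinate invariant holds to
    # machine precision.
    angle = 180.0 - interior_angle_deg(hip, knee, ankle)
    angle = float(min(max(angle, lo), hi))

    return LimbPose(
        hip_xy=hip,
        knee_xy=knee,
        ankle_xy=ankle,
        flexion_angle=angle,
        pose_type=pose_type,
        thigh_len=thigh_len,
        shank_len=shank_len,
        limb_halfwidth=halfwidth,
        global_rotation=global_rotation,
        translation=translation,
        background_level=background,
        foreground_level=foreground,
        noise_sd=noise_sd,
        blur_radius=blur_radius,
        occlusion_fraction=occlusion,
        seed=int(rng_seed),
    )


def _segment_distance(
    yy: np.ndarray, xx: np.ndarray, p0: Sequence[float], p1: Sequence[float]
) -> np.ndarray:
    """Distance from every pixel center to the segment p0-p1 (vectorized)."""
    p0 = np.asarray(p0, dtype=np.float64)
    d = np.asarray(p1, dtype=np.float64) - p0
    len2 = float(d @ d)
    px = xx - p0[0]
    py = yy - p0[1]
    t = np.clip((px * d[0] + py * d[1]) / max(len2, 1e-12), 0.0, 1.0)
    return np.hypot(px - t * d[0], py - t * d[1])


def limb_mask(pose: LimbPose, height: int, width: int) -> np.ndarray:
    """Boolean silhouette of the two capsules (before blur/noise/occlusion)."""
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    d_thigh = _segment_distance(yy, xx, pose.knee_xy, pose.hip_xy)
    d_shank = _segment_distance(yy, xx, pose.knee_xy, pose.ankle_xy)
    return np.minimum(d_thigh, d_shank) <= pose.limb_halfwidth


def render_limb(pose: LimbPose, height: int, width: int) -> np.ndarray:
    """Render the pose to an 8-bit grayscale image.

    Compositing order is fixed: capsule silhouette over background, then
    Gaussian blur, additive noise, rectangular occlusion, clamp to [0, 255].
    The knee vertex is never silently cropped: any joint closer to the
    border than the limb half-width is an error.
    """
    margin = pose.limb_halfwidth
    for name, (x, y) in (("hip", pose.hip_xy), ("knee", pose.knee_xy), ("ankle", pose.ankle_xy)):
        if not (margin <= x <= width - 1 - margin and margin <= y <= height - 1 - margin):
            raise ValueError(
                f"{name} joint at ({x:.1f}, {y:.1f}) falls outside the "
                f"{width}x{height} canvas (margin {margin:.1f})"
            )

    mask = limb_mask(pose, height, width)
    img = np.full((height, width), float(pose.background_level))
    img[mask] = float(pose.foreground_level)

    if pose.blur_radius > 0:
        img = ndimage.gaussian_filter(img, sigma=pose.blur_radius)

    rng = np.random.default_rng(np.random.SeedSequence([pose.seed & 0x7FFFFFFF, 0xB10B]))
    if pose.noise_sd > 0:
        img = img + rng.normal(0.0, pose.noise_sd, size=img.shape)

    if pose.occlusion_fraction > 0:
        img = _occlude(img, mask, pose, rng)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _occlude(
    img: np.ndarray, mask: np.ndarray, pose: LimbPose, rng: np.random.Generator
) -> np.ndarray:
    """Cover ~occlusion_fraction of limb pixels with a background rectangle."""
    limb_area = int(mask.sum())
    target = pose.occlusion_fraction * limb_area
    if limb_area == 0 or target < 1:
        return img
    ys, xs = np.nonzero(mask)
    i = int(rng.integers(0, len(ys)))
    cy, cx = int(ys[i]), int(xs[i])
    # Grow a square about a random limb pixel until it covers the target
    # number of limb pixels (capped at the stated 30% severity).
    side = 2
    h, w = img.shape
    while side < max(h, w):
        y0, y1 = max(0, cy - side // 2), min(h, cy + side // 2 + 1)
        x0, x1 = max(0, cx - side // 2), min(w, cx + side // 2 + 1)
        covered = int(mask[y0:y1, x0:x1].sum())
        if covered >= target or covered >= 0.3 * limb_area:
            break
        side += 2
    img = img.copy()
    img[y0:y1, x0:x1] = float(pose.background_level)
    return img


def noiseless(pose: LimbPose) -> LimbPose:
    """Copy of the pose with blur, noise and occlusion switched off."""
    return replace(pose, noise_sd=0.0, blur_radius=0.0, occlusion_fraction=0.0)


def record_seed(global_seed: int, index: int) -> int:
    """Deterministic per-record seed; order-stable under regeneration."""
    return int(np.random.SeedSequence([global_seed & 0x7FFFFFFF, index]).generate_state(1)[0] & 0x7FFFFFFF)


def generate_dataset(
    scheme: str,
    class_counts: Sequence[int],
    canvas: int,
    out_dir: str | Path,
    global_seed: int,
    write_images: bool = True,
) -> DatasetManifest:
    """Generate a labeled synthetic dataset on disk.

    Writes one grayscale PNG per record plus ``manifest.csv``.  Record
    order is by (label, within-label index); per-record seeds derive from
    ``global_seed`` and the global record index only, so the dataset is
    byte-reproducible.
    """
    k = 4 if scheme == "four_class" else 6
    class_counts = tuple(int(c) for c in class_counts)
    if len(class_counts) != k:
        raise ValueError(f"{scheme} needs {k} class counts, got {len(class_counts)}")
    if any(c < 0 for c in class_counts):
        raise ValueError("class counts must be nonnegative")

    out_dir = Path(out_dir)
    records: list[ImageRecord] = []
    if sum(class_counts) > 0:
        out_dir.mkdir(parents=True, exist_ok=True)
        if write_images:
            (out_dir / "images").mkdir(exist_ok=True)

    index = 0
    for label, count in enumerate(class_counts):
        for _ in range(count):
            pose = sample_pose(scheme, label, record_seed(global_seed, index), canvas=canvas)
            rec_id = f"rec_{index:05d}"
            rel_path = f"images/{rec_id}.png"
            if write_images:
                img = render_limb(pose, canvas, canvas)
                Image.fromarray(img, mode="L").save(out_dir / rel_path)
            angle = round(pose.flexion_angle, 3)
            records.append(
                ImageRecord(
                    id=rec_id,
                    path=rel_path,
                    pose_type=pose.pose_type,
                    angle_deg=angle,
                    label4=assign_four_class(angle, pose.pose_type),
                    label6=assign_six_class(angle),
                    split="",
                )
            )
            index += 1

    manifest = DatasetManifest(
        records=records, scheme=scheme, class_counts=class_counts, global_seed=int(global_seed)
    )
    if sum(class_counts) > 0:
        manifest.to_csv(out_dir / "manifest.csv")
    return manifest
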