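"""Pixel-to-centimetre scaling and the blood-vessel length difference.

A full-length standing image plus the measured height give a
proportionality constant ``p = height_px / height_cm`` (pixels per cm) that
absorbs the camera distance. Heart-to-face and heart-to-hand pixel
distances divided by ``p`` give centimetre distances, and their absolute
difference is the arterial path-length difference ``L`` fed to the
hemodynamic model. Because every pixel quantity scales with the camera
distance while ``p`` rescales identically, ``L`` is invariant to where the
camera stood.

The "heart" reference point is not observable from pose landmarks, so this
module fixes a documented anchor convention (see :data:`ANCHOR_TABLE`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Protocol, runtime_checkable

import numpy as np

from .errors import GeometryError, InputError

#: Anchor convention used for all pose-derived distances. Values are the
#: construction rules, applied to named pose landmarks:
#:   height  — vertical extent from head_top to the lower of the two heels
#:   heart   — shoulder midpoint displaced 1/8 of the shoulder-to-hip
#:             midline distance toward the hips (an exactly representable
#:             fraction, so the anchor arithmetic introduces no rounding)
#:   face    — eye midpoint raised by half the eye-to-eye distance
#:             (a forehead-centre proxy)
#:   hand    — the right wrist (the palm used for the video signal)
ANCHOR_TABLE: Mapping[str, str] = {
    "height": "head_top -> max(left_heel.y, right_heel.y), vertical extent",
    "heart": "midpoint(shoulders) + 0.125 * (midpoint(hips) - midpoint(shoulders))",
    "face": "midpoint(eyes) - (0, 0.5 * |left_eye - right_eye|)",
    "hand": "right_wrist",
}

HEART_DISPLACEMENT_FRACTION = 0.125

REQUIRED_POSE_POINTS = (
    "head_top",
    "left_heel",
    "right_heel",
    "left_shoulder",
    "right_shoulder",
    "left_hip",
    "right_hip",
    "left_eye",
    "right_eye",
    "right_wrist",
)

# Soft plausibility bounds; values outside are logged, not rejected.
HEIGHT_BOUNDS_CM = (68.0, 210.0)
WEIGHT_BOUNDS_KG = (30.0, 170.0)
AGE_BOUNDS_Y = (15.0, 90.0)


@dataclass
class Demographics:
    """A subject's demographic record.

    Height/weight/age must be positive; values outside the soft plausibility
    bounds raise a warning but are accepted (the model formulas remain
    evaluable).
    """

    subject_id: str
    height_cm: float
    weight_kg: float
    age_years: float
    gender: str | None = None
    country: str | None = None

    def __post_init__(self) -> None:
        for name, v in (
            ("height_cm", self.height_cm),
            ("weight_kg", self.weight_kg),
            ("age_years", self.age_years),
        ):
            if not np.isfinite(v) or v <= 0:
                raise InputError(f"{name} must be positive, got {v}")
        for name, v, (lo, hi) in (
            ("height_cm", self.height_cm, HEIGHT_BOUNDS_CM),
            ("weight_kg", self.weight_kg, WEIGHT_BOUNDS_KG),
            ("age_years", self.age_years, AGE_BOUNDS_Y),
        ):
            if not lo <= v <= hi:
                warnings.warn(
                    f"{name}={v} outside plausible range [{lo}, {hi}]",
                    stacklevel=2,
                )

    @property
    def bmi(self) -> float:
        """Body mass index, kg/m^2."""
        return self.weight_kg / (self.height_cm / 100.0) ** 2


@dataclass
class PoseLandmarks:
    """Named full-body landmarks from a full-length standing image."""

    points: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        missing = [k for k in REQUIRED_POSE_POINTS if k not in self.points]
        if missing:
            raise InputError(f"pose landmarks missing {missing}")

    def __getitem__(self, key: str) -> np.ndarray:
        return np.asarray(self.points[key], dtype=float)


@runtime_checkable
class PoseBackend(Protocol):
    def detect(self, image: np.ndarray) -> PoseLandmarks: ...


@dataclass
class FixturePoseBackend:
    """Pose provider returning a precomputed landmark set (tests/synthetic)."""

    landmarks: PoseLandmarks

    def detect(self, image) -> PoseLandmarks:
        return self.landmarks


@dataclass
class BodyGeometry:
    """Pixel and centimetre heart-to-face/heart-to-hand geometry."""

    height_px: float
    dist_face_px: float
    dist_hand_px: float
    p: float  # px per cm
    dist_face_cm: float
    dist_hand_cm: float
    length_cm: float  # |distF_cm - distH_cm|

    def to_dict(self) -> dict:
        return {
            "height_px": self.height_px,
            "p_px_per_cm": self.p,
            "dist_face_cm": self.dist_face_cm,
            "dist_hand_cm": self.dist_hand_cm,
            "L_cm": self.length_cm,
        }


def _midpoint(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a + b) / 2.0


def anchors_from_pose(pose: PoseLandmarks) -> dict[str, np.ndarray]:
    """Apply the documented anchor construction rules to pose landmarks."""
    shoulder_mid = _midpoint(pose["left_shoulder"], pose["right_shoulder"])
    hip_mid = _midpoint(pose["left_hip"], pose["right_hip"])
    heart = shoulder_mid + HEART_DISPLACEMENT_FRACTION * (hip_mid - shoulder_mid)
    eye_mid = _midpoint(pose["left_eye"], pose["right_eye"])
    eye_dist = float(np.linalg.norm(pose["left_eye"] - pose["right_eye"]))
    face = eye_mid - np.array([0.0, 0.5 * eye_dist])
    hand = pose["right_wrist"]
    return {"heart": heart, "face": face, "hand": hand}


def pose_distances(
    image: np.ndarray | None, backend: PoseBackend
) -> tuple[float, float, float]:
    """(height_px, distF_px, distH_px) from a full-length standing image.

    The backend supplies named landmarks; anchor points follow
    :data:`ANCHOR_TABLE`. Distances are straight-line pixel Euclidean
    distances — arterial tortuosity is absorbed into the proportionality
    assumption.
    """
    pose = backend.detect(image)
    heel_y = max(float(pose["left_heel"][1]), float(pose["right_heel"][1]))
    height_px = heel_y - float(pose["head_top"][1])
    if height_px <= 0:
        raise GeometryError("degenerate pose: head not above heels")
    a = anchors_from_pose(pose)
    dist_face_px = float(np.linalg.norm(a["face"] - a["heart"]))
    dist_hand_px = float(np.linalg.norm(a["hand"] - a["heart"]))
    return height_px, dist_face_px, dist_hand_px


def estimate_scale(height_px: float, height_cm: float) -> float:
    """Pixels-per-cm proportionality constant p = height_px / height_cm."""
    if height_px <= 0 or height_cm <= 0:
        raise InputError("height_px and height_cm must be positive")
    return height_px / height_cm


def vessel_length_difference(
    height_px: float,
    dist_face_px: float,
    dist_hand_px: float,
    height_cm: float,
) -> BodyGeometry:
    """Convert pixel distances to cm and take the arterial length difference.

    ``L = |distF_cm - distH_cm|`` in centimetres (the magnitude convention:
    the model needs a positive path-length difference and no sign is implied
    by which site sits further from the heart). Conversion to metres happens
    once, inside the hemodynamics module.
    """
    if dist_face_px <= 0 or dist_hand_px <= 0:
        raise InputError("pixel distances must be positive")
    p = estimate_scale(height_px, height_cm)
    dist_face_cm = dist_face_px / p
    dist_hand_cm = dist_hand_px / p
    length_cm = abs(dist_face_cm - dist_hand_cm)
    if length_cm >= height_cm:
        raise GeometryError(
            f"implausible geometry: L = {length_cm:.1f} cm exceeds the "
            f"subject height {height_cm:.1f} cm"
        )
    if length_cm == 0.0:
        warnings.warn(
            "face and hand are equidistant from the heart (L = 0); "
            "blood pressure is undefined at L = 0",
            stacklevel=2,
        )
    return BodyGeometry(
        height_px=height_px,
        dist_face_px=dist_face_px,
        dist_hand_px=dist_hand_px,
        p=p,
        dist_face_cm=dist_face_cm,
        dist_hand_cm=dist_hand_cm,
        length_cm=length_cm,
    )


def geometry_from_image(
    image: np.ndarray | None, backend: PoseBackend, demographics: Demographics
) -> BodyGeometry:
    """Convenience wrapper: image + measured height -> BodyGeometry."""
    h_px, f_px, hd_px = pose_distances(image, backend)
    return vessel_length_difference(h_px, f_px, hd_px, demographics.height_cm)
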