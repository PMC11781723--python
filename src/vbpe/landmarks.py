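"""Video frames -> per-frame forehead and palm regions of interest.

The tracker itself is pluggable: any object satisfying
:class:`LandmarkBackend` can provide per-frame face and hand landmarks.
Two providers are bundled: :class:`FixtureBackend`, a deterministic provider
used by the synthetic generators and the test-suite, and a MediaPipe adapter
(:mod:`vbpe.mediapipe_backend`) that is only importable when the optional
``mediapipe`` dependency is installed.

Pixel convention: origin at the top-left corner, x rightward, y downward,
0-based frame indexing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import InputError, VideoQualityError

#: Indices into the canonical fixture *face* landmark layout that bound the
#: forehead region (a quadrilateral above the eyebrows, clockwise from the
#: top-left corner). The canonical layout has 10 face points:
#: 0-3 forehead corners (TL, TR, BR, BL), 4-5 left/right eye, 6 nose tip,
#: 7 chin, 8-9 left/right temple.
FOREHEAD_INDICES: tuple[int, ...] = (0, 1, 2, 3)

#: Indices into the canonical fixture *hand* layout covering the palm centre.
#: The canonical layout has 6 hand points: 0-3 palm corners (TL, TR, BR, BL),
#: 4 wrist, 5 middle fingertip.
PALM_INDICES: tuple[int, ...] = (0, 1, 2, 3)

CANONICAL_FACE_POINTS = 10
CANONICAL_HAND_POINTS = 6

MIN_WIDTH = 320
MIN_HEIGHT = 240
MIN_FPS = 30.0


@dataclass
class VideoClip:
    """A decoded RGB video held in memory.

    frames: array of shape (n_frames, height, width, 3), 8-bit channels.
    fps: nominal frame rate in frames/second.
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise InputError(
                f"frames must have shape (n, h, w, 3), got {self.frames.shape}"
            )
        if self.fps <= 0:
            raise InputError("fps must be positive")

    @property
    def frame_count(self) -> int:
        return int(self.frames.shape[0])

    @property
    def height(self) -> int:
        return int(self.frames.shape[1])

    @property
    def width(self) -> int:
        return int(self.frames.shape[2])

    def validate(self, strict: bool = True) -> list[str]:
        """Check the minimum-resolution / frame-rate requirements.

        With ``strict=True`` violations raise :class:`InputError`; otherwise
        they are returned (and emitted) as warnings.
        """
        problems = []
        if self.frame_count == 0:
            raise InputError("empty video")
        if self.fps < MIN_FPS:
            problems.append(f"fps {self.fps} below minimum {MIN_FPS}")
        if self.width < MIN_WIDTH or self.height < MIN_HEIGHT:
            problems.append(
                f"resolution {self.width}x{self.height} below minimum "
                f"{MIN_WIDTH}x{MIN_HEIGHT}"
            )
        if problems and strict:
            raise InputError("; ".join(problems))
        for p in problems:
            warnings.warn(p, stacklevel=2)
        return problems


@dataclass
class LandmarkSet:
    """Face and hand landmarks for one frame."""

    frame_index: int
    face_points: np.ndarray  # (n_face, 2) pixel coordinates
    hand_points: np.ndarray  # (n_hand, 2)
    valid: bool = True

    def __post_init__(self) -> None:
        self.face_points = np.atleast_2d(np.asarray(self.face_points, dtype=float))
        self.hand_points = np.atleast_2d(np.asarray(self.hand_points, dtype=float))


@dataclass
class RoiPolygon:
    """A simple polygon delimiting one measurement site in one frame."""

    site: str  # "forehead" | "palm"
    vertices: np.ndarray  # (k, 2) ordered pixel coordinates
    frame_index: int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 3:
            raise InputError("ROI polygon needs at least 3 vertices")

    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    @property
    def area(self) -> float:
        return float(self.shapely().area)


@runtime_checkable
class LandmarkBackend(Protocol):
    """Interface any face/hand tracker must satisfy."""

    face_point_count: int
    hand_point_count: int

    def detect(self, video: VideoClip) -> Sequence[LandmarkSet]:
        """Return one LandmarkSet per frame (valid=False on tracking loss)."""
        ...

    def roi_indices(self, site: str) -> tuple[int, ...]:
        """Landmark indices bounding the ROI for ``site``."""
        ...


@dataclass
class FixtureBackend:
    """Deterministic landmark provider backed by precomputed landmark sets.

    Used for synthetic videos (where the generator knows the true landmark
    positions) and for ingesting landmark files produced by an external
    detector.
    """

    landmark_sets: Sequence[LandmarkSet]
    face_point_count: int = CANONICAL_FACE_POINTS
    hand_point_count: int = CANONICAL_HAND_POINTS
    forehead_indices: tuple[int, ...] = FOREHEAD_INDICES
    palm_indices: tuple[int, ...] = PALM_INDICES

    def detect(self, video: VideoClip) -> Sequence[LandmarkSet]:
        if len(self.landmark_sets) != video.frame_count:
            raise InputError(
                f"fixture has {len(self.landmark_sets)} landmark sets for a "
                f"{video.frame_count}-frame video"
            )
        return list(self.landmark_sets)

    def roi_indices(self, site: str) -> tuple[int, ...]:
        if site == "forehead":
            return self.forehead_indices
        if site == "palm":
            return self.palm_indices
        raise InputError(f"unknown site {site!r}")


def track_landmarks(
    video: VideoClip, backend: LandmarkBackend
) -> list[LandmarkSet]:
    """Run the landmark backend over every frame, checking its output.

    Frames where the backend reports a tracking failure come back with
    ``valid=False``; malformed output (wrong point counts, coordinates
    outside the frame) raises :class:`InputError` naming the frame.
    """
    if video.frame_count == 0:
        raise InputError("empty video")
    sets = list(backend.detect(video))
    if len(sets) != video.frame_count:
        raise InputError(
            f"backend returned {len(sets)} landmark sets for "
            f"{video.frame_count} frames"
        )
    for ls in sets:
        if not ls.valid:
            continue
        if ls.face_points.shape != (backend.face_point_count, 2):
            raise InputError(
                f"frame {ls.frame_index}: expected "
                f"{backend.face_point_count} face points, got "
                f"{ls.face_points.shape}"
            )
        if ls.hand_points.shape != (backend.hand_point_count, 2):
            raise InputError(
                f"frame {ls.frame_index}: expected "
                f"{backend.hand_point_count} hand points, got "
                f"{ls.hand_points.shape}"
            )
        pts = np.vstack([ls.face_points, ls.hand_points])
        if not np.all(np.isfinite(pts)):
            raise InputError(f"frame {ls.frame_index}: non-finite landmark")
        if (
            pts[:, 0].min() < 0
            or pts[:, 1].min() < 0
            or pts[:, 0].max() >= video.width
            or pts[:, 1].max() >= video.height
        ):
            raise InputError(
                f"frame {ls.frame_index}: landmark outside frame bounds"
            )
    return sets


def drop_invalid_frames(
    landmarks: Sequence[LandmarkSet],
    fps: float | None = None,
    max_gap_s: float = 2.0,
) -> tuple[list[int], list[int]]:
    """Partition frame indices into (kept, dropped) by tracking validity.

    Ordering is preserved and ``kept + dropped`` covers every frame exactly
    once. When ``fps`` is given, a consecutive run of invalid frames longer
    than ``max_gap_s`` raises :class:`VideoQualityError` instead of silently
    shrinking the signal; shorter gaps are simply dropped and later bridged
    by interpolation in the rPPG stage.
    """
    kept = [ls.frame_index for ls in landmarks if ls.valid]
    dropped = [ls.frame_index for ls in landmarks if not ls.valid]
    if not kept:
        raise VideoQualityError("no trackable frames")
    if fps is not None and dropped:
        run = 1
        prev = dropped[0]
        longest = 1
        for idx in dropped[1:]:
            run = run + 1 if idx == prev + 1 else 1
            longest = max(longest, run)
            prev = idx
        if longest / fps > max_gap_s:
            raise VideoQualityError(
                f"untrackable gap of {longest} frames "
                f"({longest / fps:.2f} s) exceeds {max_gap_s} s"
            )
    return kept, dropped


def construct_roi(
    landmarks: LandmarkSet,
    site: str,
    indices: tuple[int, ...] | None = None,
) -> RoiPolygon:
    """Build the ROI polygon for ``site`` from a fixed landmark subset.

    The polygon inherits the scale of the landmarks, so its area grows with
    the subject's apparent size in the frame. ``indices`` defaults to the
    canonical fixture tables (:data:`FOREHEAD_INDICES`/:data:`PALM_INDICES`);
    backends with other layouts pass their own table.
    """
    if not landmarks.valid:
        raise InputError(
            f"frame {landmarks.frame_index}: cannot build ROI from an "
            "invalid landmark set"
        )
    if site == "forehead":
        pts, idx = landmarks.face_points, indices or FOREHEAD_INDICES
    elif site == "palm":
        pts, idx = landmarks.hand_points, indices or PALM_INDICES
    else:
        raise InputError(f"unknown site {site!r}")
    if max(idx) >= pts.shape[0]:
        raise InputError(
            f"ROI index {max(idx)} out of range for {pts.shape[0]} landmarks"
        )
    vertices = pts[list(idx)]
    poly = RoiPolygon(site=site, vertices=vertices, frame_index=landmarks.frame_index)
    shp = poly.shapely()
    if shp.area <= 0.0:
        raise InputError(
            f"frame {landmarks.frame_index}: degenerate {site} polygon (zero area)"
        )
    if not shp.is_simple or not shp.is_valid:
        raise InputError(
            f"frame {landmarks.frame_index}: self-intersecting {site} polygon"
        )
    return poly
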