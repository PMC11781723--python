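"""Adapter for the MediaPipe face/hand/pose trackers (optional dependency).

The estimation pipeline only requires the :class:`vbpe.landmarks.
LandmarkBackend` protocol; this module provides it on top of MediaPipe's
face-mesh and hand solutions when the ``mediapipe`` package is installed.
The forehead/palm ROI index tables below refer to MediaPipe's own landmark
topology (468 face points, 21 hand points).
"""

from __future__ import annotations

import numpy as np

from .errors import InputError
from .landmarks import LandmarkSet, VideoClip

#: Face-mesh indices outlining the forehead above the eyebrows
#: (left temple -> hairline arc -> right temple -> brow line), and the
#: hand-landmark indices around the palm centre (wrist + MCP knuckles).
MEDIAPIPE_FOREHEAD_INDICES: tuple[int, ...] = (54, 68, 104, 69, 108, 151, 337,
                                               299, 333, 298, 284, 9)
MEDIAPIPE_PALM_INDICES: tuple[int, ...] = (0, 1, 5, 9, 13, 17)


class MediapipeBackend:
    """Face + hand landmark provider backed by MediaPipe."""

    face_point_count = 468
    hand_point_count = 21

    def __init__(self) -> None:
        try:
            import mediapipe as mp
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "MediapipeBackend requires the optional 'mediapipe' package; "
                "install it, or use FixtureBackend with precomputed landmark "
                "files from any external detector"
            ) from exc
        self._mp = mp

    def roi_indices(self, site: str) -> tuple[int, ...]:
        if site == "forehead":
            return MEDIAPIPE_FOREHEAD_INDICES
        if site == "palm":
            return MEDIAPIPE_PALM_INDICES
        raise InputError(f"unknown site {site!r}")

    def detect(self, video: VideoClip) -> list[LandmarkSet]:  # pragma: no cover
        mp = self._mp
        h, w = video.height, video.width
        out: list[LandmarkSet] = []
        with mp.solutions.face_mesh.FaceMesh(
            static_image_mode=False, max_num_faces=1
        ) as face_mesh, mp.solutions.hands.Hands(
            static_image_mode=False, max_num_hands=1
        ) as hands:
            for i, frame in enumerate(video.frames):
                frame = np.ascontiguousarray(frame)
                fres = face_mesh.process(frame)
                hres = hands.process(frame)
                ok = bool(fres.multi_face_landmarks) and bool(
                    hres.multi_hand_landmarks
                )
                if not ok:
                    out.append(
                        LandmarkSet(i, np.zeros((1, 2)), np.zeros((1, 2)),
                                    valid=False)
                    )
                    continue
                face_pts = np.array(
                    [(p.x * w, p.y * h)
                     for p in fres.multi_face_landmarks[0].landmark]
                )
                hand_pts = np.array(
                    [(p.x * w, p.y * h)
                     for p in hres.multi_hand_landmarks[0].landmark]
                )
                out.append(LandmarkSet(i, face_pts, hand_pts, valid=True))
        return out
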