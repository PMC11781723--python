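"""File input/output: videos, landmark files, pose fixtures, results."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .anthropometry import PoseLandmarks
from .errors import InputError
from .landmarks import LandmarkSet, VideoClip


def load_video(path: str | Path) -> VideoClip:
    """Read a video from .npz (frames + fps) or a standard container.

    Container decoding goes through imageio and requires a matching plugin;
    the .npz form is always available and is what `vbpe simulate` writes
    when no encoder is present.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"video not found: {path}")
    if path.suffix == ".npz":
        try:
            with np.load(path) as data:
                return VideoClip(frames=data["frames"], fps=float(data["fps"]))
        except Exception as exc:
            raise InputError(f"cannot decode video {path}: {exc}") from exc
    try:
        import imageio.v3 as iio

        frames = np.asarray(iio.imread(path, plugin="pyav"))
        meta = iio.immeta(path, plugin="pyav")
        return VideoClip(frames=frames, fps=float(meta["fps"]))
    except Exception as exc:  # pragma: no cover - depends on codec plugins
        raise InputError(f"cannot decode video {path}: {exc}") from exc


def save_video(video: VideoClip, path: str | Path) -> Path:
    """Write a video; falls back to .npz when no encoder plugin exists."""
    path = Path(path)
    if path.suffix != ".npz":
        try:  # pragma: no cover - depends on codec plugins
            import imageio.v3 as iio

            iio.imwrite(path, video.frames, plugin="pyav", fps=video.fps)
            return path
        except Exception:
            warnings.warn(
                f"no video encoder available; writing {path.stem}.npz instead",
                stacklevel=2,
            )
            path = path.with_suffix(".npz")
    np.savez_compressed(path, frames=video.frames, fps=video.fps)
    return path


def save_landmarks_jsonl(sets: list[LandmarkSet], path: str | Path) -> None:
    """One JSON object per frame: {frame, face, hand, valid}."""
    with open(path, "w") as fh:
        for ls in sets:
            fh.write(
                json.dumps(
                    {
                        "frame": ls.frame_index,
                        "face": ls.face_points.tolist(),
                        "hand": ls.hand_points.tolist(),
                        "valid": ls.valid,
                    }
                )
                + "\n"
            )


def load_landmarks_jsonl(path: str | Path) -> list[LandmarkSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            sets.append(
                LandmarkSet(
                    frame_index=int(obj["frame"]),
                    face_points=np.asarray(obj["face"], dtype=float),
                    hand_points=np.asarray(obj["hand"], dtype=float),
                    valid=bool(obj.get("valid", True)),
                )
            )
    if not sets:
        raise InputError(f"no landmark records in {path}")
    return sets


def save_pose_json(pose: PoseLandmarks, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: list(v) for k, v in pose.points.items()}, fh, indent=1)


def load_pose_json(path: str | Path) -> PoseLandmarks:
    with open(path) as fh:
        points = {k: tuple(v) for k, v in json.load(fh).items()}
    return PoseLandmarks(points=points)
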