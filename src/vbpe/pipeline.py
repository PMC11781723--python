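"""End-to-end orchestration: video + pose + demographics -> BP estimate.

The pipeline chains the stages in order — landmark tracking, frame quality
control, ROI construction, mean-RGB traces, chrominance pulse extraction,
band-pass, transit-time computation, anthropometric scaling and the
hemodynamic inversion — and embeds a config snapshot plus per-stage counts
in every result so a run is reproducible from its output alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import anthropometry as anthro
from . import hemodynamics as hemo
from . import io as vio
from . import landmarks as lm
from . import rppg, transit
from .errors import InputError, VbpeError

log = logging.getLogger("vbpe")


@dataclass
class PipelineConfig:
    """All tunables of an estimation run; defaults are the documented ones."""

    variant: str = "demographic"
    filter_order: int = rppg.DEFAULT_ORDER
    band_hz: tuple[float, float] = (rppg.DEFAULT_LOW_HZ, rppg.DEFAULT_HIGH_HZ)
    chrom_window_s: float = rppg.CHROM_WINDOW_S
    chrom_band_hz: tuple[float, float] = rppg.CHROM_BAND_HZ
    min_peak_distance_s: float = transit.MIN_EVENT_DISTANCE_S
    prominence_factor: float = transit.PROMINENCE_FACTOR
    max_lag_s: float | None = None  # None: half the median face IBI
    min_pairs: int = transit.MIN_PAIRS
    signed_ptt: bool = False
    diameter_ratio: float = 1.0
    constants: hemo.ModelConstants = field(default_factory=hemo.ModelConstants)
    strict_video: bool = True
    max_invalid_gap_s: float = 2.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["constants"] = dataclasses.asdict(self.constants)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "constants" in d and isinstance(d["constants"], dict):
            d["constants"] = hemo.ModelConstants(**d["constants"])
        for key in ("band_hz", "chrom_band_hz"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _extract_site_signal(
    video: lm.VideoClip,
    landmark_sets: list[lm.LandmarkSet],
    kept: list[int],
    site: str,
    backend: lm.LandmarkBackend,
    config: PipelineConfig,
) -> rppg.PpgSignal:
    by_index = {ls.frame_index: ls for ls in landmark_sets}
    rois = [
        lm.construct_roi(by_index[i], site, backend.roi_indices(site))
        for i in kept
    ]
    trace = rppg.mean_rgb_trace(video, rois, site=site)
    trace = rppg.uniform_trace(trace, frame_count=video.frame_count)
    pulse = rppg.chrom_extract(
        trace,
        window_s=config.chrom_window_s,
        band=config.chrom_band_hz,
        order=config.filter_order,
    )
    return rppg.bandpass(
        pulse,
        low=config.band_hz[0],
        high=config.band_hz[1],
        order=config.filter_order,
    )


def run_estimate(
    video: lm.VideoClip | str | Path,
    demographics: anthro.Demographics | dict | None = None,
    pose: anthro.PoseLandmarks | str | Path | None = None,
    config: PipelineConfig | None = None,
    backend: lm.LandmarkBackend | None = None,
    pose_backend: anthro.PoseBackend | None = None,
) -> hemo.BloodPressureEstimate:
    """Run the full estimation chain for one subject.

    ``backend`` supplies the face/hand landmarks (required; pass a
    :class:`vbpe.landmarks.FixtureBackend` for precomputed landmark files).
    The demographic variant needs ``demographics`` and a pose source
    (``pose`` landmarks/JSON path, or ``pose_backend``); the fixed variant
    needs neither.
    """
    config = config or PipelineConfig()
    if backend is None:
        raise InputError("a landmark backend is required")
    if isinstance(video, (str, Path)):
        video = vio.load_video(video)
    if isinstance(demographics, dict):
        demographics = anthro.Demographics(**demographics)
    video.validate(strict=config.strict_video)

    landmark_sets = lm.track_landmarks(video, backend)
    kept, dropped = lm.drop_invalid_frames(
        landmark_sets, fps=video.fps, max_gap_s=config.max_invalid_gap_s
    )
    log.info("frames kept=%d dropped=%d", len(kept), len(dropped))

    face = _extract_site_signal(video, landmark_sets, kept, "forehead",
                                backend, config)
    hand = _extract_site_signal(video, landmark_sets, kept, "palm",
                                backend, config)
    face.site, hand.site = "face", "hand"

    tt = transit.compute_transit_times(
        face,
        hand,
        min_distance_s=config.min_peak_distance_s,
        prominence_factor=config.prominence_factor,
        max_lag=config.max_lag_s,
        min_pairs=config.min_pairs,
        signed=config.signed_ptt,
    )
    log.info("PTT_s=%.4f s (%d pairs), PTT_d=%.4f s (%d pairs)",
             tt.ptt_s, tt.n_pairs_s, tt.ptt_d, tt.n_pairs_d)

    geometry = None
    if config.variant == "demographic":
        if demographics is None:
            raise InputError("demographic variant requires a demographics record")
        if isinstance(pose, (str, Path)):
            pose = vio.load_pose_json(pose)
        if pose is not None:
            pose_backend = anthro.FixturePoseBackend(pose)
        if pose_backend is None:
            raise InputError(
                "demographic variant requires pose landmarks or a pose backend"
            )
        geometry = anthro.geometry_from_image(None, pose_backend, demographics)
        log.info("geometry: p=%.3f px/cm, L=%.2f cm", geometry.p,
                 geometry.length_cm)

    params = hemo.build_parameters(
        config.variant,
        demo=demographics,
        geometry=geometry,
        constants=config.constants,
        diameter_ratio=config.diameter_ratio,
    )
    est = hemo.estimate_bp(tt, params)
    est.qc.update(
        {
            "frames_total": video.frame_count,
            "frames_dropped": len(dropped),
            "config": config.to_dict(),
        }
    )
    if geometry is not None:
        est.qc["geometry"] = geometry.to_dict()
    if demographics is not None:
        est.qc["subject_id"] = demographics.subject_id
    return est


def run_batch(
    manifest: str | Path | pd.DataFrame,
    config: PipelineConfig | None = None,
    out_path: str | Path | None = None,
) -> list[dict[str, Any]]:
    """Independent per-subject runs over a manifest.

    Manifest columns: ``subject_id, video, landmarks, pose, height_cm,
    weight_kg, age_years`` (+ optional ``gender, country``). Per-subject
    failures are recorded as structured error rows and the batch continues.
    Results (one JSON object per line) go to ``out_path`` when given.
    """
    config = config or PipelineConfig()
    if isinstance(manifest, (str, Path)):
        manifest = pd.read_csv(manifest)
    results: list[dict[str, Any]] = []
    if manifest.empty:
        log.warning("empty manifest: nothing to do")
    for idx, row in manifest.iterrows():
        sid = str(row.get("subject_id", f"row{idx}"))
        try:
            pose_path = row.get("pose")
            if pd.isna(pose_path):
                pose_path = None
            demo = anthro.Demographics(
                subject_id=sid,
                height_cm=float(row["height_cm"]),
                weight_kg=float(row["weight_kg"]),
                age_years=float(row["age_years"]),
                gender=None if pd.isna(row.get("gender")) else row.get("gender"),
                country=None if pd.isna(row.get("country")) else row.get("country"),
            )
            backend = lm.FixtureBackend(
                landmark_sets=vio.load_landmarks_jsonl(row["landmarks"])
            )
            est = run_estimate(
                video=row["video"],
                demographics=demo,
                pose=pose_path,
                config=config,
                backend=backend,
            )
            rec = {"subject_id": sid, "ok": True, **est.to_dict()}
        except (VbpeError, OSError, KeyError, ValueError) as exc:
            log.error("subject %s failed: %s", sid, exc)
            rec = {
                "subject_id": sid,
                "ok": False,
                "error": f"{type(exc).__name__}: {exc}",
            }
        results.append(rec)
    if out_path is not None:
        with open(out_path, "w") as fh:
            for rec in results:
                fh.write(json.dumps(rec) + "\n")
    return results
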