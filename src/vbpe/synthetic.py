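"""Synthetic inputs with known ground truth for every pipeline stage.

The study's recordings are not publicly available, so every input the
estimator consumes can be generated here instead: paired pulse waveforms
with a known transit delay, videos of pulsating skin-coloured patches with
matching landmark fixtures, full-length pose fixtures with known body
proportions, and demographic cohorts whose transit times are derived from
the model inversion — making each cohort exactly model-consistent by
construction. Every generator is a pure function of its seed and
parameters.

The pulse surrogate is a sum of two Gaussians per beat (a sharp systolic
peak plus a smaller, later dicrotic bump), repeated at lognormally jittered
beat intervals — a standard parametric stand-in for a PPG waveform. It is
not a physically based skin-reflectance model; video modulation is plainly
multiplicative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from . import hemodynamics as hemo
from .anthropometry import (
    BodyGeometry,
    Demographics,
    PoseLandmarks,
    vessel_length_difference,
)
from .errors import InputError
from .landmarks import (
    CANONICAL_FACE_POINTS,
    CANONICAL_HAND_POINTS,
    LandmarkSet,
    RoiPolygon,
    VideoClip,
)
from .rppg import PpgSignal, RgbTrace
from .transit import TransitTimes

# Pulse surrogate shape, as fractions of the beat period T:
# systolic peak at 0.18 T (sigma 0.08 T, amplitude 1) and dicrotic bump at
# 0.45 T (sigma 0.12 T, amplitude 0.35).
_SYS_OFFSET, _SYS_SIGMA, _SYS_AMP = 0.18, 0.08, 1.0
_DIC_OFFSET, _DIC_SIGMA, _DIC_AMP = 0.45, 0.12, 0.35

#: Heart-to-face and heart-to-hand straight-line distances as fractions of
#: stature (heart->forehead ~ 40 cm, heart->wrist ~ 66 cm at 158 cm), and
#: the heart's height above ground as a fraction of stature.
DEFAULT_FACE_FRACTION = 0.25
DEFAULT_HAND_FRACTION = 0.42
DEFAULT_HEART_HEIGHT_FRACTION = 0.72

#: Per-subject anatomical jitter (relative sd) on the distance fractions.
PROPORTION_JITTER_REL = 0.05

#: Demographic group statistics used by the cohort sampler:
#: (mean, sd, min, max) per country for age (y), height (cm), weight (kg),
#: SBP and DBP (mmHg), plus the female fraction per country.
COHORT_STATS = {
    "India": {
        "age": (45.0, 14.2, 17.0, 82.0),
        "height": (157.0, 9.6, 133.0, 195.0),
        "weight": (62.0, 11.7, 34.0, 101.0),
        "sbp": (118.0, 19.6, 85.0, 191.0),
        "dbp": (76.5, 13.1, 28.0, 113.0),
        "female_fraction": 144 / 200,
    },
    "SierraLeone": {
        "age": (34.6, 12.9, 17.0, 75.0),
        "height": (159.0, 19.8, 68.0, 200.0),
        "weight": (66.0, 17.5, 42.0, 160.0),
        "sbp": (125.0, 19.3, 85.0, 202.0),
        "dbp": (80.9, 13.3, 50.0, 126.0),
        "female_fraction": 141 / 200,
    },
}

MIN_PULSE_PRESSURE_MMHG = 10.0

#: Signed pulsatile amplitude per RGB channel. Systolic blood influx
#: *darkens* the skin (haemoglobin absorption), green most strongly and red
#: least, in the ~0.33 : 0.77 : 0.53 R:G:B ratio standard in
#: chrominance-based rPPG; scaled to ~1% peak modulation of green. The
#: negative sign carries the darkening convention, which also fixes the
#: polarity of the extracted pulse (systole appears as a positive peak).
PULSE_DEPTHS: tuple[float, float, float] = (-0.0043, -0.0100, -0.0069)


@dataclass
class SignalSpec:
    """Parameters of a synthetic pulse-pair / video generation run."""

    fs: float = 60.0
    duration_s: float = 120.0  # the study protocol's recording duration
    heart_rate_bpm: float = 62.0
    transit_delay_s: float = 2 / 60
    peak_delay_s: float | None = None
    valley_delay_s: float | None = None
    noise_sd: float = 0.0
    drift_amplitude: float = 0.0
    drift_hz: float = 0.05
    beat_jitter_cv: float = 0.03
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 30:
            raise InputError("fs must be >= 30 Hz")
        period = 60.0 / self.heart_rate_bpm
        for d in (self.transit_delay_s, self.peak_delay_s, self.valley_delay_s):
            if d is not None and not 0 <= d < period:
                raise InputError(f"delay {d}s must lie within one beat period")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def beat_period_s(self) -> float:
        return 60.0 / self.heart_rate_bpm


def _beat_times(spec: SignalSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered beat onset times covering the clip (plus guard beats)."""
    period = spec.beat_period_s
    cv = spec.beat_jitter_cv
    n_beats = int(math.ceil(spec.duration_s / period)) + 4
    if cv > 0:
        sigma = math.sqrt(math.log(1 + cv * cv))
        mu = math.log(period) - 0.5 * sigma * sigma
        intervals = rng.lognormal(mean=mu, sigma=sigma, size=n_beats)
    else:
        intervals = np.full(n_beats, period)
    return np.concatenate([[-period], np.cumsum(intervals) - period])


def pulse_waveform(t: np.ndarray, beats: np.ndarray, period: float,
                   amplitude: float = 1.0) -> np.ndarray:
    """Two-Gaussian pulse surrogate evaluated at times ``t`` (continuous)."""
    out = np.zeros_like(t, dtype=float)
    for b in beats:
        out += _SYS_AMP * np.exp(
            -0.5 * ((t - b - _SYS_OFFSET * period) / (_SYS_SIGMA * period)) ** 2
        )
        out += _DIC_AMP * np.exp(
            -0.5 * ((t - b - _DIC_OFFSET * period) / (_DIC_SIGMA * period)) ** 2
        )
    return amplitude * out


def _hand_waveform(t: np.ndarray, beats: np.ndarray, spec: SignalSpec) -> np.ndarray:
    """Hand-site waveform: a pure delay, or separately delayed peak/valley
    phases blended by a peak-centred weight when the two delays differ."""
    period = spec.beat_period_s
    dp = spec.peak_delay_s if spec.peak_delay_s is not None else spec.transit_delay_s
    dv = spec.valley_delay_s if spec.valley_delay_s is not None else spec.transit_delay_s
    if dp == dv:
        return pulse_waveform(t - dp, beats, period, spec.amplitude)
    peak_part = pulse_waveform(t - dp, beats, period, spec.amplitude)
    valley_part = pulse_waveform(t - dv, beats, period, spec.amplitude)
    w = np.zeros_like(t)
    for b in beats:
        w += np.exp(-0.5 * ((t - b - _SYS_OFFSET * period - dp) / (0.12 * period)) ** 2)
    w = np.clip(w, 0.0, 1.0)
    return w * peak_part + (1.0 - w) * valley_part


def generate_ppg_pair(
    spec: SignalSpec,
) -> tuple[PpgSignal, PpgSignal, np.ndarray]:
    """A (face, hand) raw pulse pair with known delay and beat times.

    The hand signal is the face waveform evaluated ``transit_delay_s``
    later (continuous evaluation, so non-integer-sample delays are exact);
    independent Gaussian noise of sd ``noise_sd`` (signal units) is added to
    each site. Returns the ground-truth beat onset times as the oracle for
    event-detection tests.
    """
    rng = np.random.default_rng(spec.seed)
    beats = _beat_times(spec, rng)
    t = np.arange(spec.n_samples) / spec.fs
    face = pulse_waveform(t, beats, spec.beat_period_s, spec.amplitude)
    hand = _hand_waveform(t, beats, spec)
    if spec.drift_amplitude:
        drift = spec.drift_amplitude * np.sin(2 * np.pi * spec.drift_hz * t)
        face = face + drift
        hand = hand + drift
    if spec.noise_sd > 0:
        face = face + rng.normal(0.0, spec.noise_sd, face.shape)
        hand = hand + rng.normal(0.0, spec.noise_sd, hand.shape)
    keep = (beats >= 0) & (beats <= spec.duration_s)
    return (
        PpgSignal(site="face", samples=face, fs=spec.fs),
        PpgSignal(site="hand", samples=hand, fs=spec.fs),
        beats[keep],
    )


def modulated_rgb_trace(
    spec: SignalSpec,
    base_tone: tuple[float, float, float] = (152.0, 110.0, 84.0),
    depths: tuple[float, float, float] = PULSE_DEPTHS,
    site: str = "face",
) -> tuple[RgbTrace, np.ndarray]:
    """A skin-tone mean-RGB trace multiplicatively modulated by the pulse.

    Per channel c: ``base_c * (1 + depth_c * z(t)) * (1 + drift(t))`` with
    ``z`` the zero-mean unit-peak pulse waveform and the drift a common
    multiplicative illumination oscillation. Returns (trace, beat_times).
    """
    rng = np.random.default_rng(spec.seed)
    beats = _beat_times(spec, rng)
    t = np.arange(spec.n_samples) / spec.fs
    s = pulse_waveform(t, beats, spec.beat_period_s)
    z = s - s.mean()
    denom = np.abs(z).max()
    if denom > 0:
        z = z / denom
    base = np.asarray(base_tone, dtype=float)
    depth = np.asarray(depths, dtype=float)
    samples = base * (1.0 + depth * z[:, None])
    if spec.drift_amplitude:
        drift = 1.0 + spec.drift_amplitude * np.sin(2 * np.pi * spec.drift_hz * t)
        samples = samples * drift[:, None]
    if spec.noise_sd > 0:
        samples = samples + rng.normal(0.0, spec.noise_sd, samples.shape)
    keep = (beats >= 0) & (beats <= spec.duration_s)
    return RgbTrace(site=site, samples=samples, fs=spec.fs), beats[keep]


@dataclass
class VideoLayout:
    """Placement and appearance of the two pulsating skin patches."""

    width: int = 320
    height: int = 240
    face_rect: tuple[int, int, int, int] = (60, 40, 140, 100)  # x0, y0, x1, y1
    hand_rect: tuple[int, int, int, int] = (200, 60, 280, 150)
    face_tone: tuple[float, float, float] = (152.0, 110.0, 84.0)
    hand_tone: tuple[float, float, float] = (152.0, 110.0, 84.0)
    depths: tuple[float, float, float] = PULSE_DEPTHS
    texture_sd: float = 2.0
    background: float = 64.0

    def __post_init__(self) -> None:
        fx0, fy0, fx1, fy1 = self.face_rect
        hx0, hy0, hx1, hy1 = self.hand_rect
        for x0, y0, x1, y1 in (self.face_rect, self.hand_rect):
            if not (0 <= x0 < x1 <= self.width and 0 <= y0 < y1 <= self.height):
                raise InputError("patch rectangle outside frame")
        if fx0 < hx1 and hx0 < fx1 and fy0 < hy1 and hy0 < fy1:
            raise InputError("face and hand patches overlap")


@dataclass
class SkinVideoResult:
    video: VideoClip
    landmark_sets: list[LandmarkSet]
    forehead_rois: list[RoiPolygon]
    palm_rois: list[RoiPolygon]
    beat_times: np.ndarray
    face_signal: np.ndarray
    hand_signal: np.ndarray


def _canonical_landmarks(layout: VideoLayout, n_frames: int) -> list[LandmarkSet]:
    """Static canonical-layout landmark fixture consistent with the patches."""
    fx0, fy0, fx1, fy1 = layout.face_rect
    hx0, hy0, hx1, hy1 = layout.hand_rect
    h, w = layout.height, layout.width
    # Forehead quad inset by 1 px so the ROI interior lies inside the patch.
    face = np.array(
        [
            (fx0 + 1, fy0 + 1), (fx1 - 1, fy0 + 1),
            (fx1 - 1, fy1 - 1), (fx0 + 1, fy1 - 1),
            (fx0 + 10, min(fy1 + 15, h - 1)),  # left eye
            (fx1 - 10, min(fy1 + 15, h - 1)),  # right eye
            ((fx0 + fx1) / 2, min(fy1 + 30, h - 1)),  # nose tip
            ((fx0 + fx1) / 2, min(fy1 + 50, h - 1)),  # chin
            (max(fx0 - 5, 0), fy1 - 1),  # left temple
            (min(fx1 + 5, w - 1), fy1 - 1),  # right temple
        ],
        dtype=float,
    )
    hand = np.array(
        [
            (hx0 + 1, hy0 + 1), (hx1 - 1, hy0 + 1),
            (hx1 - 1, hy1 - 1), (hx0 + 1, hy1 - 1),
            ((hx0 + hx1) / 2, min(hy1 + 20, h - 1)),  # wrist
            ((hx0 + hx1) / 2, max(hy0 - 20, 0)),  # middle fingertip
        ],
        dtype=float,
    )
    assert face.shape[0] == CANONICAL_FACE_POINTS
    assert hand.shape[0] == CANONICAL_HAND_POINTS
    return [
        LandmarkSet(frame_index=i, face_points=face, hand_points=hand)
        for i in range(n_frames)
    ]


def generate_skin_video(
    spec: SignalSpec, layout: VideoLayout | None = None
) -> SkinVideoResult:
    """Render a video of two pulsating skin patches with known delay.

    Each patch carries a static Gaussian texture (so spatial averaging
    recovers sub-quantisation modulation from the 8-bit frames) and is
    multiplicatively modulated by its site's pulse waveform; the hand
    waveform is the face waveform delayed by ``spec.transit_delay_s``.
    Returns the clip together with the true ROI polygons, a consistent
    landmark fixture and the generating signals.
    """
    layout = layout or VideoLayout()
    rng = np.random.default_rng(spec.seed)
    beats = _beat_times(spec, rng)
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    period = spec.beat_period_s

    def _norm(sig: np.ndarray) -> np.ndarray:
        z = sig - sig.mean()
        m = np.abs(z).max()
        return z / m if m > 0 else z

    face_sig = _norm(pulse_waveform(t, beats, period, spec.amplitude))
    hand_sig = _norm(_hand_waveform(t, beats, spec))
    if spec.noise_sd > 0:
        face_sig = face_sig + rng.normal(0.0, spec.noise_sd, n)
        hand_sig = hand_sig + rng.normal(0.0, spec.noise_sd, n)
    drift = (
        1.0 + spec.drift_amplitude * np.sin(2 * np.pi * spec.drift_hz * t)
        if spec.drift_amplitude
        else np.ones(n)
    )

    frames = np.empty((n, layout.height, layout.width, 3), dtype=np.uint8)
    frames[:] = np.uint8(layout.background)
    depth = np.asarray(layout.depths, dtype=np.float32)
    for rect, tone, sig in (
        (layout.face_rect, layout.face_tone, face_sig),
        (layout.hand_rect, layout.hand_tone, hand_sig),
    ):
        x0, y0, x1, y1 = rect
        tex = np.asarray(tone, dtype=np.float32) + rng.normal(
            0.0, layout.texture_sd, (y1 - y0, x1 - x0, 3)
        ).astype(np.float32)
        gain = (1.0 + depth * sig[:, None].astype(np.float32)) * drift[
            :, None
        ].astype(np.float32)
        patch = tex[None, :, :, :] * gain[:, None, None, :]
        frames[:, y0:y1, x0:x1] = np.clip(np.rint(patch), 0, 255).astype(np.uint8)

    video = VideoClip(frames=frames, fps=spec.fs)
    landmark_sets = _canonical_landmarks(layout, n)
    from .landmarks import construct_roi  # local import avoids cycle at top

    forehead = [construct_roi(ls, "forehead") for ls in landmark_sets]
    palm = [construct_roi(ls, "palm") for ls in landmark_sets]
    keep = (beats >= 0) & (beats <= spec.duration_s)
    return SkinVideoResult(
        video=video,
        landmark_sets=landmark_sets,
        forehead_rois=forehead,
        palm_rois=palm,
        beat_times=beats[keep],
        face_signal=face_sig,
        hand_signal=hand_sig,
    )


def generate_pose_fixture(
    height_cm: float,
    camera_scale_p: float,
    anchor_proportions: dict[str, float] | None = None,
    *,
    dist_face_cm: float | None = None,
    dist_hand_cm: float | None = None,
    origin: tuple[float, float] = (256.0, 64.0),
) -> tuple[PoseLandmarks, dict[str, float]]:
    """A full-length pose fixture with exactly known cm geometry.

    Landmarks are placed so that applying the documented anchor rules
    reproduces ``p * dist_cm`` pixel distances exactly: the heart, face
    anchor and wrist share one vertical line, and every constructed offset
    uses power-of-two fractions of the pixel height, so with integer inputs
    the arithmetic is exact. ``anchor_proportions`` gives the heart-to-face
    and heart-to-hand distances as fractions of stature (defaults 0.25 and
    0.42); explicit ``dist_face_cm``/``dist_hand_cm`` override them.
    """
    if height_cm <= 0:
        raise InputError("height_cm must be positive")
    if camera_scale_p <= 0:
        raise InputError("camera scale p must be positive")
    props = {
        "face": DEFAULT_FACE_FRACTION,
        "hand": DEFAULT_HAND_FRACTION,
        "heart_height": DEFAULT_HEART_HEIGHT_FRACTION,
    }
    if anchor_proportions:
        props.update(anchor_proportions)
    for k in ("face", "hand", "heart_height"):
        if not 0 < props[k] < 1:
            raise InputError(f"proportion {k}={props[k]} must lie in (0, 1)")
    if dist_face_cm is None:
        dist_face_cm = props["face"] * height_cm
    if dist_hand_cm is None:
        dist_hand_cm = props["hand"] * height_cm

    p = camera_scale_p
    height_px = p * height_cm
    x0, y_top = origin
    y_heel = y_top + height_px
    y_heart = y_heel - props["heart_height"] * height_px
    dist_face_px = p * dist_face_cm
    dist_hand_px = p * dist_hand_cm
    y_face = y_heart - dist_face_px
    y_wrist = y_heart + dist_hand_px

    # Power-of-two offsets keep the anchor reconstruction exact.
    e = height_px / 32.0  # eye half-distance
    y_eye = y_face + e
    delta = height_px / 16.0
    y_sh = y_heart - delta
    y_hip = y_heart + 7.0 * delta  # heart = sh + (1/8)(hip - sh)
    s_half = height_px / 8.0
    h_half = height_px / 16.0
    heel_half = height_px / 16.0

    points = {
        "head_top": (x0, y_top),
        "left_heel": (x0 - heel_half, y_heel),
        "right_heel": (x0 + heel_half, y_heel),
        "left_shoulder": (x0 - s_half, y_sh),
        "right_shoulder": (x0 + s_half, y_sh),
        "left_hip": (x0 - h_half, y_hip),
        "right_hip": (x0 + h_half, y_hip),
        "left_eye": (x0 - e, y_eye),
        "right_eye": (x0 + e, y_eye),
        "right_wrist": (x0, y_wrist),
        "left_wrist": (x0 - s_half, y_wrist),
    }
    truth = {
        "height_cm": float(height_cm),
        "p": float(p),
        "height_px": float(height_px),
        "dist_face_cm": float(dist_face_cm),
        "dist_hand_cm": float(dist_hand_cm),
        "L_cm": abs(float(dist_face_cm) - float(dist_hand_cm)),
    }
    return PoseLandmarks(points=points), truth


@dataclass
class CohortRecord:
    """One synthetic subject: demographics, geometry, truth and its PTTs.

    The transit times are derived from the true pressures by the model
    inversion under the subject's demographic-variant parameters, so
    re-estimating with those parameters reproduces the truth exactly.
    """

    demographics: Demographics
    geometry: BodyGeometry
    camera_scale_p: float
    true_sbp_mmhg: float
    true_dbp_mmhg: float
    ptt: TransitTimes
    parameters: hemo.VesselParameters


def _tnorm(rng, mean, sd, lo, hi) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_cohort(
    n: int,
    seed: int = 0,
    constants: hemo.ModelConstants | None = None,
    ptt_quantize_fs: float | None = None,
) -> list[CohortRecord]:
    """Sample a model-consistent synthetic cohort.

    Subjects are drawn from the two study countries (50/50) with per-country
    gender fractions; age, height, weight and true SBP/DBP are independent
    truncated normals parameterised by the per-country group statistics
    (:data:`COHORT_STATS`; height-weight correlation is not modelled). Body
    geometry uses the stature-fraction distances with 5% anatomical jitter
    and a uniform camera scale p in [3, 9] px/cm. Transit times come from
    the closed-form model inversion; with ``ptt_quantize_fs`` set they are
    additionally rounded to that sample grid and the true pressures
    recomputed, staying exactly model-consistent.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    constants = constants or hemo.ModelConstants()
    records = []
    countries = list(COHORT_STATS)
    for i in range(n):
        country = countries[int(rng.integers(len(countries)))]
        stats = COHORT_STATS[country]
        gender = "F" if rng.random() < stats["female_fraction"] else "M"
        age = _tnorm(rng, *stats["age"])
        height = _tnorm(rng, *stats["height"])
        weight = _tnorm(rng, *stats["weight"])
        sbp = _tnorm(rng, *stats["sbp"])
        dbp = _tnorm(rng, *stats["dbp"])
        for _ in range(100):
            if dbp <= sbp - MIN_PULSE_PRESSURE_MMHG:
                break
            dbp = _tnorm(rng, *stats["dbp"])
        else:
            dbp = sbp - MIN_PULSE_PRESSURE_MMHG
        demo = Demographics(
            subject_id=f"S{i:04d}",
            height_cm=height,
            weight_kg=weight,
            age_years=age,
            gender=gender,
            country=country,
        )
        face_frac = DEFAULT_FACE_FRACTION * (
            1.0 + PROPORTION_JITTER_REL * rng.standard_normal()
        )
        hand_frac = DEFAULT_HAND_FRACTION * (
            1.0 + PROPORTION_JITTER_REL * rng.standard_normal()
        )
        p = float(rng.uniform(3.0, 9.0))
        geometry = vessel_length_difference(
            height_px=p * height,
            dist_face_px=p * face_frac * height,
            dist_hand_px=p * hand_frac * height,
            height_cm=height,
        )
        params = hemo.build_parameters(
            "demographic", demo=demo, geometry=geometry, constants=constants
        )
        ptt_s = hemo.invert_ptt(sbp, params, "systolic")
        ptt_d = hemo.invert_ptt(dbp, params, "diastolic")
        if ptt_quantize_fs is not None:
            fs = ptt_quantize_fs
            ptt_s = max(1.0, round(ptt_s * fs)) / fs
            ptt_d = max(1.0, round(ptt_d * fs)) / fs
        ptt = TransitTimes(ptt_s=ptt_s, ptt_d=ptt_d, n_pairs_s=0, n_pairs_d=0)
        est = hemo.estimate_bp(ptt, params)
        records.append(
            CohortRecord(
                demographics=demo,
                geometry=geometry,
                camera_scale_p=p,
                true_sbp_mmhg=est.sbp_mmhg,
                true_dbp_mmhg=est.dbp_mmhg,
                ptt=ptt,
                parameters=params,
            )
        )
    return records


def cohort_estimates(records: list[CohortRecord], variant: str):
    """Estimate BP for every cohort record under the given variant.

    Returns a pandas DataFrame with subject labels, the truth and the
    variant's SBP/DBP estimates (the demographic variant reproduces the
    truth exactly by construction; the fixed variant diverges whenever a
    subject's geometry differs from the literature constants).
    """
    import pandas as pd

    rows = []
    for r in records:
        if variant == "demographic":
            params = r.parameters
        else:
            params = hemo.build_parameters(
                variant, constants=r.parameters.constants
            )
        est = hemo.estimate_bp(r.ptt, params)
        rows.append(
            {
                "subject_id": r.demographics.subject_id,
                "country": r.demographics.country,
                "gender": r.demographics.gender,
                "true_sbp": r.true_sbp_mmhg,
                "true_dbp": r.true_dbp_mmhg,
                "sbp": est.sbp_mmhg,
                "dbp": est.dbp_mmhg,
                "variant": variant,
            }
        )
    return pd.DataFrame(rows)
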