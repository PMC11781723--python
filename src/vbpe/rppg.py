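"""ROI pixels -> conditioned pulse waveforms.

Three stages: spatial averaging of the ROI pixels into a mean-RGB trace,
chrominance-based pulse extraction (projection of band-limited normalised
RGB onto two chrominance axes with an adaptive combination, overlap-added
over Hann windows), and a zero-phase Butterworth band-pass. Zero-phase
filtering matters here because the downstream quantity is a *timing*
measurement: a causal filter's group delay would bias peak positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig
from skimage.draw import polygon as _fill_polygon

from .errors import InputError
from .landmarks import RoiPolygon, VideoClip

DEFAULT_LOW_HZ = 0.25
DEFAULT_HIGH_HZ = 15.0
DEFAULT_ORDER = 4

#: CHROM sliding-window length (s) and the band used inside each window for
#: the chrominance components and the adaptive std ratio. The band spans the
#: heart-rate fundamentals plus a few harmonics: narrower bands (e.g. a
#: 0.5-4 Hz pulse band) noticeably distort the broad diastolic trough and
#: bias valley timing, which the transit-time stage depends on.
CHROM_WINDOW_S = 1.6
CHROM_BAND_HZ = (0.4, 6.0)


@dataclass
class RgbTrace:
    """Per-frame mean RGB of one site's ROI, on a uniform time grid."""

    site: str
    samples: np.ndarray  # (n, 3) channel means, each in [0, 255]
    fs: float
    frame_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise InputError("RgbTrace samples must have shape (n, 3)")
        if self.fs <= 0:
            raise InputError("fs must be positive")

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass
class PpgSignal:
    """A pulse waveform in arbitrary units on a uniform grid."""

    site: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InputError("fs must be positive")

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.samples]),
            delimiter=",",
            header="time_s,value",
            comments="",
        )


def roi_mask(roi: RoiPolygon, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the pixels inside an ROI polygon."""
    rr, cc = _fill_polygon(roi.vertices[:, 1], roi.vertices[:, 0], shape)
    return rr, cc


def mean_rgb_trace(
    video: VideoClip,
    rois: list[RoiPolygon],
    site: str | None = None,
) -> RgbTrace:
    """Average the pixels inside each frame's ROI into a (n, 3) trace.

    ``rois[i]`` must reference a valid frame of ``video`` via its
    ``frame_index``; the output carries those frame indices so that dropped
    frames can be bridged by :func:`uniform_trace` before filtering.
    """
    if not rois:
        raise InputError("no ROIs given")
    site = site or rois[0].site
    shape = (video.height, video.width)
    samples = np.empty((len(rois), 3), dtype=float)
    frame_indices = np.empty(len(rois), dtype=int)
    cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}
    for i, roi in enumerate(rois):
        if roi.frame_index < 0 or roi.frame_index >= video.frame_count:
            raise InputError(f"ROI frame index {roi.frame_index} out of range")
        key = roi.vertices.tobytes()
        if key not in cache:
            cache[key] = roi_mask(roi, shape)
        rr, cc = cache[key]
        if rr.size == 0:
            raise InputError(
                f"frame {roi.frame_index}: ROI encloses no interior pixels"
            )
        samples[i] = video.frames[roi.frame_index][rr, cc].mean(axis=0)
        frame_indices[i] = roi.frame_index
    return RgbTrace(site=site, samples=samples, fs=video.fps,
                    frame_indices=frame_indices)


def uniform_trace(trace: RgbTrace, frame_count: int | None = None) -> RgbTrace:
    """Linearly interpolate a trace with dropped frames onto a uniform grid.

    The grid runs at the nominal fps over ``0..frame_count-1`` so that sample
    spacing stays tied to the video clock even when frames were removed.
    """
    if trace.frame_indices is None:
        return trace
    idx = np.asarray(trace.frame_indices)
    n = frame_count if frame_count is not None else int(idx[-1]) + 1
    grid = np.arange(n)
    if idx.size == n and np.array_equal(idx, grid):
        return RgbTrace(trace.site, trace.samples, trace.fs, grid)
    filled = np.column_stack(
        [np.interp(grid, idx, trace.samples[:, c]) for c in range(3)]
    )
    return RgbTrace(trace.site, filled, trace.fs, grid)


def _butter_sos(low: float, high: float, fs: float, order: int):
    return _sig.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def _zero_phase(sos, x: np.ndarray) -> np.ndarray:
    return _sig.sosfiltfilt(sos, x, axis=0)


def bandpass(
    sig: PpgSignal,
    low: float = DEFAULT_LOW_HZ,
    high: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
) -> PpgSignal:
    """Zero-phase Butterworth band-pass (default 0.25-15 Hz, order 4).

    Applied forward-backward so no group delay biases event timing. When the
    requested high cut-off touches Nyquist at the minimum supported frame
    rate (15 Hz is exactly Nyquist at 30 fps), it is clipped to 0.45*fs with
    a warning; at higher rates an out-of-range cut-off is an error.
    """
    fs = sig.fs
    if not 0 < low < high:
        raise InputError("need 0 < low < high")
    if high >= fs / 2:
        if fs < 30.01:
            clipped = 0.45 * fs
            warnings.warn(
                f"high cut-off {high} Hz >= Nyquist at fs={fs}; clipping to "
                f"{clipped:.2f} Hz",
                stacklevel=2,
            )
            high = clipped
        else:
            raise InputError(
                f"high cut-off {high} Hz must be below Nyquist ({fs / 2} Hz); "
                "lower the cut-off or raise the frame rate"
            )
    sos = _butter_sos(low, high, fs, order)
    y = _zero_phase(sos, np.asarray(sig.samples, dtype=float))
    y = y - y.mean()
    return PpgSignal(site=sig.site, samples=y, fs=fs)


def chrom_extract(
    trace: RgbTrace,
    window_s: float = CHROM_WINDOW_S,
    band: tuple[float, float] = CHROM_BAND_HZ,
    order: int = DEFAULT_ORDER,
) -> PpgSignal:
    """Chrominance-based pulse extraction from a mean-RGB trace.

    Per sliding window (``window_s`` long, 50% overlap, Hann weighted):
    channels are normalised by their window mean, projected onto the two
    chrominance axes ``X = 3R - 2G`` and ``Y = 1.5R + G - 1.5B``, each
    band-limited (zero-phase Butterworth over ``band``), and combined as
    ``S = X_f - (sigma_X/sigma_Y) * Y_f``. Windows are overlap-added. The
    normalisation makes the output exactly invariant to a common positive
    gain on all three channels; the two-axis combination suppresses
    common-mode intensity changes (illumination, motion shading).

    A constant (zero-variance) trace yields an all-zero signal with a
    warning rather than an error.
    """
    x = np.asarray(trace.samples, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise InputError("trace too short for pulse extraction")
    if np.allclose(x.std(axis=0), 0.0):
        warnings.warn(
            "no pulsatile component: constant RGB trace", stacklevel=2
        )
        return PpgSignal(site=trace.site, samples=np.zeros(n), fs=trace.fs)

    fs = trace.fs
    win = int(round(window_s * fs))
    win = max(4, min(win - win % 2, n))  # even, at most the trace length
    hop = win // 2
    sos = _butter_sos(band[0], min(band[1], 0.49 * fs), fs, order)

    out = np.zeros(n)
    weight = np.zeros(n)
    hann = np.hanning(win)
    starts = list(range(0, n - win + 1, hop))
    if starts[-1] + win < n:
        starts.append(n - win)
    for s in starts:
        seg = x[s : s + win]
        mu = seg.mean(axis=0)
        if np.any(mu <= 0):
            continue
        rn, gn, bn = (seg / mu).T
        xs = 3.0 * rn - 2.0 * gn
        ys = 1.5 * rn + gn - 1.5 * bn
        xf = _zero_phase(sos, xs)
        yf = _zero_phase(sos, ys)
        sy = yf.std()
        alpha = xf.std() / sy if sy > 0 else 1.0
        out[s : s + win] += hann * (xf - alpha * yf)
        weight[s : s + win] += hann
    nz = weight > 1e-12
    out[nz] /= weight[nz]
    out -= out.mean()
    return PpgSignal(site=trace.site, samples=out, fs=fs)
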