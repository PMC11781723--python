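"""Event detection and pulse-transit-time computation.

Peaks of the two site signals give the systolic transit time, valleys
(peaks of the negated signal) the diastolic one. Events are paired greedily
by temporal proximity within a lag window, and the transit time is the mean
absolute paired time difference: the model downstream needs a positive
delay matched with a positive path-length difference, and no site is
assumed to lead. Signed averaging with a fixed face-minus-hand order is
available behind ``signed=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import InputError, SignalQualityError
from .rppg import PpgSignal

#: Minimum inter-event spacing (s); caps detectable heart rate at 150 bpm.
MIN_EVENT_DISTANCE_S = 0.4
#: Required peak prominence as a fraction of the signal standard deviation.
PROMINENCE_FACTOR = 0.3
MIN_EVENTS = 5
MIN_PAIRS = 5


@dataclass
class PeakTrain:
    site: str
    kind: str  # "peak" | "valley"
    indices: np.ndarray  # sample positions, strictly increasing
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if np.any(np.diff(self.indices) <= 0):
            raise InputError("event indices must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.fs

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class EventPairs:
    pairs: np.ndarray  # (m, 2): (t_face, t_hand) seconds
    unmatched_face: int
    unmatched_hand: int

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return self.pairs.shape[0]


@dataclass
class TransitTimes:
    """Mean systolic (peak-peak) and diastolic (valley-valley) delays."""

    ptt_s: float
    ptt_d: float
    n_pairs_s: int
    n_pairs_d: int


def detect_events(
    signal: PpgSignal,
    kind: str = "peak",
    min_distance_s: float = MIN_EVENT_DISTANCE_S,
    prominence_factor: float = PROMINENCE_FACTOR,
    min_events: int = MIN_EVENTS,
) -> PeakTrain:
    """Locate peaks (or valleys, via the negated signal) in a pulse signal.

    Local maxima must clear a prominence of ``prominence_factor`` times the
    signal standard deviation and be at least ``min_distance_s`` apart.
    """
    if kind not in ("peak", "valley"):
        raise InputError(f"unknown event kind {kind!r}")
    x = np.asarray(signal.samples, dtype=float)
    if kind == "valley":
        x = -x
    sd = x.std()
    if sd == 0:
        raise SignalQualityError("signal too short/noisy: zero variance")
    distance = max(1, int(round(min_distance_s * signal.fs)))
    idx, _ = find_peaks(x, distance=distance, prominence=prominence_factor * sd)
    if idx.size < min_events:
        raise SignalQualityError(
            f"signal too short/noisy: only {idx.size} {kind}s found "
            f"(need >= {min_events})"
        )
    return PeakTrain(site=signal.site, kind=kind, indices=idx, fs=signal.fs)


def pair_events(
    face: PeakTrain, hand: PeakTrain, max_lag: float | None = None
) -> EventPairs:
    """Greedy nearest-neighbour matching of corresponding cardiac events.

    Candidate pairs within ``max_lag`` seconds are accepted in order of
    increasing absolute gap (ties broken toward the earlier hand event),
    each event used at most once. ``max_lag`` defaults to half the median
    inter-beat interval of the face train, which prevents cross-beat
    mispairing.
    """
    if len(face) == 0 or len(hand) == 0:
        raise InputError("cannot pair events: empty event train")
    if face.kind != hand.kind:
        raise InputError("event trains must be of the same kind")
    if max_lag is None:
        if len(face) < 2:
            raise InputError("need >= 2 face events to infer max_lag")
        max_lag = 0.5 * float(np.median(np.diff(face.times)))
    tf, th = face.times, hand.times
    candidates = []
    for i, t in enumerate(tf):
        lo = np.searchsorted(th, t - max_lag)
        hi = np.searchsorted(th, t + max_lag, side="right")
        for j in range(lo, hi):
            candidates.append((abs(t - th[j]), th[j], i, j))
    candidates.sort()
    used_f: set[int] = set()
    used_h: set[int] = set()
    pairs = []
    for _, _, i, j in candidates:
        if i in used_f or j in used_h:
            continue
        used_f.add(i)
        used_h.add(j)
        pairs.append((tf[i], th[j]))
    pairs_arr = np.array(sorted(pairs), dtype=float).reshape(-1, 2)
    return EventPairs(
        pairs=pairs_arr,
        unmatched_face=len(tf) - len(pairs),
        unmatched_hand=len(th) - len(pairs),
    )


def mean_transit_time(
    pairs: EventPairs, min_pairs: int = MIN_PAIRS, signed: bool = False
) -> float:
    """Mean transit time over paired events.

    Default is the mean absolute face-hand difference; ``signed=True`` gives
    the mean of (t_hand - t_face) with the site order fixed.
    """
    if len(pairs) < min_pairs:
        raise SignalQualityError(
            f"only {len(pairs)} event pairs (need >= {min_pairs})"
        )
    diff = pairs.pairs[:, 1] - pairs.pairs[:, 0]
    return float(np.mean(diff)) if signed else float(np.mean(np.abs(diff)))


def compute_transit_times(
    face: PpgSignal,
    hand: PpgSignal,
    min_distance_s: float = MIN_EVENT_DISTANCE_S,
    prominence_factor: float = PROMINENCE_FACTOR,
    max_lag: float | None = None,
    min_pairs: int = MIN_PAIRS,
    signed: bool = False,
) -> TransitTimes:
    """Full transit-time computation for a conditioned signal pair."""
    if face.fs != hand.fs:
        raise InputError("face and hand signals must share a sampling rate")
    results = {}
    counts = {}
    for kind in ("peak", "valley"):
        ef = detect_events(face, kind, min_distance_s, prominence_factor)
        eh = detect_events(hand, kind, min_distance_s, prominence_factor)
        p = pair_events(ef, eh, max_lag)
        results[kind] = mean_transit_time(p, min_pairs, signed)
        counts[kind] = len(p)
    tt = TransitTimes(
        ptt_s=results["peak"],
        ptt_d=results["valley"],
        n_pairs_s=counts["peak"],
        n_pairs_d=counts["valley"],
    )
    if tt.ptt_s == 0.0 or tt.ptt_d == 0.0:
        warnings.warn(
            "zero transit time: blood pressure is undefined at PTT = 0",
            stacklevel=2,
        )
    return tt
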