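"""PPG preprocessing: bandpass filtering, beat detection and segmentation.

The processing chain mirrors standard pulse-wave analysis practice:

1. zero-phase 5th-order Butterworth bandpass (0.4--12 Hz) to remove
   baseline wander and high-frequency noise,
2. beat detection at the steepest ascent of the filtered signal (local
   maxima of the first difference, adaptive threshold + refractory period),
3. segmentation of each beat between the signal minima found on either
   side of the detection point,
4. per-beat linear detrending and amplitude normalization to [0, 1].
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, detrend, find_peaks, sosfiltfilt

logger = logging.getLogger(__name__)

__all__ = [
    "PPGSignal",
    "Beat",
    "QualityError",
    "bandpass_filter",
    "detect_beats",
    "segment_beats",
    "detrend_normalize",
    "detrend_normalize_array",
    "assign_response_bp",
]


class QualityError(ValueError):
    """Raised when a beat fails a signal-quality precondition."""


@dataclass
class PPGSignal:
    """A continuous PPG recording with optional blood-pressure reference.

    ``bp_reference`` is an (n, 2) array of (time_s, mmHg) rows; a single
    row represents a one-off cuff reading valid for the whole record.
    """

    samples: np.ndarray
    fs: float
    subject: str = "unknown"
    source: str = "unknown"
    record: str = "rec0"
    bp_reference: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("empty signal")
        if self.bp_reference is not None:
            ref = np.atleast_2d(np.asarray(self.bp_reference, dtype=float))
            if ref.shape[1] != 2:
                raise ValueError("bp_reference must be (n, 2) of (time_s, mmHg)")
            span = self.samples.size / self.fs
            if ref.shape[0] > 1 and (ref[:, 0].min() < -1e-9 or ref[:, 0].max() > span + 1e-9):
                raise ValueError("bp_reference timestamps outside signal span")
            self.bp_reference = ref

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class Beat:
    """One segmented PPG pulse.

    ``onset_index``/``offset_index``/``detection_index`` are sample indices
    into the parent signal; ``samples`` is the contiguous slice between
    onset and offset (inclusive).
    """

    samples: np.ndarray
    fs: float
    detection_index: int
    onset_index: int
    offset_index: int
    subject: str = "unknown"
    source: str = "unknown"
    record: str = "rec0"
    time_index: int = 0
    response_bp: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not (self.onset_index < self.detection_index < self.offset_index):
            raise ValueError(
                "beat indices must satisfy onset < detection < offset, got "
                f"{self.onset_index}, {self.detection_index}, {self.offset_index}"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


def bandpass_filter(
    signal: PPGSignal, low_hz: float = 0.4, high_hz: float = 12.0, order: int = 5
) -> PPGSignal:
    """Zero-phase Butterworth bandpass (default 5th order, 0.4--12 Hz).

    Applied forward-backward (``sosfiltfilt``) so beat landmarks keep their
    timing.  Requires the passband to lie below Nyquist, i.e.
    ``fs > 2 * high_hz``.
    """
    if signal.fs <= 2.0 * high_hz:
        raise ValueError(
            f"sampling frequency {signal.fs} Hz too low for a {high_hz} Hz passband; "
            f"need fs > {2.0 * high_hz} Hz"
        )
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=signal.fs, output="sos")
    filtered = sosfiltfilt(sos, signal.samples)
    return PPGSignal(
        samples=filtered,
        fs=signal.fs,
        subject=signal.subject,
        source=signal.source,
        record=signal.record,
        bp_reference=signal.bp_reference,
        meta=dict(signal.meta),
    )


def detect_beats(
    signal: PPGSignal,
    refractory_s: float = 0.5,
    threshold_fraction: float = 0.3,
    history: int = 10,
) -> np.ndarray:
    """Detect beats at the steepest ascent of the (filtered) signal.

    Candidate detections are local maxima of the first difference spaced at
    least ``refractory_s`` apart; each is accepted when its slope exceeds
    ``threshold_fraction`` times the running median of the last ``history``
    accepted slope maxima (seeded with the 90th percentile of all candidate
    slopes, which rejects spurious low-slope maxima in flat segments).

    Returns strictly increasing sample indices, one per detected beat.
    """
    min_duration = 2.0
    if signal.duration < min_duration:
        logger.warning(
            "signal of %.2f s shorter than %.1f s minimum; no beats detected",
            signal.duration,
            min_duration,
        )
        return np.array([], dtype=int)
    slope = np.diff(signal.samples)
    if np.ptp(slope) == 0:
        return np.array([], dtype=int)
    distance = max(1, int(round(refractory_s * signal.fs)))
    candidates, _ = find_peaks(slope, distance=distance, height=0.0)
    if candidates.size == 0:
        return np.array([], dtype=int)
    heights = slope[candidates]
    global_ref = float(np.percentile(heights, 90))
    recent: deque[float] = deque(maxlen=history)
    accepted: list[int] = []
    for idx, h in zip(candidates, heights):
        ref = float(np.median(recent)) if recent else global_ref
        if h >= threshold_fraction * ref:
            accepted.append(int(idx))
            recent.append(float(h))
    return np.asarray(accepted, dtype=int)


def segment_beats(
    signal: PPGSignal,
    detections: np.ndarray,
    window_fraction: float = 1.0,
    max_window_s: float | None = None,
) -> tuple[list[Beat], int]:
    """Cut single beats between the minima around each detection point.

    For each detection the onset is the argmin of the samples in the
    pre-detection search window and the offset the argmin in the
    post-detection window.  Windows span ``window_fraction`` of the
    interval to the neighbouring detection (optionally capped at
    ``max_window_s``), so with the default full-interval window the
    boundaries are the true inter-beat minima.  The first and last
    detections have no neighbour on one side and are dropped, as are
    degenerate beats (onset >= offset).

    Returns ``(beats, n_dropped)``.
    """
    detections = np.asarray(detections, dtype=int)
    if detections.size and (
        detections.min() < 0 or detections.max() >= signal.samples.size
    ):
        raise ValueError("detections out of signal range")
    beats: list[Beat] = []
    dropped = 0
    x = signal.samples
    for k, d in enumerate(detections):
        if k == 0 or k == detections.size - 1:
            dropped += 1
            continue
        w_pre = window_fraction * (d - detections[k - 1]) / signal.fs
        w_post = window_fraction * (detections[k + 1] - d) / signal.fs
        if max_window_s is not None:
            w_pre = min(w_pre, max_window_s)
            w_post = min(w_post, max_window_s)
        lo = d - int(round(w_pre * signal.fs))
        hi = d + int(round(w_post * signal.fs))
        if lo < 0 or hi >= x.size:
            dropped += 1
            continue
        onset = lo + int(np.argmin(x[lo : d + 1]))
        offset = d + int(np.argmin(x[d : hi + 1]))
        if not onset < d < offset:
            dropped += 1
            logger.debug("degenerate beat at detection %d dropped", d)
            continue
        beats.append(
            Beat(
                samples=x[onset : offset + 1].copy(),
                fs=signal.fs,
                detection_index=int(d),
                onset_index=onset,
                offset_index=offset,
                subject=signal.subject,
                source=signal.source,
                record=signal.record,
                time_index=len(beats),
            )
        )
    if dropped:
        logger.info("segmentation dropped %d of %d detections", dropped, detections.size)
    return beats, dropped


def detrend_normalize_array(
    samples: np.ndarray, mode: str = "baseline", edge: int = 3
) -> np.ndarray:
    """Detrend a beat waveform and rescale it to [0, 1].

    ``baseline`` mode (default) subtracts the secant line through the
    means of the first and last ``edge`` samples — the diastolic baseline
    spanned by the beat's boundary minima.  This removes within-beat
    drift without tilting the pulse itself: a least-squares line over a
    whole pulse has a substantial slope driven by the pulse's asymmetry,
    and subtracting it pushes every beat out of the kernel model class.
    ``least_squares`` mode applies the classic full-beat regression
    detrend instead.

    Raises :class:`QualityError` when the result is constant.
    """
    y = np.asarray(samples, dtype=float)
    if y.size < 3:
        raise QualityError("beat too short to detrend")
    if mode == "least_squares":
        y = detrend(y, type="linear")
    elif mode == "baseline":
        e = min(edge, y.size // 2)
        left = float(y[:e].mean())
        right = float(y[-e:].mean())
        t0 = (e - 1) / 2.0
        t1 = y.size - 1 - (e - 1) / 2.0
        slope = (right - left) / (t1 - t0)
        y = y - (left + slope * (np.arange(y.size) - t0))
    else:
        raise ValueError(f"unknown detrend mode {mode!r}")
    rng = float(np.ptp(y))
    if rng < 1e-12:
        raise QualityError("constant beat after detrending")
    return (y - y.min()) / rng


def detrend_normalize(beat: Beat, mode: str = "baseline", edge: int = 3) -> Beat:
    """Remove the within-beat linear trend and rescale to [0, 1].

    See :func:`detrend_normalize_array` for the two trend definitions.
    The operation is idempotent and raises :class:`QualityError` for
    beats that are constant after detrending.
    """
    y = detrend_normalize_array(beat.samples, mode=mode, edge=edge)
    return Beat(
        samples=y,
        fs=beat.fs,
        detection_index=beat.detection_index,
        onset_index=beat.onset_index,
        offset_index=beat.offset_index,
        subject=beat.subject,
        source=beat.source,
        record=beat.record,
        time_index=beat.time_index,
        response_bp=beat.response_bp,
        meta=dict(beat.meta),
    )


def assign_response_bp(beats: list[Beat], signal: PPGSignal) -> list[Beat]:
    """Attach a reference BP value to each beat.

    Continuous references: nearest reference sample in time to the beat's
    detection point.  Single cuff reading (one reference row): that value
    for every beat of the record.
    """
    ref = signal.bp_reference
    if ref is None:
        return beats
    if ref.shape[0] == 1:
        for b in beats:
            b.response_bp = float(ref[0, 1])
        return beats
    times = ref[:, 0]
    for b in beats:
        t = b.detection_index / signal.fs
        b.response_bp = float(ref[np.argmin(np.abs(times - t)), 1])
    return beats
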