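"""Beat-level feature extraction: the 15-feature morphology set.

Four feature families are computed per beat:

* pulse-wave-decomposition (PWD) features P1, P2, T1, T2, W1, W2 — peak
  amplitudes, modes and FWHM widths of the two fitted kernels;
* the second-derivative ratio b/a, taken from the fitted reconstruction
  (the fit acts as a denoiser, which matters because differentiating
  amplifies noise);
* statistical features SD, kurtosis, skewness (population 1/N moments;
  kurtosis is non-excess, i.e. a Gaussian gives 3) and the pulse width PW
  at half maximum, also from the reconstruction;
* frequency features Freq0..Freq3 — the fundamental and first three
  harmonic peak frequencies of the beat tiled ten times, from the
  *original* (normalized, unfitted) beat.

Missing sub-features are reported as NaN with an explicit missing list,
never as silent zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .decomposition import DecompositionResult, kernel_landmarks

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "statistical_features",
    "b_over_a",
    "frequency_features",
    "pulse_width",
    "extract_all",
]

FEATURE_NAMES = [
    "P1",
    "P2",
    "T1",
    "T2",
    "W1",
    "W2",
    "b_over_a",
    "SD",
    "kurt",
    "skew",
    "PW",
    "Freq0",
    "Freq1",
    "Freq2",
    "Freq3",
]


@dataclass
class FeatureVector:
    """The 15 named features of one beat plus per-feature missing flags."""

    values: dict[str, float]
    missing: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")
        absent = [n for n in FEATURE_NAMES if n not in self.values]
        if absent:
            raise ValueError(f"absent features: {absent}")
        for name in FEATURE_NAMES:
            if not np.isfinite(self.values[name]) and name not in self.missing:
                self.missing.append(name)

    @property
    def complete(self) -> bool:
        return not self.missing

    def as_dict(self) -> dict[str, float]:
        return {n: self.values[n] for n in FEATURE_NAMES}


def statistical_features(samples: np.ndarray, fs: float) -> tuple[float, float, float, float]:
    """(SD, kurt, skew, PW) of one beat waveform.

    Moments use the population (1/N) convention; kurtosis is non-excess.
    PW is the width of the waveform at half its maximum amplitude, in
    seconds (linear interpolation between samples).  A zero-variance
    series yields NaN kurtosis/skewness.
    """
    y = np.asarray(samples, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    m = y.mean()
    d = y - m
    m2 = np.mean(d**2)
    sd = math.sqrt(m2)
    if m2 < 1e-300:
        return 0.0, float("nan"), float("nan"), float("nan")
    kurt = float(np.mean(d**4) / m2**2)
    skew = float(np.mean(d**3) / m2**1.5)
    return sd, kurt, skew, pulse_width(y, fs)


def pulse_width(samples: np.ndarray, fs: float) -> float:
    """Width of the waveform at 50% of its maximum amplitude, in seconds.

    Measured from the first up-crossing to the last down-crossing of the
    half-maximum level (relative to the waveform minimum), with linear
    interpolation between samples.
    """
    y = np.asarray(samples, dtype=float)
    lo, hi = float(y.min()), float(y.max())
    if hi - lo < 1e-300:
        return float("nan")
    half = lo + 0.5 * (hi - lo)
    above = y >= half
    if not above.any():
        return float("nan")
    idx = np.nonzero(above)[0]
    first, last = int(idx[0]), int(idx[-1])
    t_left = float(first)
    if first > 0:
        t_left = first - 1 + (half - y[first - 1]) / (y[first] - y[first - 1])
    t_right = float(last)
    if last < y.size - 1:
        t_right = last + (y[last] - half) / (y[last] - y[last + 1])
    return (t_right - t_left) / fs


def b_over_a(
    reconstruction: np.ndarray, fs: float, prominence_fraction: float = 0.02
) -> float:
    """Second-derivative amplitude ratio b/a of a (smooth) beat waveform.

    The second derivative is the second difference scaled by ``fs**2``.
    The a wave is the first prominent maximum of the second derivative on
    the systolic rising edge (between beat onset and the waveform's global
    maximum); the b wave is the first minimum after it.  Typically
    negative.  Returns NaN when no a/b pair is found.
    """
    y = np.asarray(reconstruction, dtype=float)
    if y.size < 5:
        return float("nan")
    d2 = np.diff(y, n=2) * fs**2
    if np.ptp(d2) == 0:
        return float("nan")
    imax = int(np.argmax(y))
    # d2[j] estimates y'' at sample j+1; rising edge covers samples <= imax
    edge_end = max(imax, 2)  # d2 index bound, exclusive
    prom = prominence_fraction * float(np.ptp(d2))
    peaks, _ = find_peaks(d2[:edge_end], prominence=prom)
    if peaks.size == 0:
        return float("nan")
    a_idx = int(peaks[0])
    a_val = float(d2[a_idx])
    valleys, _ = find_peaks(-d2[a_idx + 1 :], prominence=prom)
    if valleys.size == 0:
        return float("nan")
    b_val = float(d2[a_idx + 1 + int(valleys[0])])
    if a_val == 0:
        return float("nan")
    return b_val / a_val


def frequency_features(
    original_beat: np.ndarray,
    fs: float,
    n_copies: int = 10,
    search_halfwidth: float = 0.5,
) -> tuple[float, float, float, float]:
    """Fundamental and harmonic peak frequencies of the tiled beat, in Hz.

    The beat is tiled ``n_copies`` times, making it exactly periodic with
    period equal to the beat duration; the magnitude spectrum of the tiled
    signal then concentrates at multiples of the fundamental.  Freq0 is the
    frequency of the largest non-DC spectral peak; Freq1..Freq3 are the
    local spectral maxima nearest 2, 3 and 4 times Freq0, accepted within
    ``search_halfwidth * Freq0`` of the expected multiple (NaN otherwise).
    """
    y = np.asarray(original_beat, dtype=float)
    if y.size < 10:
        raise ValueError("beat too short for frequency analysis")
    tiled = np.tile(y - y.mean(), n_copies)
    mag = np.abs(np.fft.rfft(tiled))
    freqs = np.fft.rfftfreq(tiled.size, d=1.0 / fs)
    peaks, _ = find_peaks(mag)
    peaks = peaks[freqs[peaks] > 0]
    if peaks.size == 0:
        return (float("nan"),) * 4
    f0_idx = peaks[int(np.argmax(mag[peaks]))]
    f0 = float(freqs[f0_idx])
    out = [f0]
    peak_freqs = freqs[peaks]
    for k in (2, 3, 4):
        target = k * f0
        dist = np.abs(peak_freqs - target)
        j = int(np.argmin(dist))
        if dist[j] <= search_halfwidth * f0:
            out.append(float(peak_freqs[j]))
        else:
            out.append(float("nan"))
    return tuple(out)  # type: ignore[return-value]


def extract_all(beat, decomposition: DecompositionResult) -> FeatureVector:
    """Full 15-feature vector of one beat.

    PWD features come from the fitted kernel landmarks; b/a, SD, kurt,
    skew and PW from the fitted reconstruction; Freq0..Freq3 from the
    original (normalized) beat samples.
    """
    lm = kernel_landmarks(decomposition)
    recon = decomposition.reconstruction
    fs = decomposition.fs
    sd, kurt, skew, pw = statistical_features(recon, fs)
    ba = b_over_a(recon, fs)
    f0, f1, f2, f3 = frequency_features(beat.samples, beat.fs)
    values = {
        "P1": lm.P1,
        "P2": lm.P2,
        "T1": lm.T1,
        "T2": lm.T2,
        "W1": lm.W1,
        "W2": lm.W2,
        "b_over_a": ba,
        "SD": sd,
        "kurt": kurt,
        "skew": skew,
        "PW": pw,
        "Freq0": f0,
        "Freq1": f1,
        "Freq2": f2,
        "Freq3": f3,
    }
    return FeatureVector(values=values)
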