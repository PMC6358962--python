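"""Systolic peak and valley detection via two-event-moving-average thresholds.

Two centred moving means of the squared signal S[n] are compared: a short one
(window W1, default 111 ms) that tracks the systolic upstroke and a long one
(window W2, default 667 ms) that tracks the full heartbeat cycle. Samples
where the short mean exceeds the long mean plus an adaptive offset
``beta * mean(S)`` form candidate blocks of interest; blocks narrower than W1
(in samples) are treated as noise and discarded. The systolic peak is the
maximum of the low-passed PPG inside each surviving block, and the diastolic
valley the minimum of the low-passed PPG strictly between consecutive peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import FilteredSignal

__all__ = ["ThresholdParams", "BeatSeries", "moving_averages",
           "blocks_of_interest", "detect_beats"]


@dataclass(frozen=True)
class ThresholdParams:
    """Moving-average window lengths (ms) and adaptive-threshold offset."""

    w1_ms: float = 111.0
    w2_ms: float = 667.0
    beta: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.w1_ms < self.w2_ms:
            raise ValueError("require 0 < w1_ms < w2_ms")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")

    def window_samples(self, w_ms: float, fs: float) -> int:
        """Window length in samples, forced odd for a symmetric centred mean."""
        w = int(round(w_ms * fs / 1000.0))
        w = max(w, 1)
        if w % 2 == 0:
            w += 1
        return w


@dataclass
class BeatSeries:
    """Detected systolic peak and diastolic valley sample indices."""

    peak_idx: np.ndarray
    valley_idx: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.peak_idx = np.asarray(self.peak_idx, dtype=int)
        self.valley_idx = np.asarray(self.valley_idx, dtype=int)
        if self.peak_idx.size and np.any(np.diff(self.peak_idx) <= 0):
            raise ValueError("peak_idx must be strictly increasing")
        expected = max(self.peak_idx.size - 1, 0)
        if self.valley_idx.size != expected:
            raise ValueError(
                f"expected exactly one valley between consecutive peaks "
                f"({expected}), got {self.valley_idx.size}"
            )

    @property
    def n_beats(self) -> int:
        return int(self.peak_idx.size)


def _centered_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Centred moving mean with partial windows (shrinking) at the edges."""
    n = x.size
    if w > n:
        raise ValueError(f"moving-average window ({w}) longer than signal ({n})")
    half = (w - 1) // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    hi = np.minimum(np.arange(n) + half + 1, n)
    lo = np.maximum(np.arange(n) - half, 0)
    return (csum[hi] - csum[lo]) / (hi - lo)


def moving_averages(
    S: np.ndarray, fs: float, params: ThresholdParams = ThresholdParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Return (MA_peak, MA_beat): the W1- and W2-window centred means of S."""
    S = np.asarray(S, dtype=float)
    w1 = params.window_samples(params.w1_ms, fs)
    w2 = params.window_samples(params.w2_ms, fs)
    return _centered_mean(S, w1), _centered_mean(S, w2)


def blocks_of_interest(
    ma_peak: np.ndarray,
    ma_beat: np.ndarray,
    S: np.ndarray,
    fs: float,
    params: ThresholdParams = ThresholdParams(),
) -> list[tuple[int, int]]:
    """Maximal runs where MA_peak exceeds the adaptive threshold.

    Threshold1[n] = MA_beat[n] + beta * mean(S); runs narrower than
    Threshold2 = W1 (in samples) are discarded as noise artifacts. Returned
    intervals are half-open ``(start, end)``.
    """
    ma_peak = np.asarray(ma_peak, float)
    ma_beat = np.asarray(ma_beat, float)
    S = np.asarray(S, float)
    if not (ma_peak.size == ma_beat.size == S.size):
        raise ValueError("arrays must have equal length")

    threshold1 = ma_beat + params.beta * float(np.mean(S))
    mask = ma_peak > threshold1
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2]
    threshold2 = params.window_samples(params.w1_ms, fs)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= threshold2]


def detect_beats(
    filtered: FilteredSignal, params: ThresholdParams = ThresholdParams()
) -> BeatSeries:
    """Detect systolic peaks (one per surviving block) and in-between valleys.

    Peaks index the maximum of the *low-passed* signal within each block so
    that amplitude features reflect pulse morphology; valleys index the
    minimum strictly between consecutive peaks. Ties break to the earliest
    index. Fewer than two blocks yield a (near-)empty series.
    """
    ma_peak, ma_beat = moving_averages(filtered.squared, filtered.fs, params)
    blocks = blocks_of_interest(ma_peak, ma_beat, filtered.squared, filtered.fs, params)

    low = filtered.lowpassed
    peaks = np.array(
        [s + int(np.argmax(low[s:e])) for s, e in blocks], dtype=int
    )
    peaks = np.unique(peaks)

    valleys = np.array(
        [p0 + 1 + int(np.argmin(low[p0 + 1:p1])) for p0, p1 in zip(peaks, peaks[1:])],
        dtype=int,
    )
    return BeatSeries(peak_idx=peaks, valley_idx=valleys, fs=filtered.fs)
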