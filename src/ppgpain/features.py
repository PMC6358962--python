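"""Sliding-window morphology and HRV feature extraction.

A 5-minute window slid in 1-minute steps over each record yields one
17-component feature vector per window:

* PPG geometry: pulse height, rise time, fall time, average heart rate
  (instantaneous HR = 60 * fs / PPI_samples, averaged over the window);
* HRV time domain: AVNN, SDNN, RMSSD, NN20, pNN20, NN50, pNN50;
* HRV frequency domain: VLF (0.003-0.04 Hz), LF (0.04-0.15 Hz),
  HF (0.15-0.4 Hz) and total (0.003-0.4 Hz) band powers from an FFT
  periodogram of the tachogram (corrected PPI series cubic-resampled to a
  uniform 4 Hz grid and mean-detrended), LF/HF ratio, and respiratory-rate
  power (maximum PSD value in 0.1-0.25 Hz).

A 14-minute record yields 10 windows. Windows with fewer than 10 beats are
dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate as spi
from scipy import signal as sps

from .beatdetect import BeatSeries
from .ppi import PPISeries
from .preprocess import FilteredSignal, PPGRecord

__all__ = [
    "WindowSpec",
    "FEATURE_NAMES",
    "FEATURE_LABELS",
    "META_COLUMNS",
    "sliding_windows",
    "geometry_features",
    "hrv_time_features",
    "hrv_freq_features",
    "extract_features",
]

#: Canonical feature order (snake_case column names).
FEATURE_NAMES: tuple[str, ...] = (
    "pulse_height", "rise_time", "fall_time", "average_hr",
    "avnn", "sdnn", "rmssd", "nn20", "pnn20", "nn50", "pnn50",
    "vlf_power", "lf_power", "hf_power", "total_power", "lf_hf_ratio",
    "resp_rate_power",
)

#: Column name -> conventional display label.
FEATURE_LABELS: dict[str, str] = {
    "pulse_height": "Pulse Height",
    "rise_time": "Rise time",
    "fall_time": "Fall time",
    "average_hr": "Average heart rate",
    "avnn": "AVNN",
    "sdnn": "SDNN",
    "rmssd": "RMSSD",
    "nn20": "NN20",
    "pnn20": "pNN20",
    "nn50": "NN50",
    "pnn50": "pNN50",
    "vlf_power": "VLF",
    "lf_power": "LF",
    "hf_power": "HF",
    "total_power": "Total",
    "lf_hf_ratio": "LF/HF",
    "resp_rate_power": "Respiratory rate power",
}

META_COLUMNS = ("subject_id", "period", "nrs", "window_index")

VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
TOTAL_BAND = (0.003, 0.4)
RESP_BAND = (0.1, 0.25)

MIN_BEATS_PER_WINDOW = 10


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 5-min windows at 1-min steps by default."""

    window_s: float = 300.0
    step_s: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.window_s:
            raise ValueError("require 0 < step_s <= window_s")


def sliding_windows(duration_s: float, spec: WindowSpec = WindowSpec()) -> list[tuple[float, float]]:
    """(start, end) second pairs: starts at 0, step_s, ... while the window fits."""
    if duration_s < spec.window_s:
        warnings.warn(
            f"record ({duration_s:.0f} s) shorter than the window "
            f"({spec.window_s:.0f} s); no windows produced"
        )
        return []
    out = []
    start = 0.0
    while start + spec.window_s <= duration_s + 1e-9:
        out.append((start, start + spec.window_s))
        start += spec.step_s
    return out


def geometry_features(
    lowpassed: np.ndarray,
    beats: BeatSeries,
    ppi_ms: np.ndarray,
) -> dict[str, float]:
    """Pulse height, rise/fall time (s) and average heart rate (bpm).

    ``beats`` and ``ppi_ms`` must already be restricted to the window. Pulse
    height averages peak-minus-preceding-valley amplitude; boundary beats
    without an adjacent valley are skipped.
    """
    peaks, valleys, fs = beats.peak_idx, beats.valley_idx, beats.fs
    if peaks.size < 2:
        raise ValueError("need at least 2 peaks in the window")
    low = np.asarray(lowpassed, dtype=float)

    # valley i sits between peaks i and i+1: it precedes peak i+1 and
    # follows peak i
    pulse_height = float(np.mean(low[peaks[1:]] - low[valleys]))
    rise_time = float(np.mean((peaks[1:] - valleys) / fs))
    fall_time = float(np.mean((valleys - peaks[:-1]) / fs))
    inst_hr = 60000.0 / np.asarray(ppi_ms, dtype=float)
    return {
        "pulse_height": pulse_height,
        "rise_time": rise_time,
        "fall_time": fall_time,
        "average_hr": float(np.mean(inst_hr)),
    }


def hrv_time_features(
    ppi_ms: np.ndarray,
    sdnn_ddof: int = 0,
    pnn_denominator: str = "pairs",
) -> dict[str, float]:
    """AVNN, SDNN, RMSSD (ms) and the NN20/pNN20/NN50/pNN50 counts.

    ``pnn_denominator`` is ``"pairs"`` (successive-difference pairs, the
    standard HRV convention, default) or ``"intervals"``.
    """
    x = np.asarray(ppi_ms, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 intervals for successive-difference features")
    diffs = np.abs(np.diff(x))
    nn20 = int(np.sum(diffs > 20.0))
    nn50 = int(np.sum(diffs > 50.0))
    denom = diffs.size if pnn_denominator == "pairs" else x.size
    return {
        "avnn": float(np.mean(x)),
        "sdnn": float(np.std(x, ddof=sdnn_ddof)),
        "rmssd": float(np.sqrt(np.mean(np.diff(x) ** 2))),
        "nn20": nn20,
        "pnn20": 100.0 * nn20 / denom,
        "nn50": nn50,
        "pnn50": 100.0 * nn50 / denom,
    }


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def hrv_freq_features(
    ppi_ms: np.ndarray,
    peak_times_s: np.ndarray,
    resample_hz: float = 4.0,
) -> dict[str, float]:
    """Band powers of the tachogram PSD (ms^2) plus LF/HF and respiratory power.

    The irregularly sampled tachogram (interval value at its ending beat time)
    is cubic-interpolated onto a uniform ``resample_hz`` grid and its
    single-segment FFT periodogram integrated over the VLF/LF/HF/total bands.
    ``lf_hf_ratio`` is NaN when HF power is zero.
    """
    x = np.asarray(ppi_ms, dtype=float)
    t = np.asarray(peak_times_s, dtype=float)
    if x.size != t.size:
        raise ValueError("one timestamp per interval required")
    if x.size < 4:
        raise ValueError("need >= 4 intervals for spectral analysis")

    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    tach = spi.interp1d(t, x, kind="cubic", assume_sorted=True)(grid)
    tach = tach - tach.mean()
    freqs, psd = sps.periodogram(tach, fs=resample_hz, window="boxcar",
                                 detrend=False)

    vlf = _band_power(freqs, psd, VLF_BAND)
    lf = _band_power(freqs, psd, LF_BAND)
    hf = _band_power(freqs, psd, HF_BAND)
    total = _band_power(freqs, psd, TOTAL_BAND)
    resp_mask = (freqs >= RESP_BAND[0]) & (freqs <= RESP_BAND[1])
    resp = float(psd[resp_mask].max()) if resp_mask.any() else 0.0
    if hf > 0:
        lf_hf = lf / hf
    else:
        warnings.warn("HF power is zero; LF/HF ratio reported as NaN")
        lf_hf = float("nan")
    return {
        "vlf_power": vlf,
        "lf_power": lf,
        "hf_power": hf,
        "total_power": total,
        "lf_hf_ratio": lf_hf,
        "resp_rate_power": resp,
    }


def _window_slice(series: PPISeries, start_s: float, end_s: float, fs: float):
    """Peaks falling in [start, end) and the corrected intervals between them."""
    peaks = series.peak_idx
    lo, hi = start_s * fs, end_s * fs
    in_win = np.flatnonzero((peaks >= lo) & (peaks < hi))
    if in_win.size < 2:
        return in_win, np.empty(0), np.empty(0)
    first, last = in_win[0], in_win[-1]
    ivals = series.corrected_ms[first:last]  # interval i ends at peak i+1
    end_times = peaks[first + 1:last + 1] / fs
    return in_win, ivals, end_times


def extract_features(
    record: PPGRecord,
    filtered: FilteredSignal,
    beats: BeatSeries,
    ppi: PPISeries,
    spec: WindowSpec = WindowSpec(),
    sdnn_ddof: int = 0,
    pnn_denominator: str = "pairs",
) -> pd.DataFrame:
    """One row of 17 features per sliding window, plus record metadata.

    Windows with fewer than ``MIN_BEATS_PER_WINDOW`` beats are dropped (a
    warning notes each). Returns an empty frame with the full schema when no
    window qualifies.
    """
    fs = record.fs
    rows = []
    for w_idx, (start_s, end_s) in enumerate(sliding_windows(record.duration_s, spec)):
        in_win, ivals, end_times = _window_slice(ppi, start_s, end_s, fs)
        if in_win.size < MIN_BEATS_PER_WINDOW:
            warnings.warn(
                f"window {w_idx} of {record.subject_id or 'record'} has "
                f"{in_win.size} beats (<{MIN_BEATS_PER_WINDOW}); dropped"
            )
            continue
        first, last = in_win[0], in_win[-1]
        win_peaks = ppi.peak_idx[first:last + 1]
        win_valleys = beats.valley_idx[first:last]
        win_beats = BeatSeries(peak_idx=win_peaks, valley_idx=win_valleys, fs=fs)

        row: dict[str, object] = {}
        row.update(geometry_features(filtered.lowpassed, win_beats, ivals))
        row.update(hrv_time_features(ivals, sdnn_ddof=sdnn_ddof,
                                     pnn_denominator=pnn_denominator))
        row.update(hrv_freq_features(ivals, end_times))
        row["subject_id"] = record.subject_id
        row["period"] = record.period
        row["nrs"] = record.nrs
        row["window_index"] = w_idx
        rows.append(row)

    columns = list(FEATURE_NAMES) + list(META_COLUMNS)
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)[columns]
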