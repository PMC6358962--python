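"""Noise and baseline filtering of raw PPG signals prior to beat detection.

The raw finger-PPG waveform carries high-frequency equipment noise and slow
baseline wander on top of the cardiac pulse. The cleaning chain is:

1. second-order Butterworth low-pass at 8 Hz (pulse morphology is preserved,
   monitor/power-line noise removed),
2. second-order Butterworth high-pass at 0.5 Hz (baseline wander removed),
3. half-wave rectification ``C[n] = max(0, H[n])`` and squaring
   ``S[n] = C[n]**2`` to emphasise the systolic upstroke for beat detection.

Both filters are applied forward-backward (zero phase) so that peak timing is
not lagged; the magnitude response is therefore the square of the single-pass
second-order response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "PPGRecord",
    "FilteredSignal",
    "butterworth_lowpass",
    "butterworth_highpass",
    "clip_square",
    "preprocess_record",
    "read_record_csv",
    "write_record_csv",
]

PERIODS = ("preoperative", "postoperative")


@dataclass
class PPGRecord:
    """A single-channel PPG recording with its acquisition metadata.

    Parameters
    ----------
    samples : np.ndarray
        Waveform amplitude in arbitrary units, uniformly sampled.
    fs : float
        Sampling frequency in Hz.
    subject_id : str
        Identifier of the subject the recording belongs to.
    period : str
        Recording period, ``"preoperative"`` or ``"postoperative"``.
    nrs : int or None
        Self-reported numeric rating scale pain score (0-10), if available.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    period: str = "preoperative"
    nrs: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("record has no samples")
        if self.period not in PERIODS:
            raise ValueError(f"period must be one of {PERIODS}, got {self.period!r}")
        if self.nrs is not None and not 0 <= int(self.nrs) <= 10:
            raise ValueError(f"NRS score must lie in [0, 10], got {self.nrs}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class FilteredSignal:
    """Output of the full preprocessing chain for one record.

    ``clipped`` is the half-wave rectified high-passed signal and ``squared``
    its elementwise square; all arrays share the input length.
    """

    lowpassed: np.ndarray
    highpassed: np.ndarray
    clipped: np.ndarray
    squared: np.ndarray
    fs: float = field(default=300.0)


def _butter_sos(fs: float, cutoff: float, order: int, btype: str) -> np.ndarray:
    nyq = fs / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(
            f"cutoff must lie strictly between 0 and the Nyquist frequency "
            f"({nyq} Hz), got {cutoff} Hz"
        )
    return sps.butter(order, cutoff / nyq, btype=btype, output="sos")


def _apply(sos: np.ndarray, samples: np.ndarray, zero_phase: bool) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if zero_phase:
        # odd-reflect padding avoids startup transients at the record edges
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def butterworth_lowpass(
    samples: np.ndarray,
    fs: float,
    cutoff: float = 8.0,
    order: int = 2,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth low-pass (default 8 Hz, order 2), zero phase by default."""
    return _apply(_butter_sos(fs, cutoff, order, "lowpass"), samples, zero_phase)


def butterworth_highpass(
    samples: np.ndarray,
    fs: float,
    cutoff: float = 0.5,
    order: int = 2,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth high-pass (default 0.5 Hz, order 2), zero phase by default."""
    return _apply(_butter_sos(fs, cutoff, order, "highpass"), samples, zero_phase)


def clip_square(highpassed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half-wave rectify and square: ``C = max(0, H)``, ``S = C**2``."""
    H = np.asarray(highpassed, dtype=float)
    C = np.maximum(0.0, H)
    return C, C * C


def preprocess_record(
    record: PPGRecord,
    lowpass_hz: float = 8.0,
    highpass_hz: float = 0.5,
    order: int = 2,
) -> FilteredSignal:
    """Run the full filtering chain on one record."""
    low = butterworth_lowpass(record.samples, record.fs, lowpass_hz, order)
    high = butterworth_highpass(low, record.fs, highpass_hz, order)
    C, S = clip_square(high)
    return FilteredSignal(lowpassed=low, highpassed=high, clipped=C, squared=S, fs=record.fs)


def read_record_csv(
    path,
    fs: float = 300.0,
    subject_id: str = "",
    period: str = "preoperative",
    nrs: int | None = None,
) -> PPGRecord:
    """Read a record CSV with ``sample_index`` and ``amplitude`` columns."""
    df = pd.read_csv(path)
    if "amplitude" not in df.columns:
        raise ValueError(f"{path}: expected an 'amplitude' column, got {list(df.columns)}")
    return PPGRecord(
        samples=df["amplitude"].to_numpy(dtype=float),
        fs=fs,
        subject_id=subject_id,
        period=period,
        nrs=nrs,
    )


def write_record_csv(record: PPGRecord, path) -> None:
    pd.DataFrame(
        {"sample_index": np.arange(record.samples.size), "amplitude": record.samples}
    ).to_csv(path, index=False)
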