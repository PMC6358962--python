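"""Peak-to-peak interval (PPI) series construction and artifact correction.

The PPI series is the PPG analogue of the ECG RR series. Noise, motion and
ectopic beats produce anomalous intervals; an interval PPI_i is flagged when
it meets any of three rule-based conditions:

T1: PPI_i < m20 - 2*sigma20  and  PPI_{i+1} > m20 + 2*sigma20
T2: PPI_i < 0.75*PPI_{i-1}   or   PPI_{i+1} < 0.75*PPI_{i-1}
T3: PPI_i > 1.75*PPI_{i-1}

where m20 and sigma20 are the mean and SD of the previous 20 (unflagged)
intervals; the history window shrinks early in the series. Flagged intervals
are reconstructed by linear interpolation between the nearest unflagged
neighbours over the interval index.

T2's second clause compares PPI_{i+1} against PPI_{i-1} by default (as the
rule set is stated); ``t2_reference="current"`` switches the comparison to
PPI_i, the plausible intended variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beatdetect import BeatSeries

__all__ = ["PPISeries", "compute_ppi", "flag_artifacts", "interpolate_flagged",
           "correct_ppi"]

_HISTORY = 20  # intervals entering the running mean/SD


@dataclass
class PPISeries:
    """PPI series in ms with per-interval artifact flags and corrections."""

    ppi_ms: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    corrected_ms: np.ndarray = field(default=None)  # type: ignore[assignment]
    peak_idx: np.ndarray = field(default=None)  # type: ignore[assignment]
    fs: float = 300.0

    def __post_init__(self) -> None:
        self.ppi_ms = np.asarray(self.ppi_ms, dtype=float)
        if self.ppi_ms.size and np.any(self.ppi_ms <= 0):
            raise ValueError("peak-to-peak intervals must be positive")
        if self.flags is None:
            self.flags = np.zeros(self.ppi_ms.size, dtype=bool)
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.corrected_ms is None:
            self.corrected_ms = self.ppi_ms.copy()
        self.corrected_ms = np.asarray(self.corrected_ms, dtype=float)
        if not (self.flags.size == self.ppi_ms.size == self.corrected_ms.size):
            raise ValueError("ppi_ms, flags and corrected_ms must share length")
        if self.peak_idx is not None:
            self.peak_idx = np.asarray(self.peak_idx, dtype=int)

    @property
    def flag_rate(self) -> float:
        return float(self.flags.mean()) if self.flags.size else 0.0


def compute_ppi(beats: BeatSeries) -> PPISeries:
    """PPI_i = (peak_{i+1} - peak_i) / fs * 1000 ms, for >= 2 detected peaks."""
    if beats.peak_idx.size < 2:
        raise ValueError(
            f"need at least 2 peaks to form an interval series, got {beats.peak_idx.size}"
        )
    ppi_ms = np.diff(beats.peak_idx) / beats.fs * 1000.0
    return PPISeries(ppi_ms=ppi_ms, peak_idx=beats.peak_idx, fs=beats.fs)


def flag_artifacts(series: PPISeries, t2_reference: str = "prev") -> np.ndarray:
    """Apply rules T1-T3 sequentially; flagged intervals leave the history.

    Rules needing an unavailable neighbour (first/last interval) skip that
    clause; T1 is skipped while fewer than 2 unflagged history intervals
    exist. Returns the boolean flag array (also stored on ``series``).
    """
    if t2_reference not in ("prev", "current"):
        raise ValueError("t2_reference must be 'prev' or 'current'")
    ppi = series.ppi_ms
    n = ppi.size
    if n == 0:
        raise ValueError("empty PPI series")
    flags = np.zeros(n, dtype=bool)
    history: list[float] = []

    for i in range(n):
        flagged = False
        nxt = ppi[i + 1] if i + 1 < n else None
        prev = ppi[i - 1] if i >= 1 else None

        if len(history) >= 2 and nxt is not None:
            m20 = float(np.mean(history[-_HISTORY:]))
            s20 = float(np.std(history[-_HISTORY:]))
            if ppi[i] < m20 - 2.0 * s20 and nxt > m20 + 2.0 * s20:
                flagged = True  # T1
        if not flagged and prev is not None:
            ref = prev if t2_reference == "prev" else ppi[i]
            if ppi[i] < 0.75 * prev or (nxt is not None and nxt < 0.75 * ref):
                flagged = True  # T2
            elif ppi[i] > 1.75 * prev:
                flagged = True  # T3
        flags[i] = flagged
        if not flagged:
            history.append(float(ppi[i]))

    series.flags = flags
    return flags


def interpolate_flagged(series: PPISeries) -> np.ndarray:
    """Replace flagged intervals by linear interpolation over interval index.

    Leading/trailing flagged runs take the nearest unflagged value. Requires
    at least one unflagged interval. Returns (and stores) ``corrected_ms``.
    """
    flags = series.flags
    good = np.flatnonzero(~flags)
    if good.size == 0:
        raise ValueError("all intervals flagged; nothing to interpolate from")
    corrected = series.ppi_ms.copy()
    bad = np.flatnonzero(flags)
    if bad.size:
        corrected[bad] = np.interp(bad, good, series.ppi_ms[good])
    series.corrected_ms = corrected
    return corrected


def correct_ppi(beats: BeatSeries, t2_reference: str = "prev") -> PPISeries:
    """Full PPI stage: intervals, artifact flags, interpolation."""
    series = compute_ppi(beats)
    flag_artifacts(series, t2_reference=t2_reference)
    interpolate_flagged(series)
    return series
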