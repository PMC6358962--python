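"""Synthetic PPG cohort generator with known ground truth.

Generates finger-PPG-like waveforms at 300 Hz: beats are placed by integrating
an instantaneous heart period (mean heart rate plus sinusoidal peak-to-peak
interval modulations in the VLF/LF/HF bands), each beat is rendered as an
asymmetric pulse (half-cosine systolic rise over ``rise_fraction`` of the
period, exponential diastolic fall), and baseline wander, Gaussian sensor
noise and occasional ectopic-like short/long interval pairs are superimposed.

Cohort generation draws per-subject parameters around class-conditional means
and SDs patterned on the reference cohort's reported feature statistics
(preoperative heart rate 66.32 +/- 10.30 bpm vs 69.66 +/- 10.28 bpm
postoperatively, lower pulse height and LF/HF balance after surgery), at the
*parameter* level — downstream stages must recover the separability from the
raw waveform.

Every operation is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import PPGRecord
from .study import NRS_POSTOP_COUNTS

__all__ = [
    "ModulationSpec",
    "SynthConfig",
    "SynthRecord",
    "generate_record",
    "generate_cohort",
    "DEFAULT_TWO_CLASS_SPECS",
    "DEFAULT_FOUR_CLASS_SPECS",
]


@dataclass(frozen=True)
class ModulationSpec:
    """One sinusoidal peak-to-peak-interval modulation line.

    ``freq_hz`` is the modulation frequency (e.g. 0.1 Hz for an LF line,
    0.25 Hz for respiratory sinus arrhythmia), ``amp_ms`` its amplitude in
    milliseconds of interval deviation.
    """

    freq_hz: float
    amp_ms: float


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording.

    Defaults emulate a 14-minute, 300 Hz recovery-room recording with HRV
    modulation lines in the VLF (0.02 Hz), LF (0.1 Hz) and HF/respiratory
    (0.25 Hz) bands.
    """

    duration_s: float = 840.0
    fs: float = 300.0
    mean_hr_bpm: float = 65.0
    modulations: tuple[ModulationSpec, ...] = (
        ModulationSpec(0.02, 30.0),
        ModulationSpec(0.10, 35.0),
        ModulationSpec(0.25, 27.0),
    )
    rise_fraction: float = 0.24
    pulse_amplitude: float = 0.9
    baseline_freq_hz: float = 0.08
    baseline_amp: float = 0.1
    noise_sd: float = 0.02
    ectopic_rate_per_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 20.0 <= self.mean_hr_bpm <= 240.0:
            raise ValueError(
                f"mean heart rate {self.mean_hr_bpm} bpm is outside the "
                "physiological range 20-240 bpm"
            )
        if not 0.0 < self.rise_fraction < 1.0:
            raise ValueError("rise_fraction must lie in (0, 1)")
        if self.ectopic_rate_per_min < 0:
            raise ValueError("ectopic_rate_per_min must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SynthRecord:
    """A generated record plus its ground truth.

    ``true_ppi_ms`` is defined from the *rounded* peak sample indices so that
    ``diff(true_peak_idx) / fs * 1000`` reproduces it exactly.
    """

    record: PPGRecord
    true_peak_idx: np.ndarray
    true_ppi_ms: np.ndarray
    config: SynthConfig | None = None

    def __post_init__(self) -> None:
        self.true_peak_idx = np.asarray(self.true_peak_idx, dtype=int)
        self.true_ppi_ms = np.asarray(self.true_ppi_ms, dtype=float)
        if np.any(np.diff(self.true_peak_idx) <= 0):
            raise ValueError("true_peak_idx must be strictly increasing")
        if self.true_ppi_ms.size != max(self.true_peak_idx.size - 1, 0):
            raise ValueError("need exactly one PPI per consecutive peak pair")


def _beat_times(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Place beat (systolic peak) times by integrating the instantaneous period."""
    base_ms = 60000.0 / config.mean_hr_bpm
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(config.modulations))
    times = [0.0]
    t = 0.0
    while True:
        ppi_ms = base_ms
        for m, phi in zip(config.modulations, phases):
            ppi_ms += m.amp_ms * np.sin(2.0 * np.pi * m.freq_hz * t + phi)
        ppi_ms = max(ppi_ms, 250.0)  # hard floor: 240 bpm
        t += ppi_ms / 1000.0
        if t > config.duration_s:
            break
        times.append(t)
    return np.asarray(times)


def _inject_ectopics(times: np.ndarray, config: SynthConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Shorten one interval by 40% and lengthen the next to conserve total time."""
    n_events = rng.poisson(config.ectopic_rate_per_min * config.duration_s / 60.0)
    if n_events == 0 or times.size < 4:
        return times
    times = times.copy()
    candidates = np.arange(1, times.size - 1)  # peak indices that may move
    picks = rng.choice(candidates, size=min(n_events, candidates.size), replace=False)
    for j in np.sort(picks):
        ppi = times[j] - times[j - 1]
        shift = 0.4 * ppi
        # keep strict ordering if a neighbouring pick already moved this peak
        if times[j] - shift > times[j - 1] + 0.05:
            times[j] -= shift
    return times


def _render_pulses(peak_times: np.ndarray, config: SynthConfig) -> np.ndarray:
    """Render the pulse waveform from peak times on the uniform sample grid.

    Between consecutive peaks the waveform falls exponentially for the first
    (1 - rise_fraction) of the interval, then rises as a half cosine into the
    next peak; the junction is the diastolic valley.
    """
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    amp = config.pulse_amplitude
    rf = config.rise_fraction

    if peak_times.size == 0:
        return np.zeros(n)
    if peak_times.size == 1:
        period = 60.0 / config.mean_hr_bpm
        segments = np.array([peak_times[0] - period, peak_times[0], peak_times[0] + period])
    else:
        first_p = peak_times[1] - peak_times[0]
        last_p = peak_times[-1] - peak_times[-2]
        segments = np.concatenate(
            [[peak_times[0] - first_p], peak_times, [peak_times[-1] + last_p]]
        )
    idx = np.clip(np.searchsorted(segments, t, side="right") - 1, 0, segments.size - 2)
    seg_start = segments[idx]
    seg_len = segments[idx + 1] - segments[idx]
    u = (t - seg_start) / seg_len  # position within the beat cycle, [0, 1)

    fall = u < (1.0 - rf)
    y = np.empty(n)
    # diastolic decay from the systolic peak (time constant = 1/4 of the fall span)
    y[fall] = amp * np.exp(-4.0 * u[fall] / (1.0 - rf))
    y[~fall] = amp * 0.5 * (1.0 - np.cos(np.pi * (u[~fall] - (1.0 - rf)) / rf))
    return y


def generate_record(config: SynthConfig) -> SynthRecord:
    """Generate one synthetic PPG record with ground-truth beat locations."""
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))

    peak_times = _inject_ectopics(_beat_times(config, rng), config, rng)
    waveform = _render_pulses(peak_times, config)

    t = np.arange(n) / config.fs
    waveform = waveform + config.baseline_amp * np.sin(
        2.0 * np.pi * config.baseline_freq_hz * t + rng.uniform(0, 2 * np.pi)
    )
    if config.noise_sd > 0:
        waveform = waveform + rng.normal(0.0, config.noise_sd, size=n)

    peak_idx = np.unique(np.clip(np.round(peak_times * config.fs).astype(int), 0, n - 1))
    true_ppi_ms = np.diff(peak_idx) / config.fs * 1000.0

    record = PPGRecord(samples=waveform, fs=config.fs)
    return SynthRecord(record=record, true_peak_idx=peak_idx,
                       true_ppi_ms=true_ppi_ms, config=config)


# --- cohort generation -------------------------------------------------------

#: Class-conditional parameter distributions as (mean, sd), patterned on the
#: reference cohort's reported pre/post feature statistics. ``N`` is the
#: preoperative no-pain status; the postoperative classes shift heart rate up
#: and pulse height, modulation amplitudes and LF/HF balance down.
_N_SPEC: dict[str, tuple[float, float]] = {
    "mean_hr_bpm": (66.32, 10.30),
    "pulse_amplitude": (0.908, 0.206),
    "rise_fraction": (0.24, 0.03),
    "vlf_amp_ms": (30.0, 8.0),
    "lf_amp_ms": (35.0, 9.0),
    "hf_amp_ms": (27.0, 7.0),
}
_P_SPEC: dict[str, tuple[float, float]] = {
    "mean_hr_bpm": (69.66, 10.28),
    "pulse_amplitude": (0.673, 0.489),
    "rise_fraction": (0.26, 0.03),
    "vlf_amp_ms": (28.0, 8.0),
    "lf_amp_ms": (29.0, 9.0),
    "hf_amp_ms": (25.0, 7.0),
}

DEFAULT_TWO_CLASS_SPECS: dict[str, dict[str, tuple[float, float]]] = {
    "N": _N_SPEC,
    "P": _P_SPEC,
}


def _graded(frac: float) -> dict[str, tuple[float, float]]:
    """Scale the N->P parameter shift by ``frac`` (severity grading)."""
    out = {}
    for key, (mean_n, sd_n) in _N_SPEC.items():
        mean_p, sd_p = _P_SPEC[key]
        out[key] = (mean_n + frac * (mean_p - mean_n),
                    sd_n + frac * (sd_p - sd_n))
    return out


DEFAULT_FOUR_CLASS_SPECS: dict[str, dict[str, tuple[float, float]]] = {
    "none": _N_SPEC,
    "mild": _graded(0.5),
    "moderate": _graded(1.0),
    "severe": _graded(1.5),
}

#: NRS scores drawable for each postoperative class, with reference-cohort weights.
_CLASS_NRS = {
    "P": ([4, 5, 6, 7, 8, 9, 10], [10, 20, 7, 17, 17, 5, 2]),
    "mild": ([1, 2, 3], [2, 4, 9]),
    "moderate": ([4, 5, 6], [10, 20, 7]),
    "severe": ([7, 8, 9, 10], [17, 17, 5, 2]),
}

#: Within-subject SD of a parameter, as a fraction of its between-subject SD;
#: keeps the pre/post pair of one subject correlated (paired design).
_WITHIN_FRACTION = 0.15

_PARAM_CLIPS = {
    "mean_hr_bpm": (30.0, 180.0),
    "pulse_amplitude": (0.05, None),
    "rise_fraction": (0.08, 0.6),
    "vlf_amp_ms": (0.0, None),
    "lf_amp_ms": (0.0, None),
    "hf_amp_ms": (0.0, None),
}


def _clip(name: str, value: float) -> float:
    lo, hi = _PARAM_CLIPS[name]
    if lo is not None:
        value = max(value, lo)
    if hi is not None:
        value = min(value, hi)
    return value


def _config_from_params(params: dict[str, float], base: SynthConfig,
                        seed: int) -> SynthConfig:
    mods = (
        ModulationSpec(0.02, params["vlf_amp_ms"]),
        ModulationSpec(0.10, params["lf_amp_ms"]),
        ModulationSpec(0.25, params["hf_amp_ms"]),
    )
    return replace(
        base,
        mean_hr_bpm=params["mean_hr_bpm"],
        pulse_amplitude=params["pulse_amplitude"],
        rise_fraction=params["rise_fraction"],
        modulations=mods,
        seed=seed,
    )


def generate_cohort(
    n_subjects: int,
    class_specs: dict[str, dict[str, tuple[float, float]]] | None = None,
    seed: int = 0,
    base_config: SynthConfig | None = None,
    post_class_weights: dict[str, float] | None = None,
) -> list[SynthRecord]:
    """Generate a paired synthetic cohort: one pre- and one postoperative
    record per subject.

    ``class_specs`` maps class labels to per-parameter (mean, sd)
    distributions; the first key is the preoperative (no pain) class, the
    remaining keys are postoperative classes. With more than one postoperative
    class, subjects are assigned a class via ``post_class_weights`` (default:
    reference-cohort NRS proportions).

    Per subject, each parameter gets a shared standardized deviate applied to
    both periods' class distributions plus a small independent within-subject
    jitter, so pre/post pairs are correlated as in a paired design.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    specs = class_specs if class_specs is not None else DEFAULT_TWO_CLASS_SPECS
    labels = list(specs)
    if len(labels) < 2:
        raise ValueError("class_specs needs a preoperative and >= 1 postoperative class")
    pre_label, post_labels = labels[0], labels[1:]

    base = base_config if base_config is not None else SynthConfig()
    rng = np.random.default_rng(seed)

    if len(post_labels) == 1:
        weights = None
    else:
        w = post_class_weights or {
            lab: sum(_CLASS_NRS[lab][1]) if lab in _CLASS_NRS else 1.0
            for lab in post_labels
        }
        weights = np.array([w[lab] for lab in post_labels], dtype=float)
        weights /= weights.sum()

    records: list[SynthRecord] = []
    for s in range(n_subjects):
        subject_id = f"S{s + 1:03d}"
        post_label = (
            post_labels[0] if weights is None
            else post_labels[rng.choice(len(post_labels), p=weights)]
        )
        z = {name: rng.standard_normal() for name in specs[pre_label]}
        for period, label in (("preoperative", pre_label), ("postoperative", post_label)):
            params = {}
            for name, (mean, sd) in specs[label].items():
                jitter = _WITHIN_FRACTION * sd * rng.standard_normal()
                params[name] = _clip(name, mean + sd * z[name] + jitter)
            rec_seed = int(rng.integers(0, 2**31 - 1))
            config = _config_from_params(params, base, rec_seed)
            synth = generate_record(config)
            if period == "preoperative":
                nrs = 0
            elif post_label in _CLASS_NRS:
                scores, wts = _CLASS_NRS[post_label]
                nrs = int(rng.choice(scores, p=np.array(wts, float) / sum(wts)))
            else:
                nrs = None
            synth.record.subject_id = subject_id
            synth.record.period = period
            synth.record.nrs = nrs
            records.append(synth)
    return records
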