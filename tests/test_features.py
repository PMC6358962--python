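import numpy as np
import pytest

from ppgpain import features as ft
from ppgpain import synth
from ppgpain.beatdetect import detect_beats
from ppgpain.pipeline import features_for_record
from ppgpain.ppi import correct_ppi
from ppgpain.preprocess import PPGRecord, preprocess_record


class TestSlidingWindows:
    @pytest.mark.parametrize("duration,expected", [
        (840.0, 10),   # 14-min record, 5-min window, 1-min step
        (300.0, 1),
        (360.0, 2),
    ])
    def test_window_counts(self, duration, expected):
        assert len(ft.sliding_windows(duration)) == expected

    def test_too_short_record_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert ft.sliding_windows(100.0) == []

    def test_windows_start_on_step_grid(self):
        wins = ft.sliding_windows(840.0)
        assert [w[0] for w in wins] == [60.0 * i for i in range(10)]
        assert all(e - s == 300.0 for s, e in wins)


class TestGeometryFeatures:
    def test_instantaneous_hr_formula(self):
        # a 300-sample interval at 300 Hz is one second: 60 bpm
        beats_ppi = np.array([1000.0, 1000.0])
        low = np.zeros(1000)
        from ppgpain.beatdetect import BeatSeries
        beats = BeatSeries(peak_idx=[100, 400, 700], valley_idx=[250, 550], fs=300.0)
        out = ft.geometry_features(low, beats, beats_ppi)
        assert out["average_hr"] == pytest.approx(60.0)

    def test_symmetric_pulses_have_equal_rise_and_fall(self):
        from ppgpain.beatdetect import BeatSeries
        low = np.zeros(2000)
        # valleys exactly midway between peaks
        beats = BeatSeries(peak_idx=[100, 400, 700], valley_idx=[250, 550], fs=300.0)
        out = ft.geometry_features(low, beats, np.array([1000.0, 1000.0]))
        assert out["rise_time"] == pytest.approx(out["fall_time"])

    def test_fixed_72bpm_record_average_hr(self):
        cfg = synth.SynthConfig(duration_s=320.0, mean_hr_bpm=72.0, modulations=(),
                                baseline_amp=0.0, noise_sd=0.0, seed=2)
        rec = synth.generate_record(cfg)
        matrix = features_for_record(rec.record)
        assert matrix["average_hr"].iloc[0] == pytest.approx(72.0, abs=0.5)

    def test_pulse_height_tracks_generator_amplitude(self):
        low_amp = synth.generate_record(synth.SynthConfig(
            duration_s=320.0, pulse_amplitude=0.4, noise_sd=0.0, seed=4))
        high_amp = synth.generate_record(synth.SynthConfig(
            duration_s=320.0, pulse_amplitude=1.2, noise_sd=0.0, seed=4))
        ph_low = features_for_record(low_amp.record)["pulse_height"].iloc[0]
        ph_high = features_for_record(high_amp.record)["pulse_height"].iloc[0]
        assert ph_high > 2.0 * ph_low


class TestHrvTimeFeatures:
    def test_constant_series(self):
        out = ft.hrv_time_features(np.full(20, 1000.0))
        assert out["avnn"] == 1000.0
        assert out["sdnn"] == 0.0 and out["rmssd"] == 0.0
        assert out["nn20"] == out["nn50"] == 0
        assert out["pnn20"] == out["pnn50"] == 0.0

    def test_alternating_series_hand_computed(self):
        x = np.tile([980.0, 1020.0], 5)  # 10 intervals, 9 diffs of 40 ms
        out = ft.hrv_time_features(x)
        assert out["rmssd"] == pytest.approx(40.0)
        assert out["nn20"] == 9 and out["pnn20"] == pytest.approx(100.0)
        assert out["nn50"] == 0

    def test_single_30ms_difference(self):
        out = ft.hrv_time_features(np.array([1000.0, 1030.0]))
        assert out["nn20"] == 1 and out["nn50"] == 0

    def test_boundary_differences_are_strict(self):
        out = ft.hrv_time_features(np.array([1000.0, 1020.0, 1070.0]))
        assert out["nn20"] == 1  # 20 ms exactly does not count, 50 ms does
        assert out["nn50"] == 0

    def test_shift_invariance_of_variability_measures(self, rng):
        x = 1000.0 + rng.normal(0, 30, size=50)
        a = ft.hrv_time_features(x)
        b = ft.hrv_time_features(x + 500.0)
        for key in ("sdnn", "rmssd", "nn20", "pnn20", "nn50", "pnn50"):
            assert a[key] == pytest.approx(b[key])

    def test_denominator_convention_switch(self):
        x = np.tile([980.0, 1020.0], 5)
        pairs = ft.hrv_time_features(x, pnn_denominator="pairs")
        ivals = ft.hrv_time_features(x, pnn_denominator="intervals")
        assert pairs["pnn20"] == pytest.approx(100.0)
        assert ivals["pnn20"] == pytest.approx(90.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            ft.hrv_time_features(np.array([1000.0]))


class TestHrvFreqFeatures:
    def _tachogram(self, freq, amp=50.0, duration=300.0):
        t = [0.0]
        while t[-1] < duration:
            t.append(t[-1] + 1.0)
        t = np.array(t[1:])
        x = 1000.0 + amp * np.sin(2 * np.pi * freq * t)
        return x, t

    def test_constant_tachogram_has_no_power(self):
        x = np.full(300, 1000.0)
        t = np.arange(1.0, 301.0)
        out = ft.hrv_freq_features(x, t)
        assert out["total_power"] == pytest.approx(0.0, abs=1e-10)

    def test_lf_line_dominates_and_sets_respiratory_peak(self):
        x, t = self._tachogram(0.1)
        out = ft.hrv_freq_features(x, t)
        assert out["lf_power"] / (out["lf_power"] + out["hf_power"]) >= 0.9
        assert out["lf_hf_ratio"] > 1.0
        # the respiratory-band PSD maximum sits at the 0.1 Hz line
        assert out["resp_rate_power"] > 0

    def test_hf_line_flips_the_balance(self):
        x, t = self._tachogram(0.3)
        out = ft.hrv_freq_features(x, t)
        assert out["hf_power"] > out["lf_power"]

    def test_band_powers_nonnegative_and_bounded_by_total(self):
        x, t = self._tachogram(0.1)
        out = ft.hrv_freq_features(x, t)
        for band in ("vlf_power", "lf_power", "hf_power"):
            assert 0 <= out[band] <= out["total_power"] * 1.05


class TestExtractFeatures:
    def test_fourteen_minute_record_gives_10x17(self, modulated_record):
        matrix = features_for_record(modulated_record.record)
        assert len(matrix) == 10
        assert list(matrix.columns[:17]) == list(ft.FEATURE_NAMES)

    def test_feature_label_set_is_canonical(self):
        assert set(ft.FEATURE_LABELS.values()) == {
            "Pulse Height", "Rise time", "Fall time", "Average heart rate",
            "AVNN", "SDNN", "RMSSD", "NN20", "pNN20", "NN50", "pNN50",
            "VLF", "LF", "HF", "Total", "LF/HF", "Respiratory rate power",
        }
        assert len(ft.FEATURE_NAMES) == 17

    def test_flat_record_yields_zero_rows(self):
        rec = PPGRecord(samples=np.zeros(300 * 400), fs=300.0)
        with pytest.warns(UserWarning):
            matrix = features_for_record(rec)
        assert len(matrix) == 0
        assert list(matrix.columns[:17]) == list(ft.FEATURE_NAMES)

    def test_pnn50_never_exceeds_pnn20(self, small_cohort_features):
        m = small_cohort_features
        assert (m["pnn50"] <= m["pnn20"] + 1e-12).all()
        assert (m["rmssd"] >= 0).all()
        for band in ("vlf_power", "lf_power", "hf_power"):
            assert (m[band] >= 0).all()

    def test_class_difference_sign_matches_generator(self, small_cohort_features):
        m = small_cohort_features
        hr = m.groupby("period")["average_hr"].mean()
        assert hr["postoperative"] > hr["preoperative"]
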