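"""Cardiac pipeline: filtering, detection, correction, HRV metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardioresp import cardiac, synth
from cardioresp.channels import (
    EventSeries,
    RRSeries,
    UnusableRecordingError,
    WaveformChannel,
)

from oracles import apen as apen_oracle
from oracles import mean_instant_hr, pnn50 as pnn50_oracle, rmssd as rmssd_oracle, sd


def _sine_channel(freq, fs=250.0, duration=30.0, amp=1.0, offset=0.0):
    t = np.arange(int(duration * fs)) / fs
    return WaveformChannel(offset + amp * np.sin(2 * np.pi * freq * t), fs)


def _tone_amplitude(x, freq, fs):
    t = np.arange(x.size) / fs
    return 2 * np.hypot(
        np.mean(x * np.cos(2 * np.pi * freq * t)),
        np.mean(x * np.sin(2 * np.pi * freq * t)),
    )


class TestFilterECG:
    def test_dc_offset_removed(self):
        ch = WaveformChannel(np.full(250 * 20, 3.7), 250.0)
        out = cardiac.filter_ecg(ch)
        assert np.abs(out.samples.mean()) < 1e-6

    def test_mains_attenuated_20db(self):
        ch = _sine_channel(50.0)
        out = cardiac.filter_ecg(ch)
        before = _tone_amplitude(ch.samples, 50.0, 250.0)
        after = _tone_amplitude(out.samples, 50.0, 250.0)
        assert 20 * np.log10(before / after) >= 20.0

    def test_passband_preserved(self):
        ch = _sine_channel(1.5)
        out = cardiac.filter_ecg(ch)
        after = _tone_amplitude(out.samples, 1.5, 250.0)
        assert after == pytest.approx(1.0, rel=0.05)

    def test_notch_above_nyquist_rejected(self):
        ch = WaveformChannel(np.zeros(100 * 20), 100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            cardiac.filter_ecg(ch, mains_hz=60.0)


class TestDetectRPeaks:
    def test_clean_synthetic_fully_recovered(self, quiet_profile):
        rr = synth.generate_rr_series(quiet_profile, 240, seed=1)
        ecg = synth.synthesize_ecg(rr.times, 250, duration=240)
        peaks = cardiac.detect_r_peaks(cardiac.filter_ecg(ecg))
        truth = rr.times[(rr.times >= 0.5) & (rr.times <= 239.5)]
        assert peaks.n == truth.size  # no misses, no false positives
        err = np.abs(truth[:, None] - peaks.times[None, :]).min(axis=1)
        assert err.max() <= 1.0 / 250 + 1e-9

    def test_flat_signal_gives_empty_result(self):
        ch = WaveformChannel(np.zeros(250 * 30), 250.0)
        peaks = cardiac.detect_r_peaks(ch)
        assert peaks.n == 0

    def test_inverted_polarity_recovered(self, quiet_profile):
        rr = synth.generate_rr_series(quiet_profile, 240, seed=2)
        ecg = synth.synthesize_ecg(rr.times, 250, duration=240)
        flipped = ecg.with_samples(-ecg.samples)
        peaks = cardiac.detect_r_peaks(cardiac.filter_ecg(flipped))
        truth = rr.times[(rr.times >= 0.5) & (rr.times <= 239.5)]
        assert peaks.n == truth.size
        err = np.abs(truth[:, None] - peaks.times[None, :]).min(axis=1)
        assert err.max() <= 1.0 / 250 + 1e-9

    def test_refractory_spacing(self, quiet_profile):
        rr = synth.generate_rr_series(quiet_profile, 240, seed=3)
        ecg = synth.synthesize_ecg(rr.times, 250, duration=240)
        peaks = cardiac.detect_r_peaks(cardiac.filter_ecg(ecg))
        assert np.all(np.diff(peaks.times) >= 0.2)


class TestCorrectRR:
    def _series(self, intervals_ms):
        times = np.concatenate([[0.0], np.cumsum(intervals_ms) / 1000.0])
        return RRSeries.from_beat_times(times)

    def test_clean_series_unchanged(self):
        rng = np.random.default_rng(0)
        iv = 800 + rng.normal(0, 25, 60)
        rr = self._series(iv)
        out = cardiac.correct_rr_intervals(rr)
        assert not out.corrected_flags.any()
        np.testing.assert_allclose(out.intervals, rr.intervals, rtol=1e-12)

    def test_long_interval_replaced_near_local_median(self):
        iv = np.full(40, 800.0)
        iv[20] = 3000.0
        out = cardiac.correct_rr_intervals(self._series(iv))
        assert out.corrected_flags.any()
        med = np.median(out.intervals)
        assert np.all(np.abs(out.intervals - med) < 100.0)

    def test_missed_beat_split_into_plausible_intervals(self):
        iv = np.full(40, 800.0)
        iv[15] = 1600.0  # one missed beat: interval doubles
        out = cardiac.correct_rr_intervals(self._series(iv))
        assert out.intervals.size == 41
        assert np.all(np.abs(out.intervals - 800.0) < 100.0)

    def test_excessive_artifacts_marks_unusable(self):
        rng = np.random.default_rng(1)
        iv = 800 + rng.normal(0, 10, 40)
        iv[::3] = 2600.0  # a third of the intervals implausible
        with pytest.raises(UnusableRecordingError) as err:
            cardiac.correct_rr_intervals(self._series(iv))
        assert err.value.reason == "excessive_rr_artifacts"

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            cardiac.correct_rr_intervals(self._series(np.full(5, 800.0)))


class TestSelectSegment:
    def _rr(self, total_s, rr_ms=1000.0):
        times = np.arange(0.0, total_s + 1e-9, rr_ms / 1000.0)
        return RRSeries.from_beat_times(times)

    def test_12min_recording_gives_11min_window(self):
        out = cardiac.select_segment(self._rr(720.0), length=660.0)
        assert out.beat_times[-1] - out.beat_times[0] == pytest.approx(660.0)

    def test_exact_length_is_identity(self):
        rr = self._rr(660.0)
        out = cardiac.select_segment(rr, length=660.0)
        np.testing.assert_array_equal(out.beat_times, rr.beat_times)

    def test_short_recording_rejected_with_report(self):
        with pytest.raises(ValueError, match="660"):
            cardiac.select_segment(self._rr(300.0), length=660.0)

    def test_offset_window(self):
        out = cardiac.select_segment(self._rr(720.0), length=600.0, start=60.0)
        assert out.beat_times[0] >= 60.0
        assert out.beat_times[-1] <= 660.0


class TestTimeDomain:
    def _series(self, intervals_ms):
        times = np.concatenate([[0.0], np.cumsum(intervals_ms) / 1000.0])
        return RRSeries.from_beat_times(times)

    def test_constant_series(self):
        out = cardiac.hrv_time_domain(self._series(np.full(30, 1000.0)))
        assert out["heart_rate"] == pytest.approx(60.0)
        assert out["sdnn"] == 0.0
        assert out["rmssd"] == 0.0
        assert out["pnn50"] == 0.0

    def test_alternating_series(self):
        iv = np.tile([800.0, 860.0], 20)
        out = cardiac.hrv_time_domain(self._series(iv))
        assert out["rmssd"] == pytest.approx(60.0)
        assert out["pnn50"] == pytest.approx(100.0)

    def test_matches_bruteforce_oracle(self, rng):
        iv = rng.uniform(600.0, 1100.0, 50)
        out = cardiac.hrv_time_domain(self._series(iv))
        vals = iv.tolist()
        assert out["heart_rate"] == pytest.approx(mean_instant_hr(vals), rel=1e-9)
        assert out["rr_mean"] == pytest.approx(sum(vals) / len(vals), rel=1e-9)
        assert out["sdnn"] == pytest.approx(sd(vals), rel=1e-9)
        assert out["rmssd"] == pytest.approx(rmssd_oracle(vals), rel=1e-9)
        assert out["pnn50"] == pytest.approx(pnn50_oracle(vals), rel=1e-9)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        st.lists(st.floats(min_value=400.0, max_value=1800.0), min_size=3, max_size=40)
    )
    def test_oracle_equivalence_property(self, intervals):
        out = cardiac.hrv_time_domain(self._series(np.array(intervals)))
        assert out["sdnn"] == pytest.approx(sd(intervals), rel=1e-9, abs=1e-9)
        assert out["rmssd"] == pytest.approx(rmssd_oracle(intervals), rel=1e-9, abs=1e-9)
        assert out["pnn50"] == pytest.approx(pnn50_oracle(intervals), rel=1e-9)


class TestFrequencyDomain:
    def _modulated(self, freq, depth=40.0, duration=300.0):
        p = synth.ConditionProfile(
            name="m", mean_rr=1000.0, lf_depth=0.0, hf_depth=depth,
            rr_noise_sd=0.0, hf_freq=freq,
        )
        rr = synth.generate_rr_series(p, duration, seed=0)
        return RRSeries.from_beat_times(rr.times)

    def test_hf_modulation_lands_in_hf_band(self):
        out = cardiac.hrv_frequency_domain(self._modulated(0.25))
        assert out["hf"] / (out["lf"] + out["hf"]) > 0.95

    def test_lf_modulation_lands_in_lf_band(self):
        out = cardiac.hrv_frequency_domain(self._modulated(0.10))
        assert out["lf"] / (out["lf"] + out["hf"]) > 0.95

    def test_normalized_powers_and_log(self, rest_profile):
        rr = synth.generate_rr_series(rest_profile, 660, seed=4)
        out = cardiac.hrv_frequency_domain(RRSeries.from_beat_times(rr.times))
        assert 0.0 <= out["lfn"] <= 1.0
        assert 0.0 <= out["hfn"] <= 1.0
        assert out["lfn"] + out["hfn"] <= 1.0 + 1e-12
        assert out["ln_hf"] == pytest.approx(np.log(out["hf"]))

    def test_short_segment_rejected(self):
        times = np.arange(0.0, 60.0, 0.8)
        with pytest.raises(ValueError, match="120"):
            cardiac.hrv_frequency_domain(RRSeries.from_beat_times(times))

    def test_window_offset_invariance(self, rest_profile):
        # metrics on a stationary synthetic series shift only within
        # Welch estimator variance when the window start moves
        rr = synth.generate_rr_series(rest_profile, 900, seed=5)
        full = RRSeries.from_beat_times(rr.times)
        a = cardiac.hrv_frequency_domain(cardiac.select_segment(full, 660, 0.0))
        b = cardiac.hrv_frequency_domain(cardiac.select_segment(full, 660, 120.0))
        assert a["hfn"] == pytest.approx(b["hfn"], abs=0.12)


class TestApproximateEntropy:
    def test_constant_series_is_zero(self):
        assert cardiac.approximate_entropy(np.full(80, 800.0)) == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        x = rng.normal(800.0, 40.0, 100)
        r = 0.2 * float(np.std(x))
        ours = cardiac.approximate_entropy(x, m=2, r=r)
        theirs = apen_oracle(x.tolist(), 2, r)
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_shuffled_sine_has_higher_entropy(self, rng):
        t = np.arange(200)
        sine = 800.0 + 40.0 * np.sin(2 * np.pi * t / 12.0)
        shuffled = rng.permutation(sine)
        r = 0.2 * float(np.std(sine))
        assert cardiac.approximate_entropy(shuffled, 2, r) > cardiac.approximate_entropy(sine, 2, r)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            cardiac.approximate_entropy(np.arange(20.0))


class TestSachaCorrection:
    def test_unit_multiplier_is_identity(self):
        fd = {"lf": 1200.0, "hf": 400.0}
        out = cardiac.sacha_correction(fd, 1000.0)
        assert out["lf_c"] == pytest.approx(1200.0)
        assert out["hf_c"] == pytest.approx(400.0)

    def test_stated_multiplication(self):
        out = cardiac.sacha_correction({"lf": 0.01, "hf": 0.004}, 800.0)
        assert out["hf_c"] == pytest.approx(0.0032)

    def test_zero_hf_reported_missing(self):
        out = cardiac.sacha_correction({"lf": 1.0, "hf": 0.0}, 900.0)
        assert out["ln_hf_c"] is None
        assert out["lf_hf_ratio_c"] is None


class TestEndToEnd:
    def test_rr_mean_recovered_within_1ms(self, quiet_profile):
        rec = synth.generate_recording(
            quiet_profile, subject_id="S01", condition="Rest", duration=720.0,
            fs=250.0, master_seed=5, subject_index=0, condition_index=0,
            waveforms=True,
        )
        filtered = cardiac.filter_ecg(rec.ecg)
        peaks = cardiac.detect_r_peaks(filtered)
        rr = cardiac.correct_rr_intervals(RRSeries.from_beat_times(peaks.times))
        seg = cardiac.select_segment(rr, 660.0)
        truth_rr = cardiac.select_segment(
            RRSeries.from_beat_times(rec.truth_r_times), 660.0
        )
        ours = cardiac.hrv_time_domain(seg)["rr_mean"]
        truth = cardiac.hrv_time_domain(truth_rr)["rr_mean"]
        assert ours == pytest.approx(truth, abs=1.0)
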