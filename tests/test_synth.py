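"""Synthetic-cohort generator: determinism, ground truth, effect contract."""

import dataclasses

import numpy as np
import pytest

from cardioresp import cardiac, resp, synth
from cardioresp.channels import BreathEvents, RRSeries
from cardioresp.features import feature_table
from cardioresp.synth import CohortConfig, ConditionProfile, ProfileError

from oracles import band_fraction_periodogram


class TestGenerateRRSeries:
    def test_degenerate_profile_gives_constant_intervals(self):
        p = ConditionProfile(name="flat", mean_rr=1000, lf_depth=0, hf_depth=0,
                             rr_noise_sd=0)
        rr = synth.generate_rr_series(p, 300, seed=5)
        assert np.all(rr.intervals == 1000.0)
        assert np.std(rr.intervals) == 0.0

    def test_mean_rr_and_duration_bound(self, rest_profile):
        rr = synth.generate_rr_series(rest_profile, 660, seed=3)
        assert rr.intervals.mean() == pytest.approx(rest_profile.mean_rr, rel=0.02)
        assert rr.times[-1] <= 660.0

    def test_same_seed_is_bit_identical(self, rest_profile):
        a = synth.generate_rr_series(rest_profile, 300, seed=9)
        b = synth.generate_rr_series(rest_profile, 300, seed=9)
        np.testing.assert_array_equal(a.times, b.times)

    def test_single_hf_modulation_concentrates_band_power(self):
        # 0.25 Hz modulation only: nearly all LF+HF power must sit in HF,
        # checked with an independent rectangular-periodogram oracle
        p = ConditionProfile(name="hf", mean_rr=1000, lf_depth=0, hf_depth=40,
                             rr_noise_sd=0, hf_freq=0.25)
        rr = synth.generate_rr_series(p, 300, seed=1)
        frac = band_fraction_periodogram(
            rr.intervals.tolist(), 1.0, (0.15, 0.40), (0.04, 0.40)
        )
        assert frac > 0.95

    def test_invalid_profile_rejected(self):
        with pytest.raises(ProfileError):
            ConditionProfile(name="bad", mean_rr=100.0)
        with pytest.raises(ProfileError):
            ConditionProfile(name="bad", mean_rr=600.0, lf_depth=200.0,
                             hf_depth=100.0, rr_noise_sd=50.0)

    def test_short_duration_rejected(self, rest_profile):
        with pytest.raises(ValueError, match="duration"):
            synth.generate_rr_series(rest_profile, 60)


class TestSynthesizeECG:
    def test_regular_rhythm_recovers_60_bpm(self):
        r_times = np.arange(1.0, 31.0, 1.0)
        ecg = synth.synthesize_ecg(r_times, fs=250)
        peaks = cardiac.detect_r_peaks(cardiac.filter_ecg(ecg))
        rr = np.diff(peaks.times) * 1000.0
        assert np.mean(60000.0 / rr) == pytest.approx(60.0, abs=0.1)

    @pytest.mark.parametrize("mean_rr", [600.0, 850.0, 1100.0])
    def test_truth_recovery_within_one_sample(self, mean_rr):
        p = ConditionProfile(name="t", mean_rr=mean_rr, lf_depth=20, hf_depth=25,
                             rr_noise_sd=15, hr_entropy_mix=0.7)
        rr = synth.generate_rr_series(p, 240, seed=2)
        fs = 250.0
        ecg = synth.synthesize_ecg(rr.times, fs, duration=240)
        peaks = cardiac.detect_r_peaks(cardiac.filter_ecg(ecg))
        truth = rr.times[(rr.times >= 0.5) & (rr.times <= 239.5)]
        err = np.abs(truth[:, None] - peaks.times[None, :]).min(axis=1)
        assert truth.size == peaks.n
        assert np.max(err) <= 1.0 / fs + 1e-9

    def test_powerline_toggle_creates_and_filter_removes_mains_line(self):
        r_times = np.arange(1.0, 60.0, 0.9)
        dirty = synth.synthesize_ecg(r_times, fs=250, powerline=True, duration=60)
        clean = cardiac.filter_ecg(dirty)

        def amp_at_50(x, fs):
            t = np.arange(x.size) / fs
            c = np.cos(2 * np.pi * 50 * t)
            s = np.sin(2 * np.pi * 50 * t)
            return 2 * np.hypot(np.mean(x * c), np.mean(x * s))

        before = amp_at_50(dirty.samples, 250)
        after = amp_at_50(clean.samples, 250)
        assert before > 0.09  # injected 0.1-amplitude line present
        assert 20 * np.log10(before / after) >= 20.0

    def test_empty_r_times_rejected(self):
        with pytest.raises(ValueError):
            synth.synthesize_ecg(np.array([]), fs=250)


class TestSynthesizeRespiration:
    def test_symmetric_breaths_give_unit_phase_ratio(self):
        p = ConditionProfile(name="sym", ie_ratio=1.0, bb_jitter_sd=0.0,
                             resp_rate=15.0, resp_amp=100.0)
        w = synth.synthesize_respiration(p, 300, seed=4)
        events = resp.detect_breaths(resp.preprocess_respiration(w))
        feats = resp.resp_features(events, w)
        assert feats["phase_ratio"] == pytest.approx(1.0, abs=0.02)

    def test_amplitude_doubling_is_linear(self):
        base = ConditionProfile(name="a", resp_amp=100.0, bb_jitter_sd=0.0)
        double = dataclasses.replace(base, resp_amp=200.0)
        feats = {}
        for key, p in (("base", base), ("double", double)):
            w = synth.synthesize_respiration(p, 300, seed=6)
            ev = resp.detect_breaths(resp.preprocess_respiration(w))
            feats[key] = resp.resp_features(ev, resp.preprocess_respiration(w))
        ratio = feats["double"]["amplitude"] / feats["base"]["amplitude"]
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_bb_jitter_recovered_as_sdbb(self):
        p = ConditionProfile(name="j", bb_jitter_sd=200.0, resp_rate=15.0)
        truth = synth.generate_breath_truth(p, 660, seed=8)
        w = synth.render_respiration(truth, 660, 250)
        ev = resp.detect_breaths(resp.preprocess_respiration(w))
        sdbb = np.std(ev.bb_intervals, ddof=1)
        assert sdbb == pytest.approx(200.0, rel=0.15)

    def test_breath_count_matches_truth(self, quiet_profile):
        truth = synth.generate_breath_truth(quiet_profile, 660, seed=2)
        w = synth.render_respiration(truth, 660, 250)
        ev = resp.detect_breaths(resp.preprocess_respiration(w))
        assert ev.n_breaths == truth.peak_times.size


class TestGenerateCohort:
    def test_empty_cohort_is_valid(self):
        recs = synth.generate_cohort(CohortConfig(n_subjects=0))
        assert recs == []

    def test_determinism_bit_identical(self):
        cfg = CohortConfig(n_subjects=2, duration=240.0, master_seed=21)
        a = synth.generate_cohort(cfg, waveforms=True)
        b = synth.generate_cohort(cfg, waveforms=True)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.ecg.samples, rb.ecg.samples)
            np.testing.assert_array_equal(ra.thoracic.samples, rb.thoracic.samples)
            np.testing.assert_array_equal(ra.truth_r_times, rb.truth_r_times)

    def test_truth_intervals_match_generated_series(self, small_cohort):
        rec = small_cohort[0]
        rr = RRSeries.from_beat_times(rec.truth_r_times)
        assert np.all(rr.intervals > 0)
        np.testing.assert_allclose(
            np.diff(rec.truth_r_times) * 1000.0, rr.intervals, rtol=1e-12
        )

    def test_group_mean_heart_rates_near_targets(self, cohort_table):
        hr = cohort_table.groupby("condition")["heart_rate"].mean()
        assert hr["Rest"] == pytest.approx(69.25, abs=2.0)
        assert hr["SICT"] == pytest.approx(81.07, abs=2.0)

    def test_subject_effects_shared_across_conditions(self, small_cohort):
        # within-subject pairing: same random-effect multipliers in all
        # three of a subject's condition profiles
        by_subject = {}
        for rec in small_cohort:
            by_subject.setdefault(rec.subject_id, []).append(rec)
        for recs in by_subject.values():
            base = {c.condition: c.profile_used for c in recs}
            ratio_rest = base["Rest"].resp_amp / synth.DEFAULT_PROFILES["Rest"].resp_amp
            ratio_sict = base["SICT"].resp_amp / synth.DEFAULT_PROFILES["SICT"].resp_amp
            assert ratio_rest == pytest.approx(ratio_sict, rel=1e-12)


class TestEffectSizeContract:
    """Each injected condition contrast must surface with the right sign
    in its paired downstream feature at cohort level."""

    @pytest.mark.parametrize(
        "feature,direction",
        [
            ("heart_rate", +1),       # shorter mean RR -> faster heart rate
            ("hfn", -1),              # withdrawn HF modulation
            ("apen", -1),             # more regular tachogram
            ("amplitude_thoracic", +1),
            ("phase_ratio_thoracic", +1),
            ("sdbb_thoracic", +1),
        ],
    )
    def test_sict_contrast_sign(self, cohort_table, feature, direction):
        g = cohort_table.groupby("condition")[feature].mean()
        assert np.sign(g["SICT"] - g["Rest"]) == direction

    def test_imagination_matches_rest(self, cohort_table):
        g = cohort_table.groupby("condition")[["heart_rate", "hfn", "sdbb_thoracic"]].mean()
        for col in g.columns:
            # Imag is generated from the Rest profile: any difference is
            # sampling noise, bounded well below the SICT contrast
            sict_effect = abs(g.loc["SICT", col] - g.loc["Rest", col])
            imag_effect = abs(g.loc["Imag", col] - g.loc["Rest", col])
            assert imag_effect < 0.25 * sict_effect
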