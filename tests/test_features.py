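"""Index extraction: hand-computed examples, closed forms, generator
round-trips and Parseval-style conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from felicity import (ALPHA, BETA, ChannelTrace, NNSeries,
                      compute_alpha_asymmetry, compute_band_power,
                      compute_emg_rms, compute_hr, compute_hrv_spectrum,
                      compute_nn50, compute_pupil_mean,
                      compute_respiration_depth, compute_respiration_rate,
                      compute_rmssd, compute_sc_mean, detect_r_peaks,
                      extract_index_table, generate_emg, generate_nn_series,
                      generate_respiration, make_subject_profile, render_ecg,
                      synthesize_recording)
from felicity.cohort import default_epochs
from felicity.features import BandDefinition, _welch_psd, ExtractionError


def nn_from_intervals(nn_ms):
    times = np.concatenate([[0.0], np.cumsum(np.asarray(nn_ms) / 1000.0)])
    return NNSeries(times, np.asarray(nn_ms, dtype=float))


class TestTimeDomainHRV:
    def test_hr_closed_forms(self):
        assert compute_hr(nn_from_intervals([1000] * 10)) == pytest.approx(60)
        assert compute_hr(nn_from_intervals([500] * 10)) == pytest.approx(120)
        assert compute_hr(nn_from_intervals([800] * 10)) == pytest.approx(75)

    @pytest.mark.parametrize("nn,expected", [
        ([1000] * 6, 0),
        ([800, 860, 900, 960, 1000], 2),   # diffs 60, 40, 60, 40
        ([800, 851], 1),                   # strict > 50 boundary
        ([800, 850], 0),                   # exactly 50 does not count
    ])
    def test_nn50_hand_counts(self, nn, expected):
        assert compute_nn50(nn_from_intervals(nn)) == expected

    def test_rmssd_hand_computation(self):
        assert compute_rmssd(nn_from_intervals([1000] * 5)) == 0.0
        assert compute_rmssd(nn_from_intervals([1000, 1060, 1000])) == \
            pytest.approx(60.0)

    @given(st.lists(st.floats(min_value=300, max_value=2000), min_size=3,
                    max_size=50),
           st.floats(min_value=0.1, max_value=5.0))
    @settings(max_examples=100, deadline=None)
    def test_nn50_rmssd_match_naive_loop_and_scale(self, nn, c):
        series = nn_from_intervals(nn)
        n50 = sum(1 for a, b in zip(nn, nn[1:]) if abs(b - a) > 50)
        rmssd = (sum((b - a) ** 2 for a, b in zip(nn, nn[1:]))
                 / (len(nn) - 1)) ** 0.5
        assert compute_nn50(series) == n50
        assert compute_rmssd(series) == pytest.approx(rmssd, rel=1e-12)
        scaled = nn_from_intervals([v * c for v in nn])
        assert compute_rmssd(scaled) == pytest.approx(c * rmssd, rel=1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            compute_nn50(nn_from_intervals([1000]))


class TestSpectralHRV:
    def test_flat_tachogram_flags_ratio_undefined(self):
        spec = compute_hrv_spectrum(nn_from_intervals([1000] * 200))
        assert spec["lf"] < 1e-6 and spec["hf"] < 1e-6
        assert np.isnan(spec["lf_hf"])

    @pytest.mark.parametrize("lf_amp,hf_amp,dominant", [
        (50.0, 0.0, "lf"), (0.0, 50.0, "hf")])
    def test_single_modulation_concentrates_band(self, lf_amp, hf_amp,
                                                 dominant):
        nn = generate_nn_series(60, lf_amp, hf_amp, 0, 300, seed=1)
        spec = compute_hrv_spectrum(nn)
        assert spec[dominant] / (spec["lf"] + spec["hf"]) >= 0.90

    def test_band_sum_bounded_by_total_psd_integral(self):
        nn = generate_nn_series(70, 30, 20, 15, 300, seed=2)
        spec = compute_hrv_spectrum(nn)
        # recompute the full PSD integral on the same tachogram path
        from scipy import interpolate, signal as ssig
        t = nn.beat_times_s[1:]
        f = interpolate.interp1d(t, nn.nn_ms, kind="cubic")
        tt = np.arange(t[0], t[-1], 0.25)
        tach = ssig.detrend(f(tt))
        freqs, psd = _welch_psd(tach, 4.0, 128.0)
        total = np.trapezoid(psd, freqs)
        assert spec["vlf"] + spec["lf"] + spec["hf"] <= total * 1.01

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="120"):
            compute_hrv_spectrum(nn_from_intervals([1000] * 50))


class TestRPeakDetection:
    def test_unit_impulse_train_recovers_metronome(self):
        fs = 256.0
        x = np.zeros(int(30 * fs))
        x[((np.arange(28) + 0.5) * fs).astype(int)] = 1.0
        nn = detect_r_peaks(ChannelTrace("ecg", fs, x))
        assert np.allclose(nn.nn_ms, 1000.0, atol=1000 / fs)

    def test_template_ecg_roundtrip_within_one_sample(self):
        truth = generate_nn_series(70, 40, 25, 30, duration_s=300, seed=3)
        ecg = render_ecg(truth, fs=256)
        det = detect_r_peaks(ecg)
        # align: drop detections outside the true beat range
        assert abs(len(det.beat_times_s) - len(truth.beat_times_s)) <= 1
        m = min(len(det.nn_ms), len(truth.nn_ms))
        assert np.max(np.abs(det.nn_ms[:m] - truth.nn_ms[:m])) <= 1000 / 256

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="10 s"):
            detect_r_peaks(ChannelTrace("ecg", 256, np.zeros(5 * 256)))


class TestScalarChannels:
    def test_sc_mean_constant_masked_and_ramp(self):
        tr = ChannelTrace("gsr", 32, np.full(320, 5.0), "uS")
        assert compute_sc_mean(tr) == 5.0
        spiked = ChannelTrace("gsr", 32, np.r_[np.full(320, 5.0), [50.0]], "uS")
        mask = np.r_[np.zeros(320, bool), [True]]
        assert compute_sc_mean(spiked, mask) == 5.0
        ramp = ChannelTrace("gsr", 32, np.linspace(0, 10, 10001), "uS")
        assert compute_sc_mean(ramp) == pytest.approx(5.0)

    def test_sc_all_masked_rejected(self):
        tr = ChannelTrace("gsr", 32, np.ones(10), "uS")
        with pytest.raises(ValueError, match="masked"):
            compute_sc_mean(tr, np.ones(10, bool))

    def test_emg_rms_closed_forms(self):
        assert compute_emg_rms(ChannelTrace("e", 1024, np.zeros(1024))) == 0.0
        t = np.arange(10 * 1024) / 1024
        sine = ChannelTrace("e", 1024, 3.0 * np.sin(2 * np.pi * 50 * t))
        assert compute_emg_rms(sine) == pytest.approx(3.0 / np.sqrt(2), rel=0.01)
        burst = generate_emg(10.0, burst_rate=np.inf, fs=1024, duration_s=20,
                             seed=4)
        assert compute_emg_rms(burst) == pytest.approx(10.0, rel=0.10)

    def test_respiration_depth_and_rate(self):
        tr = generate_respiration(12, 2.0, fs=64, duration_s=120)
        assert compute_respiration_depth(tr) == pytest.approx(2.0, rel=0.02)
        assert compute_respiration_rate(tr) == pytest.approx(12.0, abs=0.5)
        slow = generate_respiration(6, 1.0, fs=64, duration_s=120)
        assert compute_respiration_rate(slow) == pytest.approx(6.0, abs=0.5)

    def test_alternating_depth_averages(self):
        # breath cycles alternating peak-to-trough 1 and 3 -> mean depth 2
        fs, f0 = 64.0, 0.25
        t = np.arange(int(120 * fs)) / fs
        cycle = np.floor(t * f0).astype(int)
        amp = np.where(cycle % 2 == 0, 0.5, 1.5)
        tr = ChannelTrace("rsp", fs, amp * np.sin(2 * np.pi * f0 * t))
        assert compute_respiration_depth(tr) == pytest.approx(2.0, rel=0.05)

    def test_flat_respiration_rejected(self):
        with pytest.raises(ValueError, match="flat|cycles"):
            compute_respiration_depth(ChannelTrace("rsp", 64, np.zeros(6400)))

    def test_pupil_mean_with_blinks_and_ramp(self):
        tr = ChannelTrace("p", 60, np.full(600, 4.0), "mm")
        assert compute_pupil_mean(tr) == 4.0
        x = np.full(600, 4.0)
        x[::10] = 0.0  # 10% zero dropouts
        assert compute_pupil_mean(ChannelTrace("p", 60, x)) == pytest.approx(4.0)
        ramp = ChannelTrace("p", 60, np.linspace(3, 5, 601), "mm")
        assert compute_pupil_mean(ramp) == pytest.approx(4.0)

    def test_pupil_all_blinked_rejected(self):
        with pytest.raises(ValueError, match="blink"):
            compute_pupil_mean(ChannelTrace("p", 60, np.zeros(60)))


class TestBandPower:
    def test_pure_alpha_tone(self):
        fs = 128.0
        t = np.arange(int(60 * fs)) / fs
        tr = ChannelTrace("eeg", fs, np.sin(2 * np.pi * 10 * t))
        pa = compute_band_power(tr, ALPHA)
        pb = compute_band_power(tr, BETA)
        total = 0.5  # variance of a unit sinusoid
        assert pa / total >= 0.99
        assert pb < 0.01 * total

    def test_two_tone_ratio_matches_parseval(self):
        fs = 128.0
        t = np.arange(int(120 * fs)) / fs
        a, b = 2.0, 0.5
        x = a * np.sin(2 * np.pi * 10 * t) + b * np.sin(2 * np.pi * 20 * t)
        tr = ChannelTrace("eeg", fs, x)
        ratio = compute_band_power(tr, ALPHA) / compute_band_power(tr, BETA)
        assert ratio == pytest.approx(a ** 2 / b ** 2, rel=0.05)

    def test_zero_trace_and_nyquist_guard(self):
        assert compute_band_power(ChannelTrace("e", 128, np.zeros(1280)),
                                  ALPHA) == 0.0
        with pytest.raises(ValueError, match="Nyquist"):
            compute_band_power(ChannelTrace("e", 50, np.zeros(1000)), BETA)

    def test_masked_artifact_segments_do_not_change_power(self):
        fs = 128.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * t)
        clean = compute_band_power(ChannelTrace("e", fs, x), ALPHA)
        spiked = np.r_[x, np.full(int(2 * fs), 80.0)]
        mask = np.r_[np.zeros(len(x), bool), np.ones(int(2 * fs), bool)]
        masked = compute_band_power(ChannelTrace("e", fs, spiked), ALPHA,
                                    mask=mask)
        assert masked == pytest.approx(clean, rel=0.02)


class TestAlphaAsymmetry:
    def test_identity_and_antisymmetry(self):
        fs = 128.0
        t = np.arange(int(60 * fs)) / fs
        rng = np.random.default_rng(5)
        x = np.sin(2 * np.pi * 10 * t) + 0.1 * rng.standard_normal(len(t))
        left = ChannelTrace("l", fs, x)
        right = ChannelTrace("r", fs, 2.0 * x)
        assert compute_alpha_asymmetry(left, left) == 0.0
        lr = compute_alpha_asymmetry(left, right)
        rl = compute_alpha_asymmetry(right, left)
        assert lr == pytest.approx(-rl)
        assert lr == pytest.approx(np.log(4.0), rel=0.02)

    def test_zero_power_rejected(self):
        flat = ChannelTrace("l", 128, np.zeros(128 * 30))
        with pytest.raises(ValueError, match="zero alpha"):
            compute_alpha_asymmetry(flat, flat)


@pytest.fixture(scope="module")
def small_cohort():
    epochs = default_epochs(150.0)
    return [synthesize_recording(
        make_subject_profile("happiness_true", seed=10 + i),
        list(epochs), seed=20 + i, subject_id=f"s{i:02d}")
        for i in range(4)]


class TestIndexTable:
    def test_structure_and_completeness(self, small_cohort):
        tab = extract_index_table(small_cohort)
        assert len(tab) == 12
        assert not tab.isna().any().any()

    def test_noise_free_means_follow_hypothesis_signs(self, small_cohort):
        tab = extract_index_table(small_cohort)
        m = tab.groupby("epoch").mean(numeric_only=True)
        assert m.loc["relax", "SC"] < m.loc["happiness", "SC"]
        assert m.loc["relax", "SC"] < m.loc["stress", "SC"]
        assert m.loc["stress", "emg_zyg"] < m.loc["happiness", "emg_zyg"]
        assert m.loc["happiness", "hf_power"] > m.loc["relax", "hf_power"]

    def test_missing_epoch_rejected(self, small_cohort):
        rec = small_cohort[0]
        broken = type(rec)(subject_id="bad", nn=rec.nn,
                           channels={k: v for k, v in rec.channels.items()
                                     if k != "gsr"},
                           epochs=rec.epochs, seed=0)
        with pytest.raises(ExtractionError, match="bad"):
            extract_index_table([broken])
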