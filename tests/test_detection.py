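"""Band-pass filtering, sonogram conventions, call and click detection."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pupcalls as pc
from pupcalls.detection import (
    ClickEvent,
    Sonogram,
    bandpass,
    compute_sonogram,
    detect_calls,
    detect_clicks,
    filter_clicks_outside_calls,
    frame_features,
    include_recording,
)
from pupcalls.evaluate import detection_scores

from conftest import FS, render_tone


class TestBandpass:
    def _tone(self, freq, fs=FS, dur=0.1):
        t = np.arange(int(dur * fs)) / fs
        return np.sin(2 * np.pi * freq * t)

    def test_passband_tone_preserved_within_1db(self):
        x = self._tone(70_000)
        y = bandpass(x, FS)
        core = slice(5000, -5000)
        gain_db = 20 * np.log10(np.std(y[core]) / np.std(x[core]))
        assert abs(gain_db) < 1.0

    def test_stopband_tone_attenuated_40db(self):
        x = self._tone(10_000)
        y = bandpass(x, FS)
        core = slice(5000, -5000)
        atten_db = -20 * np.log10(np.std(y[core]) / np.std(x[core]))
        assert atten_db >= 40.0

    def test_white_noise_matches_fft_mask_oracle(self):
        # independent oracle: ideal brick-wall masking in the frequency domain
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2**18)
        y = bandpass(x, FS)
        spec = np.fft.rfft(x)
        f = np.fft.rfftfreq(x.size, 1 / FS)
        spec[(f < 25_000) | (f > 110_000)] = 0
        oracle = np.fft.irfft(spec, n=x.size)
        assert np.var(y) == pytest.approx(np.var(oracle), rel=0.03)

    def test_zero_phase_no_onset_shift(self):
        x = render_tone(onset_s=0.1, seed=3)
        y = bandpass(x, FS)
        i_true = int(0.1 * FS)
        i_found = np.argmax(np.abs(y) > 0.5 * np.max(np.abs(y)))
        assert abs(i_found - i_true) < int(0.002 * FS)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            bandpass(np.zeros(1000), 200_000)


class TestSonogram:
    def test_reported_resolutions_at_250khz(self):
        son = compute_sonogram(np.random.default_rng(0).standard_normal(FS // 4), FS)
        assert son.reported_time_resolution_ms == 1.02
        assert son.reported_freq_resolution_khz == 0.98
        assert son.time_step == pytest.approx(256 / FS)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            compute_sonogram(np.zeros(100), FS)

    def test_constant_tone_has_constant_argmax(self):
        t = np.arange(FS // 10) / FS
        son = compute_sonogram(np.sin(2 * np.pi * 70_000 * t), FS)
        peaks = son.freqs[np.argmax(son.power, axis=1)]
        assert np.all(peaks == peaks[0])
        assert abs(peaks[0] - 70_000) < FS / 512

    def test_power_scales_quadratically_with_amplitude(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(FS // 10)
        p1 = compute_sonogram(x, FS).power.sum()
        p2 = compute_sonogram(2 * x, FS).power.sum()
        assert p2 == pytest.approx(4 * p1, rel=1e-4)

    def test_axes_cover_zero_to_nyquist(self):
        son = compute_sonogram(np.zeros(4096), FS)
        assert son.freqs[0] == 0
        assert son.freqs[-1] == FS / 2


def _toy_sonogram(power):
    power = np.asarray(power, dtype=np.float32)
    nf = power.shape[1]
    return Sonogram(
        power=power,
        times=(np.arange(power.shape[0]) + 1) * 256 / FS,
        freqs=np.linspace(0, FS / 2, nf),
        fs=FS,
        block=2 * (nf - 1),
    )


class TestFrameFeatures:
    def test_single_hot_bin_purity_one(self):
        son = _toy_sonogram([[0, 5, 0, 0], [0, 0, 0, 0]])
        f = frame_features(son)
        assert f.purity[0] == 1.0
        assert f.purity[1] == 0.0  # all-zero frame: purity defined as 0

    def test_flat_spectrum_purity_is_one_over_n(self):
        son = _toy_sonogram([np.ones(8)])
        assert frame_features(son).purity[0] == pytest.approx(1 / 8)

    def test_identical_adjacent_frames_zero_discontinuity(self):
        son = _toy_sonogram([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]])
        d = frame_features(son).discontinuity
        assert d[0] == pytest.approx(0.0, abs=1e-6)
        assert d[1] > 0.1

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_purity_invariant_under_uniform_scaling(self, scale):
        base = np.array([[1.0, 3.0, 0.5, 2.0]])
        p0 = frame_features(_toy_sonogram(base)).purity[0]
        p1 = frame_features(_toy_sonogram(base * scale)).purity[0]
        assert p1 == pytest.approx(p0, rel=1e-4)

    def test_mean_freq_is_power_weighted(self):
        son = _toy_sonogram([[0, 1, 0, 1]])
        f = frame_features(son)
        expected = (son.freqs[1] + son.freqs[3]) / 2
        assert f.mean_freq[0] == pytest.approx(expected)


class TestDetectCalls:
    def test_silence_yields_no_calls(self):
        rng = np.random.default_rng(0)
        son = compute_sonogram(rng.standard_normal(FS // 2) * 0.01, FS)
        assert detect_calls(son) == []

    def test_single_tone_boundaries_within_2ms(self):
        x = render_tone(duration_s=0.05, onset_s=0.1, seed=4)
        son = compute_sonogram(bandpass(x, FS), FS)
        calls = detect_calls(son)
        assert len(calls) == 1
        assert calls[0].onset == pytest.approx(0.100, abs=0.002)
        assert calls[0].offset == pytest.approx(0.150, abs=0.002)

    def test_segments_disjoint_and_sorted(self, short_analysis):
        iv = short_analysis.intervals
        assert np.all(iv[1:, 0] >= iv[:-1, 1])
        assert np.all(np.diff(iv[:, 0]) > 0)

    def test_recall_and_precision_on_synthetic_audio(self, short_recording, short_analysis):
        _, _, truth = short_recording
        sc = detection_scores(truth.call_intervals, short_analysis.intervals)
        assert sc.recall >= 0.95
        assert sc.precision >= 0.95
        assert sc.onset_mae_s <= 0.002
        assert sc.offset_mae_s <= 0.002

    def test_invalid_thresholds_rejected(self):
        son = _toy_sonogram([np.ones(4)])
        with pytest.raises(ValueError):
            detect_calls(son, purity_threshold=0.0)


class TestDetectClicks:
    def test_tonal_frame_is_not_click(self):
        x = render_tone(duration_s=0.05, onset_s=0.1, seed=5)
        son = compute_sonogram(bandpass(x, FS), FS)
        calls = detect_calls(son)
        clicks = filter_clicks_outside_calls(detect_clicks(son), calls)
        assert clicks == []

    def test_broadband_burst_is_click(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(FS // 4) * 0.005
        i0 = int(0.1 * FS)
        x[i0 : i0 + 500] += rng.standard_normal(500) * 0.5  # 2 ms loud burst
        son = compute_sonogram(x, FS)
        clicks = detect_clicks(son)
        assert len(clicks) == 1
        assert clicks[0].time == pytest.approx(0.1, abs=0.005)

    def test_injected_click_count_recovered(self, wt8):
        # ~10 clicks in 30 s; detected count within +/- 1 of truth
        noisy = dataclasses.replace(wt8, click_rate=0.33)
        meta = pc.RecordingMeta("c", "WT", 8, duration=30.0)
        wave, truth = pc.synth_recording(noisy, meta, seed=12)
        an = pc.analyze_audio(wave, FS, meta)
        assert truth.click_times  # the configuration did plant clicks
        assert abs(an.n_clicks - len(truth.click_times)) <= 1


class TestInclusionRule:
    @pytest.mark.parametrize("n,expected", [(9, False), (10, True), (0, False)])
    def test_minimum_call_count(self, n, expected):
        assert include_recording(n) is expected
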