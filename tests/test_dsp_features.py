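"""Feature-extraction stages: hand-computed oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcheart.dsp_features import (
    FEATURE_IDS,
    BoundaryConfig,
    EnvelopeSignal,
    MelConfig,
    SmoothingConfig,
    build_feature_tensor,
    butterworth_lowpass,
    compute_threshold,
    detect_fhs_boundaries,
    fix_duration,
    hilbert_envelope,
    log_mel_spectrogram,
    mean_peak_interval,
    mel_filterbank,
    mel_inverse,
    mel_scale,
    normalize_amplitude,
    smooth,
    split_channels,
)
from mcheart.synthetic_pcg import SynthSpec, generate_recording


class TestNormalize:
    def test_forced_values(self):
        assert np.allclose(
            normalize_amplitude(np.array([2.0, -4.0, 1.0])), [0.5, -1.0, 0.25]
        )

    def test_idempotent(self, rng):
        x = normalize_amplitude(rng.normal(size=100))
        assert np.allclose(normalize_amplitude(x), x)
        assert np.max(np.abs(x)) == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_amplitude(np.zeros(10))


class TestButterworth:
    def test_dc_unit_gain(self):
        x = np.full(4000, 0.7)
        y = butterworth_lowpass(x, 150.0, 2, 4000)
        assert np.allclose(y[500:-500], 0.7, atol=1e-6)

    def test_passband_tone_preserved(self):
        t = np.arange(0, 10, 1 / 4000)
        y = butterworth_lowpass(np.sin(2 * np.pi * 10 * t), 150.0, 2, 4000)
        rms = np.sqrt(np.mean(y[4000:-4000] ** 2))
        assert abs(rms - 1 / np.sqrt(2)) < 0.01 / np.sqrt(2)

    def test_stopband_tone_attenuated(self):
        t = np.arange(0, 10, 1 / 4000)
        y = butterworth_lowpass(np.sin(2 * np.pi * 1000 * t), 150.0, 2, 4000)
        assert np.max(np.abs(y[4000:-4000])) < 0.05

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            butterworth_lowpass(np.zeros(100), 2500.0, 2, 4000)


class TestHilbertEnvelope:
    def test_pure_tone_envelope_is_amplitude(self):
        t = np.arange(0, 2, 1 / 4000)
        env = hilbert_envelope(3.0 * np.sin(2 * np.pi * 50 * t), 4000)
        assert np.allclose(env.values[400:-400], 3.0, rtol=0.02)

    def test_zero_signal_zero_envelope(self):
        assert np.all(hilbert_envelope(np.zeros(100), 4000).values == 0.0)

    def test_am_tone_tracks_modulator(self):
        t = np.arange(0, 5, 1 / 4000)
        modulator = 1 + 0.5 * np.cos(2 * np.pi * 2 * t)
        env = hilbert_envelope(modulator * np.sin(2 * np.pi * 100 * t), 4000)
        interior = slice(4000, -4000)
        err = np.sqrt(np.mean((env.values[interior] - modulator[interior]) ** 2))
        assert err / np.sqrt(np.mean(modulator[interior] ** 2)) < 0.05


class TestSmooth:
    def test_impulse_ramp(self):
        assert np.allclose(
            smooth(np.array([0.0, 0, 6, 0, 0]), 3), [0, 0, 2, 2, 2]
        )

    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=50)
        assert np.array_equal(smooth(x, 1), x)

    def test_constant_signal_startup_ramp(self):
        y = smooth(np.ones(6), SmoothingConfig(3))
        assert np.allclose(y, [1 / 3, 2 / 3, 1, 1, 1, 1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=60),
        st.integers(1, 10),
    )
    def test_total_variation_contraction(self, values, n):
        """Moving-average smoothing never increases the total variation of
        the zero-embedded signal (boundary jumps counted)."""
        x = np.array(values)
        y = smooth(x, n)
        tv = lambda a: abs(a[0]) + np.abs(np.diff(a)).sum() + abs(a[-1])
        assert tv(y) <= tv(x) + 1e-9


class TestThresholdAndBoundaries:
    def test_constant_envelope(self):
        assert compute_threshold(np.array([1.0, 1, 1, 1])) == pytest.approx(1.0)

    def test_hand_computed_values(self):
        assert compute_threshold(np.array([0.0, 2, 0, 2])) == pytest.approx(2.0)
        assert compute_threshold(np.array([0.0, 0, 3, 3, 0, 0])) == pytest.approx(
            1 + np.sqrt(2)
        )

    def test_threshold_matches_two_pass_oracle(self, rng):
        for _ in range(100):
            v = rng.gamma(2.0, 1.0, size=rng.integers(10, 500))
            mean = v.sum() / v.size
            var = ((v - mean) ** 2).sum() / v.size
            oracle = mean + np.sqrt(var)
            assert abs(compute_threshold(v) - oracle) <= 1e-9 * abs(oracle)

    def test_mask_elementwise_comparison(self):
        env = EnvelopeSignal(np.array([0.0, 0, 3, 3, 0, 0]), 4000)
        mask = detect_fhs_boundaries(env, 1 + np.sqrt(2)).mask
        assert np.array_equal(mask, [0, 0, 1, 1, 0, 0])

    def test_threshold_extremes(self):
        env = EnvelopeSignal(np.array([0.5, 1.0, 2.0]), 4000)
        assert np.all(detect_fhs_boundaries(env, 0.0).mask == 1)
        assert np.all(detect_fhs_boundaries(env, 5.0).mask == 0)

    def test_cleanup_fills_gaps_and_drops_speckle(self):
        rate = 1000  # 20 ms = 20 samples
        env = np.zeros(200)
        env[50:100] = 3.0  # real lobe
        env[52:54] = 0.1  # small gap inside it (2 ms)
        env[150:155] = 3.0  # 5 ms speckle
        mask = detect_fhs_boundaries(
            EnvelopeSignal(env, rate), 1.0, BoundaryConfig(0.02, 0.01)
        ).mask
        assert np.all(mask[50:100] == 1)
        assert np.all(mask[150:155] == 0)

    def test_split_channels_partition_identity(self, rng):
        v = rng.gamma(1.0, 1.0, size=300)
        m = (rng.random(300) < 0.4).astype(float)
        env = EnvelopeSignal(v, 4000)
        from mcheart.dsp_features import BoundaryMask

        fhs, murmur = split_channels(env, BoundaryMask(m))
        assert np.array_equal(fhs + murmur, v)
        assert np.all(fhs[m == 0] == 0) and np.all(murmur[m == 1] == 0)

    def test_split_channels_length_mismatch_rejected(self):
        from mcheart.dsp_features import BoundaryMask

        with pytest.raises(ValueError):
            split_channels(
                EnvelopeSignal(np.ones(5), 4000), BoundaryMask(np.ones(4))
            )


class TestMelScale:
    def test_anchor_values(self):
        assert mel_scale(0.0) == 0.0
        assert mel_scale(700.0) == pytest.approx(2595 * np.log10(2), rel=1e-12)
        assert mel_scale(1400.0) == pytest.approx(2595 * np.log10(3), rel=1e-12)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            mel_scale(-1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0, 1999), st.floats(0.01, 2000))
    def test_strictly_increasing(self, f, step):
        assert mel_scale(f + step) > mel_scale(f)

    def test_inverse_round_trip(self):
        f = np.linspace(0, 2000, 50)
        assert np.allclose(mel_inverse(mel_scale(f)), f)

    def test_filterbank_centers_strictly_increasing(self):
        _, centers = mel_filterbank(MelConfig(n_mels=40, rate=4000))
        assert np.all(np.diff(centers) > 0)


class TestLogMelSpectrogram:
    def test_frame_count_formula(self, rng):
        x = rng.normal(size=200000)  # 50 s at 4000 Hz
        cfg = MelConfig(window=512, hop=256, n_mels=40, rate=4000)
        out = log_mel_spectrogram(x, cfg)
        assert out.shape == (40, 1 + (200000 - 512) // 256)

    def test_pure_tone_peaks_at_matching_band(self):
        t = np.arange(0, 10, 1 / 4000)
        cfg = MelConfig(n_mels=140, rate=4000)
        out = log_mel_spectrogram(np.sin(2 * np.pi * 100 * t), cfg)
        _, centers = mel_filterbank(cfg)
        band = int(out.mean(axis=1).argmax())
        spacing = np.diff(centers).max()
        assert abs(centers[band] - 100.0) <= max(spacing, 10.0)

    def test_ref_max_tops_out_at_zero_db(self, rng):
        out = log_mel_spectrogram(
            rng.normal(size=8000), MelConfig(n_mels=30, rate=4000)
        )
        assert out.max() == pytest.approx(0.0, abs=1e-9)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            log_mel_spectrogram(np.zeros(100), MelConfig(rate=4000))


class TestMeanPeakInterval:
    def test_burst_train_interval_recovered(self):
        rate = 4000
        x = np.zeros(10 * rate)
        burst = np.hanning(400) * np.sin(2 * np.pi * 80 * np.arange(400) / rate)
        for k in range(20):
            x[k * 2000 : k * 2000 + 400] += burst
        assert mean_peak_interval(x, rate) == pytest.approx(0.5, abs=0.02)

    def test_single_burst_returns_duration_sentinel(self):
        rate = 4000
        x = np.zeros(4 * rate)
        x[100:500] = np.hanning(400)
        assert mean_peak_interval(x, rate) == pytest.approx(4.0)

    def test_murmur_shortens_interval_on_matched_cohorts(self):
        """Murmur energy between the S1/S2 lobes adds peaks, so the mean
        interval of murmur-free recordings exceeds the matched murmur mean
        (a cohort-level direction; single pairs can tie)."""
        ia, ip = [], []
        for i in range(10):
            a = generate_recording(SynthSpec(seed=300 + i, murmur="none"))
            p = generate_recording(SynthSpec(seed=300 + i, murmur="systolic"))
            ia.append(mean_peak_interval(a.recording.samples, 4000))
            ip.append(mean_peak_interval(p.recording.samples, 4000))
        assert np.mean(ia) > np.mean(ip)


class TestFixDuration:
    def test_exact_length_unchanged(self, rng):
        x = rng.normal(size=200000)
        assert np.array_equal(fix_duration(x, 4000, 50.0), x)

    def test_short_signal_tiled(self, rng):
        x = rng.normal(size=40000)  # 10 s
        out = fix_duration(x, 4000, 50.0)
        assert out.shape == (200000,)
        assert np.array_equal(out, np.tile(x, 5))

    def test_long_signal_cropped_from_start(self, rng):
        x = rng.normal(size=240000)  # 60 s
        assert np.array_equal(fix_duration(x, 4000, 50.0), x[:200000])

    def test_trim_applied_both_ends(self):
        x = np.arange(100.0)
        out = fix_duration(x, 10, 1.0, trim=20)
        assert out[0] == 20.0 and out.size == 10

    def test_excessive_trim_rejected(self):
        with pytest.raises(ValueError):
            fix_duration(np.zeros(100), 10, 1.0, trim=50)


class TestBuildFeatureTensor:
    @pytest.mark.parametrize(
        "feature_id,n_channels,has_pi",
        [(9, 2, True), (1, 1, True), (3, 3, True), (7, 3, True), (12, 2, False)],
    )
    def test_channel_and_scalar_counts(
        self, clean_recording, feature_id, n_channels, has_pi
    ):
        from dataclasses import replace

        fs = replace(FEATURE_IDS[feature_id], sample_sec=10.0)
        t = build_feature_tensor(clean_recording.recording, fs)
        assert t.channels.shape[0] == n_channels
        assert ("mean_peak_interval" in t.scalars) == has_pi
        assert len({c.shape for c in t.channels}) == 1

    def test_murmur_channel_hotter_with_murmur(self, murmur_pair):
        from dataclasses import replace

        absent, present = murmur_pair
        fs = replace(FEATURE_IDS[5], sample_sec=10.0)  # spec + PI + murmurs
        ta = build_feature_tensor(absent.recording, fs)
        tp = build_feature_tensor(present.recording, fs)
        i = fs.channel_names.index("murmurs")
        assert tp.channels[i].mean() > ta.channels[i].mean()

    def test_pipeline_channel_partition_identity(self):
        res = generate_recording(SynthSpec(seed=3, murmur="systolic"))
        r = res.recording
        xn = normalize_amplitude(fix_duration(r.samples, r.rate, 10.0))
        env = hilbert_envelope(butterworth_lowpass(xn, 150, 2, r.rate), r.rate)
        mask = detect_fhs_boundaries(env, compute_threshold(env), BoundaryConfig())
        fhs, murmur = split_channels(env, mask)
        assert np.array_equal(fhs + murmur, env.values)

    def test_spurious_runs_decrease_with_smoothing(self):
        """Stronger envelope smoothing removes threshold speckle, the reason
        the murmur channels benefit from the moving average."""
        res = generate_recording(SynthSpec(seed=5, murmur="systolic", snr_db=15.0))
        r = res.recording
        env0 = hilbert_envelope(
            butterworth_lowpass(normalize_amplitude(r.samples), 150, 2, r.rate),
            r.rate,
        )
        counts = []
        for n in (20, 40, 70):
            env = EnvelopeSignal(smooth(env0.values, n), r.rate)
            mask = detect_fhs_boundaries(
                env, compute_threshold(env), BoundaryConfig()
            ).mask
            counts.append(int((np.diff(np.concatenate([[0], mask, [0]])) == 1).sum()))
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[2] < counts[0]
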