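"""Augmentation operators: identity behavior, formula contracts, policy."""

import numpy as np
import pytest
from scipy.signal import welch
from scipy.stats import kstest

from lungsound.augment import (DEFAULT_OPS, AugmentOp, IntensityPolicy,
                               attack_coefficient, colored_noise, cutmix,
                               dynamic_range_compress, formant_shift,
                               freq_dropout, mixup, pitch_shift, room_reverb,
                               sample_policy, spec_augment, time_stretch, vtlp)

FS = 22050


def tone(freq, seconds=2.0, fs=FS):
    return np.sin(2 * np.pi * freq * np.arange(int(seconds * fs)) / fs)


def dominant_freq(x, fs=FS):
    return np.fft.rfftfreq(x.size, 1 / fs)[np.abs(np.fft.rfft(x)).argmax()]


class TestTimeStretch:
    def test_unit_rate_is_identity(self):
        x = tone(440)
        np.testing.assert_array_equal(time_stretch(x, 1.0), x)

    def test_output_length_formula(self):
        x = np.random.default_rng(0).normal(size=132300)
        assert time_stretch(x, 0.8).size == round(132300 / 0.8) == 165375

    def test_pitch_preserved_under_stretch(self):
        y = time_stretch(tone(440), 1.2)
        assert abs(dominant_freq(y) - 440) < 5

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            time_stretch(tone(440), -1.0)


class TestPitchShift:
    def test_zero_shift_is_identity(self):
        x = tone(440)
        np.testing.assert_array_equal(pitch_shift(x, 0), x)

    def test_two_semitones_up(self):
        y = pitch_shift(tone(440), 2)
        assert abs(dominant_freq(y) - 440 * 2 ** (2 / 12)) < 5

    def test_length_always_preserved(self):
        x = tone(440)
        for n in (-2, -0.5, 1, 2):
            assert pitch_shift(x, n).size == x.size


class TestDynamicRangeCompression:
    def test_attack_coefficient_formula(self):
        assert attack_coefficient(1.0, 1.0) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_zero_input_fixed_point(self):
        np.testing.assert_array_equal(
            dynamic_range_compress(np.zeros(1000)), np.zeros(1000))

    def test_step_envelope_monotone_toward_one(self):
        x = np.ones(4000)
        # reconstruct the envelope: gain = threshold/g once g passes threshold
        out = dynamic_range_compress(x, t_attack=0.005, t_release=0.05,
                                     sample_rate=FS, threshold=0.5)
        g = np.where(out < 1.0, 0.5 / out, np.nan)
        valid = np.isfinite(g)
        assert np.all(np.diff(g[valid]) >= -1e-12)
        assert g[valid][-1] == pytest.approx(1.0, abs=1e-3)

    def test_quiet_signal_untouched(self):
        x = 0.1 * tone(200, 0.2)
        np.testing.assert_allclose(dynamic_range_compress(x), x, atol=1e-12)

    def test_invalid_time_constant(self):
        with pytest.raises(ValueError):
            dynamic_range_compress(np.ones(10), t_attack=0.0)


class TestVTLP:
    def test_identity_warp(self):
        spec = np.random.default_rng(1).random((64, 10))
        np.testing.assert_allclose(vtlp(spec, 1.0), spec, atol=1e-12)

    def test_energy_moves_to_alpha_times_frequency(self):
        spec = np.zeros((256, 4))
        spec[100] = 1.0
        out = vtlp(spec, 1.1)
        centroid = (np.arange(256) @ out[:, 0]) / out[:, 0].sum()
        assert abs(centroid - 110) < 1.5

    def test_shape_preserved(self):
        spec = np.random.default_rng(2).random((128, 65))
        assert vtlp(spec, 0.85).shape == spec.shape


class TestFormantShift:
    def test_identity(self):
        mag = np.random.default_rng(3).random(128)
        np.testing.assert_array_equal(formant_shift(mag, 1.0), mag)

    def test_floor_indexing(self):
        mag = np.arange(128, dtype=float)
        out = formant_shift(mag, 1.1)
        assert out[10] == mag[int(np.floor(10 * 1.1))] == mag[11]

    def test_impulse_index_inversion(self):
        mag = np.zeros(64)
        mag[9] = 1.0
        out = formant_shift(mag, 0.9)
        assert out[10] == 1.0  # floor(10 * 0.9) = 9

    def test_out_of_range_reads_zero(self):
        mag = np.ones(64)
        out = formant_shift(mag, 1.5)
        assert np.all(out[43:] == 0)  # floor(k * 1.5) >= 64 for k >= 43


class TestFreqDropout:
    def test_p_zero_identity(self):
        spec = np.random.default_rng(4).random((32, 16))
        np.testing.assert_array_equal(
            freq_dropout(spec, 0.0, np.random.default_rng(0)), spec)

    def test_p_one_zeroes_everything(self):
        spec = np.ones((32, 16))
        assert np.all(freq_dropout(spec, 1.0, np.random.default_rng(0)) == 0)

    def test_dropout_fraction_matches_probability(self):
        spec = np.ones((400, 250))  # 1e5 cells
        out = freq_dropout(spec, 0.1, np.random.default_rng(5))
        frac = np.mean(out == 0)
        assert abs(frac - 0.1) < 0.01


class TestMixupCutmix:
    def test_mixup_endpoints_and_midpoint(self):
        xi, xj = np.array([1.0, 1.0]), np.array([0.0, 0.0])
        yi, yj = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        full = mixup(xi, xj, yi, yj, lam=1.0)
        np.testing.assert_array_equal(full.data, xi)
        np.testing.assert_array_equal(full.mixed_label, yi)
        mid = mixup(xi, xj, yi, yj, lam=0.5)
        np.testing.assert_array_equal(mid.data, [0.5, 0.5])

    def test_mixup_lambda_distribution_symmetric(self):
        rng = np.random.default_rng(6)
        lams = rng.beta(0.4, 0.4, size=10000)
        assert abs(lams.mean() - 0.5) < 0.02

    def test_mixup_label_convexity(self):
        rng = np.random.default_rng(7)
        xi, xj = rng.normal(size=100), rng.normal(size=100)
        out = mixup(xi, xj, np.array([1.0, 0.0]), np.array([0.0, 1.0]), rng=rng)
        assert out.mixed_label.sum() == pytest.approx(1.0)
        assert np.all(out.mixed_label >= 0)

    def test_cutmix_coverage(self):
        rng = np.random.default_rng(8)
        xi, xj = np.zeros(10000), np.ones(10000)
        out = cutmix(xi, xj, np.array([1.0, 0.0]), np.array([0.0, 1.0]),
                     coverage=0.30, rng=rng)
        assert abs(np.mean(out.data == 1.0) - 0.30) <= 1e-4 + 1 / 10000
        np.testing.assert_allclose(out.mixed_label, [0.7, 0.3], atol=1e-9)

    def test_cutmix_identical_sources(self):
        x = np.random.default_rng(9).normal(size=500)
        out = cutmix(x, x, np.array([1.0, 0.0]), np.array([1.0, 0.0]),
                     rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out.data, x)

    def test_cutmix_start_positions_uniform(self):
        n, m = 1000, 300
        starts = [cutmix(np.zeros(n), np.ones(n), np.array([1.0, 0.0]),
                         np.array([0.0, 1.0]), rng=np.random.default_rng(s)
                         ).applied_ops[0][1]["start"]
                  for s in range(300)]
        stat = kstest(np.array(starts) / (n - m), "uniform")
        assert stat.pvalue > 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mixup(np.zeros(3), np.zeros(4), np.array([1.0]), np.array([1.0]))


class TestRoomReverb:
    def test_zero_tail_scales_input(self):
        x = np.random.default_rng(10).normal(size=1000)
        out = room_reverb(x, amplitude=0.7, decay=10.0, ir_duration=0.0)
        np.testing.assert_allclose(out, 0.7 * x, atol=1e-12)

    def test_impulse_recovers_impulse_response(self):
        rng = np.random.default_rng(11)
        x = np.zeros(22050)
        x[0] = 1.0
        out = room_reverb(x, amplitude=0.5, decay=20.0, ir_duration=0.3,
                          rng=np.random.default_rng(11))
        h_len = int(0.3 * FS)
        t = np.arange(h_len) / FS
        eta = np.ones(h_len)
        eta[1:] = np.random.default_rng(11).standard_normal(h_len - 1)
        np.testing.assert_allclose(out[:h_len], 0.5 * np.exp(-20 * t) * eta, atol=1e-9)

    def test_impulse_response_envelope_decay_rate(self):
        x = np.zeros(22050)
        x[0] = 1.0
        gamma = 30.0
        out = room_reverb(x, amplitude=1.0, decay=gamma, ir_duration=0.3,
                          rng=np.random.default_rng(12))
        h_len = int(0.3 * FS)
        t = np.arange(1, h_len) / FS
        log_env = np.log(np.abs(out[1:h_len]) + 1e-300)
        slope = np.polyfit(t, log_env, 1)[0]
        assert abs(slope - (-gamma)) < 0.15 * gamma


class TestColoredNoise:
    def test_sigma_zero_identity(self):
        x = tone(100, 0.1)
        np.testing.assert_array_equal(colored_noise(x, "white", 0.0), x)

    def test_white_noise_std_near_target(self):
        x = np.zeros(100000)
        out = colored_noise(x, "white", 0.01, np.random.default_rng(13))
        assert abs(out.std() - 0.01) / 0.01 < 0.05

    def test_brown_vs_white_psd_slope(self):
        n = 2 ** 17
        rng = np.random.default_rng(14)
        white = colored_noise(np.zeros(n), "white", 0.01, rng)
        brown = colored_noise(np.zeros(n), "brown", 0.01, rng)
        slopes = []
        for sig in (white, brown):
            f, p = welch(sig, fs=1.0, nperseg=4096)
            keep = (f > 1e-3) & (f < 0.4)
            slopes.append(np.polyfit(np.log10(f[keep]), 10 * np.log10(p[keep]), 1)[0])
        # brown is -20 dB/decade steeper than white
        assert abs((slopes[1] - slopes[0]) - (-20)) < 4

    def test_unknown_color(self):
        with pytest.raises(ValueError):
            colored_noise(np.zeros(10), "violet", 0.01)


class TestSpecAugment:
    def test_zero_caps_identity(self):
        spec = np.random.default_rng(15).random((30, 40))
        np.testing.assert_array_equal(
            spec_augment(spec, 0, 0, np.random.default_rng(0)), spec)

    def test_masked_cells_zero_others_unchanged(self):
        spec = np.random.default_rng(16).random((128, 65)) + 1.0  # strictly positive
        out = spec_augment(spec, 15, 25, np.random.default_rng(1))
        changed = out != spec
        assert np.all(out[changed] == 0)
        zero_rows = np.flatnonzero(np.all(out == 0, axis=1))
        zero_cols = np.flatnonzero(np.all(out == 0, axis=0))
        assert zero_rows.size <= 15 and zero_cols.size <= 25
        if zero_rows.size:
            assert np.all(np.diff(zero_rows) == 1)  # one contiguous band

    def test_cap_clipped_with_warning(self):
        spec = np.ones((8, 8))
        with pytest.warns(UserWarning):
            spec_augment(spec, 30, 40, np.random.default_rng(2))


class TestPolicy:
    def test_intensity_table(self):
        assert IntensityPolicy("light").op_count_range == (1, 2)
        assert IntensityPolicy("light").scale_factor == 0.5
        assert IntensityPolicy("medium").op_count_range == (2, 4)
        assert IntensityPolicy("heavy").op_count_range == (3, 6)
        assert IntensityPolicy("heavy").scale_factor == 1.5
        with pytest.raises(ValueError):
            IntensityPolicy("extreme")

    @pytest.mark.parametrize("level,count_range,factor",
                             [("light", (1, 2), 0.5), ("heavy", (3, 6), 1.5)])
    def test_sampled_counts_and_scaled_ranges(self, level, count_range, factor):
        policy = IntensityPolicy(level)
        rng = np.random.default_rng(17)
        for _ in range(50):
            drawn = sample_policy(DEFAULT_OPS, policy, rng)
            assert count_range[0] <= len(drawn) <= count_range[1]
            for op, params in drawn:
                for name, value in params.items():
                    lo, hi, neutral = op.params[name]
                    s_lo = neutral + factor * (lo - neutral)
                    s_hi = neutral + factor * (hi - neutral)
                    assert min(s_lo, s_hi) - 1e-12 <= value <= max(s_lo, s_hi) + 1e-12

    def test_fixed_seed_reproducible(self):
        policy = IntensityPolicy("medium")
        a = sample_policy(DEFAULT_OPS, policy, np.random.default_rng(42))
        b = sample_policy(DEFAULT_OPS, policy, np.random.default_rng(42))
        assert [(op.name, params) for op, params in a] == \
               [(op.name, params) for op, params in b]

    def test_pairwise_ops_ordered_last(self):
        policy = IntensityPolicy("heavy")
        rng = np.random.default_rng(18)
        for _ in range(30):
            drawn = sample_policy(DEFAULT_OPS, policy, rng)
            domains = [op.domain for op, _ in drawn]
            if "pairwise" in domains:
                first = domains.index("pairwise")
                assert all(d == "pairwise" for d in domains[first:])

    def test_empty_op_list_rejected(self):
        with pytest.raises(ValueError):
            sample_policy([], IntensityPolicy("light"), np.random.default_rng(0))


class TestPathologyBandPreservation:
    """Light-intensity single operators keep a 500 Hz wheeze peak in band."""

    @pytest.mark.parametrize("op_name", ["time_stretch", "dynamic_range_compress",
                                         "room_reverb", "colored_noise"])
    def test_waveform_ops_preserve_wheeze_band(self, op_name):
        from lungsound.synthdata import synth_wheeze
        rng = np.random.default_rng(19)
        x = synth_wheeze(2.0, (450.0, 550.0), rng)
        policy = IntensityPolicy("light")
        op = next(o for o in DEFAULT_OPS if o.name == op_name)
        params = {k: (lo + hi) / 2 for k, (lo, hi) in
                  op.scaled_params(policy.scale_factor).items()}
        if op_name == "time_stretch":
            y = time_stretch(x, 1.1)
        elif op_name == "dynamic_range_compress":
            y = dynamic_range_compress(x, params["t_attack"], params["t_release"])
        elif op_name == "room_reverb":
            y = room_reverb(x, params["amplitude"], params["decay"], rng=rng)
        else:
            y = colored_noise(x, "white", 0.005, rng)
        assert 400 <= dominant_freq(y) <= 600

    def test_small_pitch_shift_preserves_band(self):
        from lungsound.synthdata import synth_wheeze
        x = synth_wheeze(2.0, (450.0, 550.0), np.random.default_rng(20))
        y = pitch_shift(x, 1.0)  # light intensity keeps |n| <= 1
        assert 400 <= dominant_freq(y) <= 600
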