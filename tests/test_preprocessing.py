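"""Stance segmentation, filtering, time normalization, per-participant
standardization, rescaling and feature assembly."""

import logging

import numpy as np
import pytest
from scipy.interpolate import PchipInterpolator

from gaitprint import (
    PipelineConfig,
    assemble,
    build_stride_patterns,
    detect_stance,
    feature_index,
    feature_unindex,
    lowpass,
    patterns_matrix,
    rescale_unit,
    standardize_participant,
    time_normalize,
)
from gaitprint.channels import CHANNELS, N_FEATURES, N_SAMPLES
from gaitprint.synthetic import TrialRecord


class TestDetectStance:
    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="no stance"):
            detect_stance(np.zeros(1000), rate=2400.0)

    def test_brute_force_threshold_scan(self):
        v = np.zeros(600)
        v[100:500] = 800.0
        seg = detect_stance(v, rate=2400.0)
        assert (seg.heel_strike_index, seg.toe_off_index) == (100, 500)
        # brute-force oracle: first/last index at or above threshold
        above = np.flatnonzero(v >= 15.0)
        assert seg.heel_strike_index == above[0]
        assert seg.toe_off_index == above[-1] + 1

    def test_short_noise_spikes_rejected(self):
        v = np.zeros(2000)
        v[500:1300] = 700.0
        v[50:60] = 400.0  # 10-sample spike < 50 ms at 2400 Hz
        seg = detect_stance(v, rate=2400.0)
        assert (seg.heel_strike_index, seg.toe_off_index) == (500, 1300)

    def test_multiple_qualifying_runs_strict_error(self):
        v = np.zeros(3000)
        v[100:800] = 500.0
        v[1500:2400] = 500.0
        with pytest.raises(ValueError, match="single step"):
            detect_stance(v, rate=2400.0)
        seg = detect_stance(v, rate=2400.0, strict=False)
        assert (seg.heel_strike_index, seg.toe_off_index) == (1500, 2400)

    def test_round_trip_with_rendered_raw_trial(self, tiny_truth):
        from gaitprint import generate_trial, render_raw

        for seed in range(5):
            trial = generate_trial(tiny_truth, 2, 1, trial_seed=100 + seed)
            raw = render_raw(trial, pad_noise_amp=5.0, seed=seed)
            seg = detect_stance(raw.grf[2], raw.force_rate)
            assert (seg.heel_strike_index, seg.toe_off_index) == raw.intended_stance


class TestLowpass:
    def test_dc_gain_one(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(lowpass(x, 240.0, 15.0), x, atol=1e-9)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(2400) / 240.0
        x = np.sin(2 * np.pi * 1.5 * t)  # cutoff / 10
        y = lowpass(x, 240.0, 15.0)
        mid = slice(240, 2160)
        assert np.max(np.abs(y[mid] - x[mid])) < 0.01

    def test_stopband_attenuation_40db(self):
        t = np.arange(4800) / 240.0
        x = np.sin(2 * np.pi * 45.0 * t)  # 3 x cutoff
        y = lowpass(x, 240.0, 15.0)
        assert np.max(np.abs(y[480:-480])) < 0.01  # >= 40 dB down

    def test_minus_3db_at_cutoff(self):
        t = np.arange(9600) / 240.0
        x = np.sin(2 * np.pi * 15.0 * t)
        y = lowpass(x, 240.0, 15.0)
        amp = np.max(np.abs(y[2400:-2400]))
        assert amp == pytest.approx(1.0 / np.sqrt(2.0), abs=0.02)

    def test_zero_phase_no_shift(self):
        # a symmetric bump stays centered after filtering
        n = 480
        x = np.exp(-0.5 * ((np.arange(n) - 240) / 30.0) ** 2)
        y = lowpass(x, 240.0, 15.0)
        assert abs(int(np.argmax(y)) - 240) <= 1

    def test_cutoff_at_nyquist_errors(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(np.zeros(100), 240.0, 120.0)


class TestTimeNormalize:
    def test_constant(self):
        out = time_normalize(np.full(53, 2.5))
        assert out.shape == (100,)
        np.testing.assert_allclose(out, 2.5, atol=1e-12)

    def test_linear_ramp_reproduced(self):
        out = time_normalize(np.linspace(0.0, 1.0, 240))
        np.testing.assert_allclose(out, np.linspace(0.0, 1.0, 100), atol=1e-12)

    def test_endpoints_exact(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(57)
        out = time_normalize(y)
        assert out[0] == y[0] and out[-1] == y[-1]

    def test_monotone_no_overshoot_vs_oracle(self):
        # step-like monotone input: output bounded by input range and equal
        # to an independently constructed PCHIP oracle
        y = np.concatenate([np.zeros(20), np.linspace(0, 1, 5), np.ones(20)])
        out = time_normalize(y)
        assert out.min() >= 0.0 - 1e-12 and out.max() <= 1.0 + 1e-12
        oracle = PchipInterpolator(np.arange(y.size), y)(
            np.linspace(0, y.size - 1, 100)
        )
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            time_normalize(np.array([1.0, 2.0, 3.0]))


class TestStandardize:
    def test_two_point_standardization(self):
        t = np.array([[+2.0], [-2.0]])
        out = standardize_participant(t)
        # mean 0; sample SD (ddof=1) of {+2,-2} is 2*sqrt(2), so values are
        # +-1/sqrt(2) ... with two trials the z-scores are +-0.707
        np.testing.assert_allclose(out, [[+2 / (2 * np.sqrt(2))], [-2 / (2 * np.sqrt(2))]])

    def test_identical_trials_floored_to_zero(self, caplog):
        t = np.tile(np.linspace(0, 1, 10), (3, 1))
        with caplog.at_level(logging.WARNING, logger="gaitprint.preprocessing"):
            out = standardize_participant(t)
        np.testing.assert_array_equal(out, 0.0)
        assert any("floored" in r.message for r in caplog.records)

    def test_known_mean_sd_recovered(self):
        rng = np.random.default_rng(4)
        t = rng.normal(3.0, 2.0, size=(40, 25))
        out = standardize_participant(t)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_single_trial_errors(self):
        with pytest.raises(ValueError, match=">= 2"):
            standardize_participant(np.ones((1, 10)))

    def test_scalar_mode_uses_one_sd(self):
        rng = np.random.default_rng(9)
        t = rng.standard_normal((20, 30)) * np.linspace(1, 5, 30)
        out = standardize_participant(t, sd_mode="scalar")
        # per-sample SDs are NOT all 1 in scalar mode
        assert np.std(out.std(axis=0, ddof=1)) > 0.1


class TestRescale:
    def test_divides_by_max_abs(self):
        t = np.array([[1.0, -4.0], [2.0, 0.5]])
        np.testing.assert_allclose(rescale_unit(t), t / 4.0)

    def test_all_zero_left_alone(self, caplog):
        with caplog.at_level(logging.WARNING, logger="gaitprint.preprocessing"):
            out = rescale_unit(np.zeros((3, 5)))
        np.testing.assert_array_equal(out, 0.0)

    def test_max_abs_exactly_one_and_odd_symmetry(self):
        rng = np.random.default_rng(2)
        t = rng.standard_normal((10, 50)) * 3.3
        out = rescale_unit(t)
        assert np.max(np.abs(out)) == 1.0
        np.testing.assert_allclose(rescale_unit(-t), -out)


class TestAssemble:
    def test_index_bookkeeping(self):
        channels = {c: np.full(N_SAMPLES, k / 12.0) for k, c in enumerate(CHANNELS)}
        pattern = assemble(channels, subject_id=0, day=1, trial_id="t")
        for k in range(12):
            np.testing.assert_array_equal(
                pattern.features[100 * k : 100 * k + 100], k / 12.0
            )

    def test_index_utility_round_trip(self):
        for i in range(N_FEATURES):
            c, s = feature_unindex(i)
            assert feature_index(c, s) == i

    def test_missing_channel_errors(self):
        channels = {c: np.zeros(N_SAMPLES) for c in CHANNELS[:-1]}
        with pytest.raises(ValueError, match="missing"):
            assemble(channels, 0, 1, "t")


def _mini_trials(rng, n_subjects=2, n_trials=4, offset=None, gain=None):
    """Tiny processed trials; optional per-participant offset/gain on one channel."""
    trials = []
    for subject in range(n_subjects):
        for k in range(n_trials):
            channels = {}
            for c in CHANNELS:
                n = 53 if not c.startswith("grf") else 530
                x = np.sin(np.linspace(0, 3, n) + subject) + rng.normal(0, 0.3, n)
                if c == "knee_flex_ext":
                    if offset is not None:
                        x = x + offset * (subject + 1)
                    if gain is not None:
                        x = x * gain ** (subject + 1)
                channels[c] = x
            trials.append(TrialRecord(subject, 1, f"s{subject}t{k}", channels))
    return trials


class TestPipeline:
    def test_deterministic(self):
        t1 = _mini_trials(np.random.default_rng(0))
        t2 = _mini_trials(np.random.default_rng(0))
        X1, _ = patterns_matrix(build_stride_patterns(t1))
        X2, _ = patterns_matrix(build_stride_patterns(t2))
        np.testing.assert_array_equal(X1, X2)

    def test_features_in_unit_interval(self):
        X, _ = patterns_matrix(build_stride_patterns(_mini_trials(np.random.default_rng(1))))
        assert X.shape[1] == N_FEATURES
        assert X.min() >= -1.0 and X.max() <= 1.0

    @pytest.mark.parametrize("kind", ["offset", "gain"])
    def test_body_size_effects_eliminated(self, kind):
        # adding a per-participant constant offset or multiplicative gain to
        # a raw channel leaves the stride patterns unchanged (to fp roundoff)
        base = _mini_trials(np.random.default_rng(3))
        changed = _mini_trials(
            np.random.default_rng(3),
            offset=37.0 if kind == "offset" else None,
            gain=2.5 if kind == "gain" else None,
        )
        X0, _ = patterns_matrix(build_stride_patterns(base))
        X1, _ = patterns_matrix(build_stride_patterns(changed))
        np.testing.assert_allclose(X1, X0, atol=1e-9)


class TestPatternIO:
    def test_save_load_round_trip(self, tmp_path):
        trials = _mini_trials(np.random.default_rng(7))
        from gaitprint import load_stride_patterns, save_stride_patterns

        patterns = build_stride_patterns(trials)
        path = tmp_path / "patterns.csv"
        save_stride_patterns(patterns, path)
        loaded = load_stride_patterns(path)
        assert [p.trial_id for p in loaded] == [p.trial_id for p in patterns]
        X0, y0 = patterns_matrix(patterns)
        X1, y1 = patterns_matrix(loaded)
        np.testing.assert_allclose(X1, X0, atol=1e-12)
        np.testing.assert_array_equal(y1, y0)
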