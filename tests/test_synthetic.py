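"""Generator contracts: planted structure, determinism, noise statistics,
rigid-marker invariants and the dataset writer round trip."""

import numpy as np
import pytest
from scipy import stats

from gaitprint import (
    SyntheticSpec,
    desk_scale_spec,
    generate_dataset,
    generate_templates,
    generate_trial,
    load_dataset_tables,
    planted_indices,
    render_raw,
    write_dataset,
)
from gaitprint.channels import ANGLE_CHANNELS, CHANNELS, window_samples
from gaitprint.synthetic import _smooth_noise


class TestSpecValidation:
    def test_rejects_bad_window(self):
        with pytest.raises(ValueError, match="window"):
            desk_scale_spec(planted_window=(0.5, 0.2))

    def test_rejects_negative_effect(self):
        with pytest.raises(ValueError, match="effect_size"):
            desk_scale_spec(effect_size=-1.0)

    def test_rejects_unknown_planted_channel(self):
        with pytest.raises(ValueError, match="unknown"):
            desk_scale_spec(planted_channels=("hip_ab_ad", "nope"))


class TestTemplates:
    def test_zero_effect_all_subjects_identical_with_warning(self):
        spec = desk_scale_spec(effect_size=0.0)
        with pytest.warns(UserWarning, match="unidentifiable"):
            truth = generate_templates(spec)
        s = np.linspace(0, 1, 101)
        for c in CHANNELS:
            t0 = truth.subject_template(0, c, s)
            for subject in range(1, spec.n_subjects):
                np.testing.assert_array_equal(truth.subject_template(subject, c, s), t0)

    def test_planted_deviation_energy_confined_to_window(self):
        spec = desk_scale_spec(
            seed=3, planted_channels=("hip_ab_ad",), planted_window=(0.0, 0.3)
        )
        truth = generate_templates(spec)
        s = (np.arange(100) + 0.5) / 100  # sample centers, 1% bins
        inside = np.zeros(100, dtype=bool)
        inside[list(window_samples(spec.planted_window))] = True
        total_dev = np.zeros(100)
        for c in CHANNELS:
            dev_sq = np.zeros(100)
            for subject in range(spec.n_subjects):
                dev = truth.subject_template(subject, c, s) - truth.subject_template(
                    0, c, s
                )
                dev_sq += dev**2
            if c != "hip_ab_ad":
                assert dev_sq.sum() == 0.0
            else:
                total_dev = dev_sq
        assert total_dev[inside].sum() >= 0.95 * total_dev.sum() > 0

    def test_determinism_bit_identical(self):
        spec = desk_scale_spec(seed=12)
        t1, t2 = generate_templates(spec), generate_templates(spec)
        s = np.linspace(0, 1, 77)
        for subject in range(spec.n_subjects):
            for c in CHANNELS:
                np.testing.assert_array_equal(
                    t1.subject_template(subject, c, s), t2.subject_template(subject, c, s)
                )

    def test_planted_variable_set_matches_index_utility(self, tiny_truth, tiny_spec):
        expected = planted_indices(tiny_spec.planted_channels, tiny_spec.planted_window)
        assert tiny_truth.planted_variable_set == tuple(expected)


class TestTrials:
    def test_unknown_subject_errors(self, tiny_truth):
        with pytest.raises(KeyError):
            generate_trial(tiny_truth, subject_id=999, day=1, trial_seed=0)

    def test_trial_reproducible_from_seed(self, tiny_truth):
        a = generate_trial(tiny_truth, 0, 1, trial_seed=5)
        b = generate_trial(tiny_truth, 0, 1, trial_seed=5)
        for c in CHANNELS:
            np.testing.assert_array_equal(a[c], b[c])

    def test_noise_free_trial_equals_template(self):
        spec = desk_scale_spec(
            noise_sigma={c: 0.0 for c in CHANNELS}, effect_size=0.0, day2_drift=0.0,
            planted_channels=(),
        )
        truth = generate_templates(spec)
        trial = generate_trial(truth, 0, 1, trial_seed=1)
        for c in CHANNELS:
            n = len(trial[c])
            s = np.linspace(0, 1, n)
            np.testing.assert_allclose(trial[c], truth.subject_template(0, c, s), atol=1e-12)

    def test_per_sample_noise_sd_matches_sigma(self):
        # Monte-Carlo: across many trials of one subject (no planted modes,
        # fixed stance length via zero spread) the per-sample SD matches the
        # stated sigma within 10%
        spec = desk_scale_spec(
            n_subjects=2, effect_size=0.0, planted_channels=(), stance_sd=0.0
        )
        truth = generate_templates(spec)
        trials = [generate_trial(truth, 0, 1, trial_seed=s) for s in range(500)]
        c = "hip_flex_ext"
        X = np.stack([t[c] for t in trials])
        sd = X.std(axis=0, ddof=1)
        assert np.all(np.abs(sd - 1.5) / 1.5 < 0.10)

    def test_day2_without_drift_matches_day1_distribution(self):
        # KS test on a per-trial summary statistic, not rejected at alpha=0.01
        spec = desk_scale_spec(n_subjects=2, day2_drift=0.0, stance_sd=0.0)
        truth = generate_templates(spec)
        stat = lambda t: float(np.mean(t["knee_flex_ext"]))
        a = [stat(generate_trial(truth, 0, 1, trial_seed=s)) for s in range(120)]
        b = [stat(generate_trial(truth, 0, 2, trial_seed=s + 10_000)) for s in range(120)]
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_smooth_noise_marginal_sd_exact(self):
        rng = np.random.default_rng(0)
        x = np.stack([_smooth_noise(np.random.default_rng(i), 200, 2.0, 8.0) for i in range(800)])
        sd = x.std(axis=0, ddof=1)
        assert np.all(np.abs(sd - 2.0) / 2.0 < 0.12)


class TestDiscriminabilityPlacement:
    def test_between_within_ratio_maximal_in_planted_set(self, tiny_spec, tiny_truth):
        # brute-force per-variable discriminability on time-normalized (not
        # participant-standardized) features
        from gaitprint.preprocessing import lowpass, time_normalize

        rng = np.random.default_rng(1)
        feats, labels = [], []
        for subject in range(tiny_spec.n_subjects):
            for k in range(12):
                trial = generate_trial(
                    tiny_truth, subject, 1, trial_seed=int(rng.integers(2**31))
                )
                rows = []
                for c in CHANNELS:
                    rate = 240.0 if c in ANGLE_CHANNELS else 2400.0
                    cut = 15.0 if c in ANGLE_CHANNELS else 50.0
                    rows.append(time_normalize(lowpass(trial[c], rate, cut)))
                feats.append(np.concatenate(rows))
                labels.append(subject)
        X, y = np.stack(feats), np.array(labels)
        grand = X.mean(axis=0)
        between = np.zeros(X.shape[1])
        within = np.zeros(X.shape[1])
        for subject in np.unique(y):
            block = X[y == subject]
            between += len(block) * (block.mean(axis=0) - grand) ** 2
            within += ((block - block.mean(axis=0)) ** 2).sum(axis=0)
        score = between / within
        planted = np.array(tiny_truth.planted_variable_set)
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[planted] = True
        assert score.argmax() in planted
        # planted variables dominate the top of the ranking (the lowpass
        # smears some deviation energy just past the window edge)
        top = np.argsort(-score)[: len(planted) // 2]
        assert mask[top].mean() > 0.8


class TestRawRendering:
    def test_marker_distances_rigid(self, tiny_truth):
        trial = generate_trial(tiny_truth, 0, 1, trial_seed=3)
        raw = render_raw(trial)
        for seg, block in raw.marker_blocks.items():
            d0 = np.linalg.norm(block[0][:, None] - block[0][None, :], axis=-1)
            for t in range(1, block.shape[0], 7):
                dt = np.linalg.norm(block[t][:, None] - block[t][None, :], axis=-1)
                np.testing.assert_allclose(dt, d0, atol=1e-10)

    def test_vertical_force_threshold_contract(self, tiny_truth):
        trial = generate_trial(tiny_truth, 1, 1, trial_seed=4)
        raw = render_raw(trial, pad_noise_amp=5.0, seed=2)
        a, b = raw.intended_stance
        v = raw.grf[2]
        assert np.all(v[a:b] >= 15.0)
        assert np.all(v[:a] < 15.0) and np.all(v[b:] < 15.0)
        assert np.all(v >= 0.0)


class TestDatasetIO:
    def test_dataset_determinism(self):
        spec = desk_scale_spec(seed=5, n_subjects=3, trials_per_day=4)
        d1, d2 = generate_dataset(spec), generate_dataset(spec)
        assert len(d1.trials) == len(d2.trials) == 3 * 8
        for t1, t2 in zip(d1.trials, d2.trials):
            assert t1.trial_id == t2.trial_id
            for c in CHANNELS:
                np.testing.assert_array_equal(t1.channels[c], t2.channels[c])

    def test_trials_per_day_range_respects_bounds(self):
        spec = SyntheticSpec(n_subjects=6, trials_per_day=(29, 40), seed=2)
        ds = generate_dataset(spec)
        for subject in range(6):
            n1 = sum(1 for t in ds.trials if t.subject_id == subject and t.day == 1)
            n2 = sum(1 for t in ds.trials if t.subject_id == subject and t.day == 2)
            assert 29 <= n1 + n2 <= 40
            assert max(n1, n2) <= 20

    def test_write_load_round_trip(self, tmp_path):
        spec = desk_scale_spec(seed=9, n_subjects=2, trials_per_day=3)
        ds = generate_dataset(spec)
        out = write_dataset(ds, tmp_path / "data")
        trials, manifest = load_dataset_tables(out)
        assert manifest["seed"] == 9
        assert len(trials) == len(ds.trials)
        for orig, loaded in zip(ds.trials, trials):
            assert loaded.subject_id == orig.subject_id
            for c in CHANNELS:
                np.testing.assert_allclose(loaded.channels[c], orig.channels[c], atol=1e-12)
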