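"""Augmentation operators: dataset-statistics ranges and composition algebra."""

import numpy as np
import pytest
from scipy import stats as sps

from nirsbreath.augment import (
    AugmentConfig,
    AugmentStats,
    amplitude_scale,
    augment,
    augment_batch,
    compute_aug_stats,
    dc_offset,
    horizontal_flip,
    sample_beta,
    sample_gamma,
)
from nirsbreath.nirs_io import WindowedSample


def w(data, label=0, pid="p"):
    return WindowedSample(data=np.atleast_2d(np.asarray(data, dtype=float)),
                          label=label, participant_id=pid)


def pooled_stats(samples):
    return compute_aug_stats(samples, per_channel=False)


class TestStats:
    def test_singleton_dataset(self):
        s = pooled_stats([w([0.0, 1.0, 2.0])])
        assert s.min_of_min == s.max_of_min == 0
        assert s.min_of_max == s.max_of_max == 2
        assert s.min_ptp == s.max_ptp == 2

    def test_two_sample_hand_enumeration(self):
        a, b = w([0.0, 1.0]), w([-1.0, 3.0])
        s = pooled_stats([a, b])
        assert (s.min_of_min, s.max_of_min) == (-1, 0)
        assert (s.min_of_max, s.max_of_max) == (1, 3)
        assert (s.min_ptp, s.max_ptp) == (1, 4)
        # permutation invariance of extrema
        s2 = pooled_stats([b, a])
        assert (s2.min_of_min, s2.max_of_max, s2.min_ptp) == (-1, 3, 1)

    def test_per_channel_stats_shape(self):
        s = compute_aug_stats([w(np.arange(8).reshape(2, 4))], per_channel=True)
        assert s.min_of_min.shape == (2,)
        np.testing.assert_array_equal(s.min_of_min, [0, 4])

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            compute_aug_stats([])

    def test_leakage_guard(self):
        samples = [w([0.0, 1.0], pid="train1"), w([0.0, 1.0], pid="heldout")]
        with pytest.raises(ValueError, match="heldout"):
            compute_aug_stats(samples, forbid_participants={"heldout"})


class TestSampling:
    def test_beta_singleton_dataset_is_identity(self, rng):
        win = w([0.0, 2.0])
        s = pooled_stats([win])
        assert sample_beta(s, win, rng) == pytest.approx(0.0)

    def test_beta_interval_by_substitution(self, rng):
        # dataset extrema -1/3, window range [0, 2] -> beta in [-1, 1]
        s = pooled_stats([w([-1.0, 3.0]), w([0.0, 2.0])])
        win = w([0.0, 2.0])
        draws = np.array([sample_beta(s, win, rng) for _ in range(500)])
        assert draws.min() >= -1 and draws.max() <= 1
        assert draws.min() < -0.9 and draws.max() > 0.9  # spans the interval

    def test_beta_keeps_window_inside_dataset_envelope(self, rng):
        samples = [w(rng.normal(size=6)) for _ in range(10)]
        s = pooled_stats(samples)
        for win in samples:
            b = sample_beta(s, win, rng)
            assert win.data.min() + b >= s.min_of_min - 1e-12
            assert win.data.max() + b <= s.max_of_max + 1e-12

    def test_gamma_degenerate_interval(self, rng):
        s = pooled_stats([w([0.0, 2.0])])
        assert sample_gamma(s, rng) == pytest.approx(2.0)

    def test_gamma_all_constant_dataset_falls_back_to_one(self, rng):
        s = pooled_stats([w([1.0, 1.0])])
        assert sample_gamma(s, rng) == pytest.approx(1.0)

    def test_gamma_uniform_over_ptp_interval(self, rng):
        s = pooled_stats([w([0.0, 0.4]), w([0.0, 2.3])])
        draws = np.array([sample_gamma(s, rng) for _ in range(10_000)])
        assert draws.min() >= 0.4 and draws.max() <= 2.3
        p = sps.kstest(draws, sps.uniform(loc=0.4, scale=1.9).cdf).pvalue
        assert p > 0.01

    def test_gamma_ratio_mode_bounds_scaled_ptp(self, rng):
        samples = [w(rng.normal(size=8)) for _ in range(6)]
        s = pooled_stats(samples)
        win = samples[0]
        g = sample_gamma(s, rng, mode="ratio", window=win)
        scaled_ptp = np.ptp(win.data) * g
        assert s.min_ptp - 1e-12 <= scaled_ptp <= s.max_ptp + 1e-12


class TestOperators:
    def test_dc_offset_elementwise(self):
        out = dc_offset(w([1.0, 2.0, 3.0]), -0.5)
        np.testing.assert_allclose(out.data, [[0.5, 1.5, 2.5]])

    def test_dc_offset_per_channel_constants(self):
        # each channel shifted by exactly its own constant
        betas = np.array([0.004, -0.012, -0.007, 0.005])
        win = w(np.zeros((4, 10)))
        out = dc_offset(win, betas)
        np.testing.assert_allclose(out.data, np.tile(betas[:, None], (1, 10)))

    def test_scale_elementwise_and_ptp_linearity(self):
        out = amplitude_scale(w([0.0, 1.0, -1.0]), 2.0)
        np.testing.assert_allclose(out.data, [[0.0, 2.0, -2.0]])
        assert np.ptp(out.data) == pytest.approx(2 * 2.0)

    def test_identity_parameters(self):
        win = w([0.3, -0.1, 0.7])
        assert np.array_equal(dc_offset(win, 0.0).data, win.data)
        assert np.array_equal(amplitude_scale(win, 1.0).data, win.data)
        assert np.array_equal(horizontal_flip(win, force=False).data, win.data)

    def test_flip_reverses_and_is_involution(self):
        win = w([1.0, 2.0, 3.0])
        flipped = horizontal_flip(win, force=True)
        np.testing.assert_allclose(flipped.data, [[3.0, 2.0, 1.0]])
        np.testing.assert_allclose(
            horizontal_flip(flipped, force=True).data, win.data
        )

    def test_flip_frequency_half(self, rng):
        win = w([1.0, 2.0])
        n_flip = sum(
            horizontal_flip(win, rng, p=0.5).data[0, 0] == 2.0 for _ in range(10_000)
        )
        assert n_flip / 10_000 == pytest.approx(0.5, abs=0.01)

    def test_label_and_shape_preserved(self, rng):
        win = w(np.arange(12).reshape(3, 4), label=2)
        for out in (dc_offset(win, 1.0), amplitude_scale(win, 0.5),
                    horizontal_flip(win, rng)):
            assert out.data.shape == win.data.shape
            assert out.label == 2


class TestComposition:
    def test_hand_composed_example(self):
        # scale 2: [0,1] -> [0,2]; offset 1 -> [1,3]; flip -> [3,1]
        win = w([0.0, 1.0])
        out = horizontal_flip(dc_offset(amplitude_scale(win, 2.0), 1.0), force=True)
        np.testing.assert_allclose(out.data, [[3.0, 1.0]])

    def test_neutral_composition_is_identity(self):
        win = w([0.2, -0.4, 0.9])
        out = horizontal_flip(dc_offset(amplitude_scale(win, 1.0), 0.0), force=False)
        np.testing.assert_array_equal(out.data, win.data)

    def test_composite_operator_preserves_shape_and_label(self, rng):
        samples = [w(rng.normal(size=(2, 16)), label=i % 4, pid=f"p{i}")
                   for i in range(6)]
        stats = compute_aug_stats(samples)
        cfg = AugmentConfig()
        for win in samples:
            out = augment(win, stats, cfg, rng)
            assert out.data.shape == win.data.shape
            assert out.label == win.label

    def test_singleton_composite_without_flip_is_near_identity(self, rng):
        # singleton dataset: gamma fixed to its own ptp != 1, so only check
        # that beta sampled post-scaling recentres into the envelope
        win = w([0.0, 1.0])
        stats = pooled_stats([win])
        cfg = AugmentConfig(flip_probability=0.0)
        out = augment(win, stats, cfg, rng)
        assert out.data.min() >= stats.min_of_min - 1e-12
        assert out.data.max() <= stats.max_of_max + 1e-12


class TestBatchAugment:
    def test_batch_matches_operator_invariants(self, rng):
        X = rng.normal(size=(32, 4, 24))
        samples = [w(x) for x in X]
        stats = compute_aug_stats(samples, per_channel=True)
        # ratio mode keeps the scaled peak-to-peak inside the dataset range,
        # so the offset interval never inverts and containment is guaranteed
        out = augment_batch(X, stats, AugmentConfig(gamma_mode="ratio"), rng)
        assert out.shape == X.shape
        assert np.all(out.min(axis=2) >= stats.min_of_min - 1e-9)
        assert np.all(out.max(axis=2) <= stats.max_of_max + 1e-9)
        # literal mode: shape preserved, offsets recentre where possible
        out2 = augment_batch(X, stats, AugmentConfig(), rng)
        assert out2.shape == X.shape and np.all(np.isfinite(out2))

    def test_batch_flip_probability_zero_and_one(self, rng):
        X = np.arange(24, dtype=float).reshape(2, 3, 4)
        stats = compute_aug_stats([w(x) for x in X], per_channel=True)
        cfg0 = AugmentConfig(flip_probability=0.0)
        cfg1 = AugmentConfig(flip_probability=1.0)
        out0 = augment_batch(X, stats, cfg0, np.random.default_rng(0))
        out1 = augment_batch(X, stats, cfg1, np.random.default_rng(0))
        # same draws, one flipped: time-reversal relates the two outputs
        np.testing.assert_allclose(out1, out0[:, :, ::-1])
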