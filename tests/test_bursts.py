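"""Burst detection tests: envelope, state selection, binarization, metrics."""

from __future__ import annotations

import numpy as np
import pytest

from burstnet import bursts
from burstnet.containers import BetaEnvelope, BurstTrain
from burstnet.conditioning import condition
from burstnet.hmm import HMMConfig, fit

from conftest import make_posterior


def _tone(freq, fs=100.0, dur=20.0):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestEnvelope:
    def test_beta_tone_envelope_flat(self):
        env = bursts.beta_envelope(_tone(20.0), 100.0).env
        interior = env[200:-200]
        assert interior.std() / interior.mean() < 0.05

    def test_linearity_under_scaling(self):
        x = _tone(20.0)
        e1 = bursts.beta_envelope(x, 100.0).env
        e2 = bursts.beta_envelope(2.0 * x, 100.0).env
        np.testing.assert_allclose(e2, 2.0 * e1, rtol=1e-10)

    def test_out_of_band_tone_suppressed(self):
        e20 = bursts.beta_envelope(_tone(20.0), 100.0).env[200:-200].mean()
        e5 = bursts.beta_envelope(_tone(5.0), 100.0).env[200:-200].mean()
        assert e5 < 0.10 * e20

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bursts.beta_envelope(_tone(20.0), 50.0, band=(13.0, 30.0))

    def test_matches_mne_reference(self, rng):
        """Channel-batched convolution equals mne's Morlet TFR."""
        mne_tf = pytest.importorskip("mne.time_frequency")
        x = rng.standard_normal((3, 2000))
        ours = np.stack([e.env for e in bursts.beta_envelopes(x, 100.0)])
        W = mne_tf.tfr_array_morlet(x[None], sfreq=100.0,
                                    freqs=np.arange(13.0, 31.0), n_cycles=7,
                                    output="complex", verbose="error")
        ref = np.abs(W[0]).mean(axis=-2)
        np.testing.assert_allclose(ours, ref, atol=1e-10)


class TestSelectBurstState:
    def test_affine_transform_of_envelope_selected(self, rng):
        env_vals = rng.uniform(0.1, 2.0, 200)
        g2 = 0.1 + 0.3 * env_vals / env_vals.max()   # positive affine in env
        gamma = np.vstack([(1 - g2) * 0.4, (1 - g2) * 0.6, g2])
        post = make_posterior(gamma)
        env = BetaEnvelope("R00", env_vals, 100.0)
        state, corrs = bursts.select_burst_state(post, env)
        assert state == 2
        assert corrs[2] == pytest.approx(1.0)

    def test_tie_resolves_to_lower_index(self, rng):
        e = rng.uniform(0, 1, 100)
        gamma = np.vstack([e, e, 1 - 2 * e / 2])
        gamma = gamma / gamma.sum(axis=0)
        post = make_posterior(gamma)
        state, corrs = bursts.select_burst_state(
            post, BetaEnvelope("R00", e, 100.0))
        assert state == 0

    def test_all_constant_rows_rejected(self):
        gamma = np.full((2, 50), 0.5)
        post = make_posterior(gamma)
        env = BetaEnvelope("R00", np.ones(50), 100.0)
        with pytest.raises(ValueError, match="undefined"):
            bursts.select_burst_state(post, env)


class TestBinarize:
    def test_strict_two_thirds_threshold(self):
        gamma = np.array([[0.50, 0.70, 0.90, 0.60]])
        gamma = np.vstack([gamma, 1 - gamma])
        post = make_posterior(gamma)
        train = bursts.binarize(post, 0)
        np.testing.assert_array_equal(train.b, [0, 1, 1, 0])
        assert train.visits == [(1, 3)]

    def test_all_below_threshold_empty(self):
        gamma = np.vstack([np.full(10, 0.6), np.full(10, 0.4)])
        train = bursts.binarize(make_posterior(gamma), 0)
        assert train.n_visits == 0 and train.b.sum() == 0

    def test_exact_two_thirds_is_not_burst(self):
        gamma = np.vstack([np.array([2.0 / 3.0, 0.9]),
                           np.array([1.0 / 3.0, 0.1])])
        train = bursts.binarize(make_posterior(gamma), 0)
        np.testing.assert_array_equal(train.b, [0, 1])

    def test_visits_respect_epoch_boundaries(self):
        gamma = np.vstack([np.full(10, 0.9), np.full(10, 0.1)])
        train = bursts.binarize(make_posterior(gamma), 0,
                                epochs=[(0, 5), (5, 10)])
        assert train.visits == [(0, 5), (5, 10)]

    def test_total_burst_time_monotone_in_threshold(self, rng):
        g = rng.uniform(0, 1, 500)
        gamma = np.vstack([g, 1 - g])
        post = make_posterior(gamma)
        times = [bursts.binarize(post, 0, thr).occupancy
                 for thr in (0.5, 0.6, 2 / 3, 0.8, 0.9)]
        assert all(a >= b for a, b in zip(times, times[1:]))


class TestSummarize:
    def _env(self, values, fs=100.0):
        return BetaEnvelope("R00", values, fs)

    def test_single_visit_arithmetic(self):
        b = np.zeros(1000, dtype=np.uint8)
        b[10:20] = 1
        env_vals = np.ones(1000)
        env_vals[12] = 5.0
        s = bursts.summarize(BurstTrain("R00", b, 100.0), self._env(env_vals))
        assert s.burst_amplitude == 5.0
        assert s.mean_duration_s == pytest.approx(0.1)
        assert s.total_burst_time == pytest.approx(0.01)
        assert s.count_rate_hz == pytest.approx(0.1)

    def test_amplitude_is_mean_of_visit_maxima(self):
        b = np.zeros(100, dtype=np.uint8)
        b[10:20] = 1
        b[50:60] = 1
        env_vals = np.zeros(100)
        env_vals[15], env_vals[55] = 3.0, 5.0
        s = bursts.summarize(BurstTrain("R00", b, 100.0), self._env(env_vals))
        assert s.burst_amplitude == pytest.approx(4.0)

    def test_empty_train_flagged(self):
        s = bursts.summarize(BurstTrain("R00", np.zeros(100, np.uint8), 100.0),
                             self._env(np.ones(100)))
        assert not s.amplitude_defined
        assert s.total_burst_time == 0.0 and s.count_rate_hz == 0.0
        assert np.isnan(s.burst_amplitude)

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            bursts.summarize(BurstTrain("R00", np.zeros(10, np.uint8), 100.0),
                             self._env(np.ones(20)))

    def test_total_burst_time_is_visit_sum_over_length(self, rng):
        b = (rng.uniform(0, 1, 500) < 0.2).astype(np.uint8)
        train = BurstTrain("R00", b, 100.0)
        s = bursts.summarize(train, self._env(np.ones(500)))
        assert s.total_burst_time == sum(
            hi - lo for lo, hi in train.visits) / 500


class TestGlobalCollapse:
    def _summary(self, amp=2.0, defined=True):
        from burstnet.containers import BurstSummary
        return BurstSummary("R", amp if defined else np.nan, 0.5, 0.2, 0.3,
                            0.6, 5, amplitude_defined=defined)

    def test_identical_regions_collapse_to_common_value(self):
        means, excl = bursts.global_collapse([self._summary()] * 5)
        assert means["burst_amplitude"] == pytest.approx(2.0)
        assert excl["burst_amplitude"] == 0

    def test_undefined_region_excluded_and_counted(self):
        ss = [self._summary(3.0)] * 3 + [self._summary(defined=False)]
        means, excl = bursts.global_collapse(ss)
        assert means["burst_amplitude"] == pytest.approx(3.0)
        assert excl["burst_amplitude"] == 1

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            bursts.global_collapse([self._summary(defined=False)] * 3)


def test_detected_bursts_overlap_planted_visits():
    """HMM-detected burst visits match planted bursts (Dice >= 0.7)."""
    from burstnet.containers import binary_from_visits
    from burstnet.simulate import SimulationConfig, simulate_resting

    dices = []
    for seed in range(10):
        cfg = SimulationConfig(n_regions=2, n_epochs=6, seed=seed)
        recs, gt = simulate_resting(cfg, 1)
        rec = condition(recs[0], target_fs=recs[0].fs)
        hcfg = HMMConfig(n_states=3, seed=seed, n_restarts=2, max_iter=40)
        post = fit(rec.data[0], rec.fs, hcfg, epochs=rec.epochs,
                   region_id="R00")
        env = bursts.beta_envelope(rec.data[0], rec.fs)
        train, state, corrs = bursts.detect_bursts(post, env,
                                                   epochs=rec.epochs)
        planted = binary_from_visits(gt.subjects[0].visits[0],
                                     rec.n_samples).astype(bool)
        det = train.b.astype(bool)
        dice = 2 * np.sum(det & planted) / max(det.sum() + planted.sum(), 1)
        dices.append(dice)
    assert np.mean(dices) >= 0.7
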