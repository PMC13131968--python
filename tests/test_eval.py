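import numpy as np
import pytest

from hmmindy.evaluate import (aligned_accuracy, kmeans_baseline,
                              parameter_correlation, psd_validation,
                              random_hmm_baseline, train_test_split_eval)
from hmmindy.hmm import HmmParams, near_diagonal_transitions, \
    simulate_states, uniform_initial
from hmmindy.model import simulate
from tests.conftest import tiny_obs, tiny_params


class TestAlignedAccuracy:
    def test_identical_sequences_score_one(self):
        z = np.array([0, 0, 1, 1, 2])
        acc, perm, conf = aligned_accuracy(z, z, 3)
        assert acc == 1.0
        assert np.array_equal(perm, [0, 1, 2])
        assert np.trace(conf) == len(z)

    def test_global_flip_scores_one_after_alignment(self):
        z = np.array([0, 1, 0, 1, 1])
        acc, perm, _ = aligned_accuracy(1 - z, z, 2)
        assert acc == 1.0
        assert np.array_equal(perm, [1, 0])

    def test_confusion_trace_equals_accuracy(self):
        rng = np.random.default_rng(0)
        z_true = rng.integers(0, 3, 500)
        z_est = rng.integers(0, 3, 500)
        acc, _, conf = aligned_accuracy(z_est, z_true, 3)
        assert acc == pytest.approx(np.trace(conf) / 500)

    def test_random_labels_score_near_max_occupancy(self):
        """Uniform random labels against a sticky 2-state chain: aligned
        accuracy concentrates at the max-occupancy fraction (>= 1/2)."""
        rng = np.random.default_rng(1)
        hmm = HmmParams(near_diagonal_transitions(2), uniform_initial(2))
        for k in range(200):
            z_true = simulate_states(hmm, 1500, rng=rng)
            z_rand = rng.integers(0, 2, 1500)
            acc, _, _ = aligned_accuracy(z_rand, z_true, 2)
            occ = np.bincount(z_true, minlength=2).max() / 1500
            assert acc >= 0.5 - 0.05
            # random labels cannot beat the constant-majority rule by
            # more than binomial noise
            assert acc <= max(occ, 0.5) + 0.06

    def test_constant_estimator_scores_max_occupancy(self):
        z_true = np.array([0] * 70 + [1] * 30)
        acc, _, _ = aligned_accuracy(np.zeros(100, int), z_true, 2)
        assert acc == pytest.approx(0.7)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            aligned_accuracy(np.zeros(5, int), np.zeros(6, int), 2)


class TestBaselines:
    def test_random_hmm_reproducible_and_bounded(self):
        hmm = HmmParams(near_diagonal_transitions(2), uniform_initial(2))
        z_true = simulate_states(hmm, 5000, seed=0)
        a = random_hmm_baseline(hmm, z_true, n_draws=10, seed=7)
        b = random_hmm_baseline(hmm, z_true, n_draws=10, seed=7)
        assert np.array_equal(a, b)
        assert np.all((a >= 0.4) & (a <= 1.0))

    def test_single_state_baseline_trivially_perfect(self):
        hmm = HmmParams([[1.0]], [1.0])
        z_true = np.zeros(100, int)
        accs = random_hmm_baseline(hmm, z_true, n_draws=3, seed=0)
        assert np.all(accs == 1.0)

    def test_kmeans_separates_disjoint_channel_means(self):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((4, 600)) * 0.1
        Y[:, 300:] += 5.0
        z_true = np.r_[np.zeros(300, int), np.ones(300, int)]
        _, acc = kmeans_baseline(Y, z_true, 2, seed=0)
        assert acc > 0.99

    def test_kmeans_blind_to_purely_temporal_structure(self):
        """Regimes that differ only in dynamics, not marginals, defeat
        K-means on raw observation vectors."""
        rng = np.random.default_rng(3)
        T = 2000
        z_true = np.r_[np.zeros(T // 2, int), np.ones(T // 2, int)]
        # same marginal N(0,1) in both halves, different autocorrelation
        a = rng.standard_normal(T // 2)
        b = np.convolve(rng.standard_normal(T // 2 + 50), np.ones(50) / 50,
                        "valid")[: T // 2]
        b = b / b.std()
        Y = np.r_[a, b].reshape(1, T)
        _, acc = kmeans_baseline(Y, z_true, 2, seed=0)
        assert acc < 0.65


class TestParameterCorrelation:
    def test_perfect_fit_scores_one(self):
        p = tiny_params(seed=0)
        out = parameter_correlation(p, p, np.array([0, 1]))
        for v in out.values():
            assert v == pytest.approx(1.0)

    def test_scale_invariance_resolves_degeneracy(self):
        """Jointly rescaling W by c and all Gamma by 1/c leaves every
        correlation at 1 (the model's known scale degeneracy)."""
        p = tiny_params(seed=1)
        q = p.copy()
        q.W = 4.0 * q.W
        q.g = q.g / 2.0
        out = parameter_correlation(p, q, np.array([0, 1]))
        for v in out.values():
            assert v == pytest.approx(1.0, abs=1e-10)

    def test_independent_redraw_scores_near_zero(self):
        rs = []
        for seed in range(100):
            a = tiny_params(n_exc=4, seed=seed)
            b = tiny_params(n_exc=4, seed=seed + 1000)
            out = parameter_correlation(a, b, np.array([0, 1]),
                                        apply_truth_mask=False)
            rs.append(out["W_EE"])
        assert abs(np.mean(rs)) < 0.1

    def test_truth_mask_applied_to_fit(self):
        p = tiny_params(seed=2)
        p.mask[0, 1] = False
        p.W[0, 1] = 0.0
        q = p.copy()
        q.W = q.W.copy()
        q.W[0, 1] = 5.0  # spurious fitted connection on a true zero
        masked = parameter_correlation(p, q)
        unmasked = parameter_correlation(p, q, apply_truth_mask=False)
        assert masked["W_EE"] == pytest.approx(1.0)
        assert unmasked["W_EE"] < 1.0

    def test_constant_block_reported_missing_not_zero(self):
        p = tiny_params(seed=3)
        q = p.copy()
        q.g[:] = 1.0       # fitted Gamma exactly constant
        out = parameter_correlation(p, q, np.array([0, 1]))
        assert out["Gamma1_EE"] is None

    def test_slot_alignment_uses_permutation(self):
        p = tiny_params(seed=4)
        q = p.copy()
        q.g = q.g[::-1].copy()        # regimes stored in swapped slots
        out = parameter_correlation(p, q, permutation=np.array([1, 0]))
        assert out["Gamma1_EE"] == pytest.approx(1.0)


class TestPsdValidation:
    def test_self_simulation_scores_high(self):
        p = tiny_params(seed=5)
        obs = tiny_obs(seed=5, q=0.1, r=0.05)
        labels = np.zeros(4000, dtype=int)
        _, Y = simulate(p, obs, labels, seed=0)
        out = psd_validation(p, obs, Y, labels, fs=250.0, band=(0.5, 60.0),
                             seed=1)
        assert out[0] > 0.9

    def test_mismatched_spectra_score_low(self):
        """White noise data against a narrowband oscillator model."""
        rng = np.random.default_rng(0)
        fs, T = 250.0, 4000
        Y = rng.standard_normal((1, T))
        t = np.arange(T) / fs
        Ysim = np.sin(2 * np.pi * 10 * t).reshape(1, T)
        from scipy import signal as sps
        from scipy.stats import pearsonr
        nper = int(2 * fs)
        f, pw = sps.welch(Y, fs=fs, nperseg=nper, axis=1)
        _, po = sps.welch(Ysim + 0.01 * rng.standard_normal((1, T)),
                          fs=fs, nperseg=nper, axis=1)
        keep = (f >= 0.5) & (f <= 30)
        r = pearsonr(np.log(pw[:, keep]).ravel(),
                     np.log(po[:, keep]).ravel())[0]
        assert r < 0.5

    def test_too_little_data_per_state_raises(self):
        p = tiny_params(seed=6)
        obs = tiny_obs(seed=6)
        labels = np.zeros(100, dtype=int)   # < 2 s at 250 Hz
        Y = np.random.default_rng(0).standard_normal((3, 100))
        with pytest.raises(ValueError, match="2 s"):
            psd_validation(p, obs, Y, labels, fs=250.0)


class TestTrainTestSplit:
    def test_degenerate_split_rejected(self):
        from hmmindy.blind import BlindConfig
        Y = np.zeros((2, 100))
        with pytest.raises(ValueError):
            train_test_split_eval(Y, np.zeros(100, int), BlindConfig(m=2),
                                  None, split=1.0)

    def test_frozen_params_and_comparable_accuracy(self):
        from hmmindy.synth import SynthSpec, generate_dataset
        from tests.test_blind import small_cfg
        ds = generate_dataset(SynthSpec(n_exc=4, T=4000), seed=31)
        train_acc, test_acc, res = train_test_split_eval(
            ds.Y, ds.labels, small_cfg(seed=31), ds.obs, split=0.75,
            mask=ds.params.mask)
        assert 0.0 <= train_acc <= 1.0 and 0.0 <= test_acc <= 1.0
        # labeling held-out data must not have perturbed the parameters
        res.params.validate()
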