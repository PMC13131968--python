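import numpy as np
import pytest

from hmmindy import _kernels
from hmmindy.kalman import (FitConfig, ekf_step, filter_sequence,
                            fit_inner_loop, loss_and_grads)
from hmmindy.model import ObservationModel, simulate
from tests.conftest import tiny_obs, tiny_params


def reference_kalman_step(A, H, Q, R, x, P, y):
    """Textbook linear Kalman filter step, written independently."""
    xp = A @ x
    Pp = A @ P @ A.T + Q
    S = H @ Pp @ H.T + R
    K = Pp @ H.T @ np.linalg.inv(S)
    x_new = xp + K @ (y - H @ xp)
    P_new = (np.eye(len(x)) - K @ H) @ Pp
    return x_new, P_new


def near_linear_params(n_exc=2, seed=0, scale=1e-6):
    """Model operating in the tanh's linear range: slopes tiny, weights
    scaled up so the effective linear map stays finite."""
    rng = np.random.default_rng(seed)
    n = 2 * n_exc
    p = tiny_params(n_exc=n_exc, seed=seed)
    p.g[:] = 1.0
    p.S[:] = scale
    p.W = p.W / scale          # W tanh(S x) ~= (W S) x = original W x
    p.V[:] = 0.0
    p.C[:] = 0.0
    return p


class TestLinearEquivalence:
    def test_ekf_matches_reference_kf_on_linear_system(self):
        n_exc = 2
        p = near_linear_params(n_exc=n_exc)
        obs = tiny_obs(n_exc=n_exc, seed=1)
        n = p.n
        A_lin = p.W * p.S + np.diag(p.D)    # effective linear dynamics
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((n_exc, 30))
        x_ref, P_ref = np.zeros(n), np.eye(n)
        x_ekf, P_ekf = np.zeros(n), np.eye(n)
        for t in range(Y.shape[1]):
            x_ref, P_ref = reference_kalman_step(
                A_lin, obs.H, obs.Q, obs.R, x_ref, P_ref, Y[:, t])
            x_ekf, P_ekf, _ = ekf_step(p, obs, x_ekf, P_ekf, Y[:, t], 0)
            assert np.allclose(x_ekf, x_ref, atol=1e-8)
            assert np.allclose(P_ekf, P_ref, atol=1e-8)


class TestEkfStep:
    def test_zero_innovation_leaves_prediction(self, small_model, small_obs):
        x = np.zeros(small_model.n)
        P = np.eye(small_model.n)
        # one step to get a nontrivial prediction, then feed it back
        from hmmindy.model import step_dynamics, observe
        xp = step_dynamics(small_model, x, 0, 0.0)
        y = observe(small_obs, xp, 0.0)
        x2, P2, resid = ekf_step(small_model, small_obs, x, P, y, 0)
        assert np.allclose(x2, xp, atol=1e-10)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_covariance_stays_symmetric_psd(self, small_model, small_obs, rng):
        x = np.zeros(small_model.n)
        P = np.eye(small_model.n)
        for t in range(50):
            y = rng.standard_normal(3)
            x, P, _ = ekf_step(small_model, small_obs, x, P, y, t % 2)
            assert np.allclose(P, P.T, atol=1e-10)
            assert np.min(np.linalg.eigvalsh(P)) > -1e-10

    def test_singular_innovation_covariance_mentions_regularization(self):
        p = tiny_params(n_exc=1)
        obs = ObservationModel(np.zeros((1, 2)), np.zeros((2, 2)),
                               np.zeros((1, 1)))
        with pytest.raises(np.linalg.LinAlgError, match="[Rr]egulariz"):
            ekf_step(p, obs, np.zeros(2), np.eye(2), np.ones(1), 0)


class TestFilterSequence:
    def test_noise_free_self_consistent_data_gives_tiny_loss(self):
        p = tiny_params(seed=4)
        obs0 = tiny_obs(seed=4, q=0.0, r=0.0)
        labels = np.zeros(200, dtype=int)
        X, Y = simulate(p, obs0, labels, seed=0)
        obs = tiny_obs(seed=4, q=1e-8, r=1e-8)
        trace = filter_sequence(p, obs, Y, labels)
        assert trace.loss / Y.size < 1e-4

    def test_T1_reduces_to_single_step(self, small_model, small_obs, rng):
        y = rng.standard_normal((3, 1))
        trace = filter_sequence(small_model, small_obs, y, np.zeros(1, int))
        x1, P1, r1 = ekf_step(small_model, small_obs,
                              np.zeros(small_model.n),
                              np.eye(small_model.n), y[:, 0], 0)
        assert np.allclose(trace.xhat[:, 0], x1, atol=1e-12)
        assert np.allclose(trace.resid[:, 0], r1, atol=1e-12)
        assert np.allclose(trace.P_final, P1, atol=1e-12)

    def test_true_labels_beat_shuffled_labels(self):
        """Filtering with the generating regime labels gives lower loss
        than with independently shuffled labels, in nearly all trials."""
        wins = 0
        n_trials = 50
        for trial in range(n_trials):
            p = tiny_params(seed=trial)
            rng = np.random.default_rng(trial)
            p.g[0] = np.abs(1.0 + 0.6 * rng.standard_normal(p.n))
            p.g[1] = np.abs(1.0 - 0.6 * rng.standard_normal(p.n))
            obs = tiny_obs(seed=trial, q=0.05, r=0.05)
            labels = (np.arange(300) // 75) % 2
            X, Y = simulate(p, obs, labels, seed=trial)
            shuffled = np.random.default_rng(trial + 1).permutation(labels)
            good = filter_sequence(p, obs, Y, labels).loss
            bad = filter_sequence(p, obs, Y, shuffled).loss
            wins += good < bad
        assert wins >= int(0.95 * n_trials)


class TestGradients:
    def test_full_mode_gradients_match_finite_differences(self):
        """Tape gradients (covariance inside the graph) vs central FD of
        the true filtering loss, n=4 populations, T=20."""
        p = tiny_params(n_exc=2, seed=1)
        obs = tiny_obs(n_exc=2, seed=1)
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((2, 20))
        labels = (np.arange(20) // 5) % 2
        n = p.n
        x0, P0 = np.zeros(n), np.eye(n)
        _, grads, _, _ = loss_and_grads(p, obs, Y, labels, x0, P0, "full",
                                        "innovation")

        def loss_at(q):
            l, _, _, _ = loss_and_grads(q, obs, Y, labels, x0, P0,
                                        "detached", "innovation")
            return l

        eps = 1e-5
        for name in ("D", "S", "V", "C"):
            for k in range(n):
                qa, qb = p.copy(), p.copy()
                getattr(qa, name)[k] += eps
                getattr(qb, name)[k] -= eps
                fd = (loss_at(qa) - loss_at(qb)) / (2 * eps)
                assert grads[name][k] == pytest.approx(
                    fd, rel=1e-4, abs=1e-6), f"{name}[{k}]"
        for idx in [(0, 0), (1, 0), (2, 1), (0, 2), (3, 3)]:
            qa, qb = p.copy(), p.copy()
            qa.W[idx] += eps
            qb.W[idx] -= eps
            fd = (loss_at(qa) - loss_at(qb)) / (2 * eps)
            assert grads["W"][idx] == pytest.approx(fd, rel=1e-4, abs=1e-6)
        for idx in [(0, 0), (1, 3)]:
            qa, qb = p.copy(), p.copy()
            qa.g[idx] += eps
            qb.g[idx] -= eps
            fd = (loss_at(qa) - loss_at(qb)) / (2 * eps)
            assert grads["g"][idx] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_detached_gradients_match_frozen_gain_finite_differences(self):
        p = tiny_params(n_exc=2, seed=2)
        obs = tiny_obs(n_exc=2, seed=2)
        rng = np.random.default_rng(1)
        Y = np.ascontiguousarray(rng.standard_normal((2, 20)))
        labels = np.zeros(20, dtype=np.int64)
        n = p.n
        x0, P0 = np.zeros(n), np.eye(n)
        _, grads, _, _ = loss_and_grads(p, obs, Y, labels, x0, P0,
                                        "detached", "innovation")
        out = _kernels.ekf_forward(p.modulated_W(), p.D, p.S, p.V, p.C,
                                   obs.H, obs.Q, obs.R, labels, Y, x0, P0, 1)
        K = out[5]

        def frozen(q):
            return _kernels.ekf_forward_frozen_gains(
                q.modulated_W(), q.D, q.S, q.V, q.C, obs.H, labels, Y, x0,
                K, 1)

        eps = 1e-6
        for name in ("D", "S", "V", "C"):
            for k in range(n):
                qa, qb = p.copy(), p.copy()
                getattr(qa, name)[k] += eps
                getattr(qb, name)[k] -= eps
                fd = (frozen(qa) - frozen(qb)) / (2 * eps)
                assert grads[name][k] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestInnerLoop:
    def test_zero_learning_rate_keeps_params(self, small_dataset):
        ds = small_dataset
        cfg = FitConfig(lr=1e-30, passes=1)
        out, trace, _ = fit_inner_loop(ds.params, ds.obs, ds.Y, ds.labels,
                                       cfg)
        assert np.allclose(out.W, ds.params.W, atol=1e-12)
        assert np.allclose(out.g, ds.params.g, atol=1e-12)

    def test_loss_decreases_from_perturbed_truth(self, small_dataset):
        ds = small_dataset
        rng = np.random.default_rng(0)
        start = ds.params.copy()
        start.W = start.W * (1 + 0.3 * rng.standard_normal(start.W.shape))
        from hmmindy.model import project_constraints
        start = project_constraints(start)
        losses = [filter_sequence(start, ds.obs, ds.Y, ds.labels).loss]
        params, opt = start, None
        for _ in range(5):
            params, trace, opt = fit_inner_loop(
                params, ds.obs, ds.Y, ds.labels,
                FitConfig(passes=1, lr=3e-3, g_anchor=1.0), opt)
            losses.append(trace.loss)
        assert losses[-1] < losses[0]

    def test_output_always_satisfies_constraints(self, small_dataset):
        ds = small_dataset
        params, trace, _ = fit_inner_loop(
            ds.params, ds.obs, ds.Y, ds.labels, FitConfig(passes=2, lr=3e-2))
        params.validate()
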