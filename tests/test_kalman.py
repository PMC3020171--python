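"""Kalman recursion: random-walk coefficient tracking and the OLS limit."""

import numpy as np
import pytest

from nirsmap.kalman import (KalmanConfig, KalmanConfigError, init_state,
                            predict, step_all_channels, update)


class TestInit:
    def test_default_initialization(self):
        s = init_state(5, KalmanConfig(p0=1e4))
        assert s.x_hat.shape == (1, 5)
        assert not s.x_hat.any()  # state starts at zero
        np.testing.assert_array_equal(s.p_cov[0], 1e4 * np.eye(5))
        assert s.k == 0 and s.rss[0] == 0.0 and not s.gram.any()

    def test_scalar_filter(self):
        s = init_state(1)
        assert s.x_hat.shape == (1, 1)

    def test_init_deterministic(self):
        a, b = init_state(3), init_state(3)
        assert np.array_equal(a.x_hat, b.x_hat)
        assert np.array_equal(a.p_cov, b.p_cov)

    @pytest.mark.parametrize("bad", [dict(q=-1), dict(r=0), dict(p0=0)])
    def test_invalid_config(self, bad):
        with pytest.raises(KalmanConfigError):
            KalmanConfig(**bad)


class TestPredict:
    def test_no_process_noise_leaves_p(self):
        cfg = KalmanConfig(q=0.0)
        s = init_state(4, cfg)
        p_before = s.p_cov.copy()
        predict(s, cfg)
        np.testing.assert_array_equal(s.p_cov, p_before)

    def test_trace_grows_by_L_q(self):
        cfg = KalmanConfig(q=0.01)
        s = init_state(5, cfg)
        tr = np.trace(s.p_cov[0])
        predict(s, cfg)
        assert np.trace(s.p_cov[0]) == pytest.approx(tr + 5 * 0.01)

    def test_repeated_predict_closed_form(self):
        cfg = KalmanConfig(q=0.3, p0=2.0)
        s = init_state(3, cfg)
        for _ in range(50):
            predict(s, cfg)
        np.testing.assert_allclose(s.p_cov[0], (2.0 + 50 * 0.3) * np.eye(3),
                                   atol=1e-10)


class TestUpdate:
    def test_zero_row_is_uninformative(self):
        cfg = KalmanConfig()
        s = init_state(3, cfg)
        x0, p0 = s.x_hat.copy(), s.p_cov.copy()
        update(s, np.array([5.0]), np.zeros(3), cfg)
        np.testing.assert_array_equal(s.x_hat, x0)
        np.testing.assert_array_equal(s.p_cov, p0)

    def test_scalar_closed_form_gain(self):
        cfg = KalmanConfig(q=0.0, r=1.0, p0=1.0)
        s = init_state(1, cfg)
        update(s, np.array([2.0]), np.ones(1), cfg)
        # K = P/(P+r) = 0.5; x moves halfway to y
        assert s.x_hat[0, 0] == pytest.approx(1.0)

    def test_nonfinite_input_rejected(self):
        cfg = KalmanConfig()
        s = init_state(2, cfg)
        with pytest.raises(ValueError, match="non-finite"):
            update(s, np.array([np.nan]), np.ones(2), cfg)

    def test_degenerates_to_batch_ols(self, random_design):
        """q=0 + diffuse prior reproduces per-step batch OLS coefficients."""
        cfg = KalmanConfig.diffuse()
        rng = np.random.default_rng(31)
        H = random_design.matrix
        beta = np.array([1.0, -0.5, 0.3, 0.0, 2.0])
        y = H @ beta + rng.normal(0, 0.5, 200)
        s = init_state(5, cfg)
        for k in range(200):
            predict(s, cfg)
            update(s, y[k : k + 1], H[k], cfg)
            if k + 1 >= 6:
                b_ols, *_ = np.linalg.lstsq(H[: k + 1], y[: k + 1], rcond=None)
                assert np.max(np.abs(s.x_hat[0] - b_ols)) < 1e-6
                # recursive RSS equals batch RSS at the current estimate
                rss_ols = np.sum((y[: k + 1] - H[: k + 1] @ b_ols) ** 2)
                assert s.rss[0] == pytest.approx(rss_ols, abs=1e-5)

    def test_covariance_stays_symmetric_psd(self):
        cfg = KalmanConfig(q=1e-3, r=0.25, p0=10.0)
        s = init_state(4, cfg)
        rng = np.random.default_rng(32)
        for _ in range(1000):
            predict(s, cfg)
            update(s, rng.normal(size=1), rng.normal(size=4), cfg)
        p = s.p_cov[0]
        np.testing.assert_array_equal(p, p.T)
        assert np.linalg.eigvalsh(p).min() >= -1e-8


class TestStepAllChannels:
    def test_identical_channels_give_identical_states(self):
        cfg = KalmanConfig()
        s = init_state(3, cfg, n_channels=24)
        rng = np.random.default_rng(33)
        for _ in range(20):
            y = np.full(24, rng.normal())
            step_all_channels(s, y, rng.normal(size=3), None, cfg)
        assert np.all(s.x_hat == s.x_hat[0])
        assert np.all(s.p_cov == s.p_cov[0])

    def test_permutation_equivariance(self):
        cfg = KalmanConfig()
        rng = np.random.default_rng(34)
        ys = rng.normal(size=(30, 6))
        rows = rng.normal(size=(30, 3))
        perm = rng.permutation(6)
        s1 = init_state(3, cfg, n_channels=6)
        s2 = init_state(3, cfg, n_channels=6)
        for k in range(30):
            step_all_channels(s1, ys[k], rows[k], None, cfg)
            step_all_channels(s2, ys[k][perm], rows[k], None, cfg)
        np.testing.assert_array_equal(s1.x_hat[perm], s2.x_hat)

    def test_single_channel_composes_predict_update(self):
        cfg = KalmanConfig()
        rng = np.random.default_rng(35)
        s_multi = init_state(3, cfg, n_channels=1)
        s_direct = init_state(3, cfg, n_channels=1)
        for _ in range(15):
            y, row = rng.normal(size=1), rng.normal(size=3)
            step_all_channels(s_multi, y, row, None, cfg)
            predict(s_direct, cfg)
            update(s_direct, y, row, cfg)
        np.testing.assert_array_equal(s_multi.x_hat, s_direct.x_hat)
        np.testing.assert_array_equal(s_multi.rss, s_direct.rss)

    def test_channel_count_mismatch_raises(self):
        cfg = KalmanConfig()
        s = init_state(3, cfg, n_channels=4)
        with pytest.raises(ValueError, match="channels"):
            step_all_channels(s, np.zeros(5), np.zeros(3), None, cfg)


def test_parameter_recovery_with_default_noise_covariances(short_protocol):
    """beta_1 recovery within 10% with the default q/r on white-noise data."""
    from nirsmap.design import build_design

    design = build_design(short_protocol)
    cfg = KalmanConfig()  # q=(0.01)^2, r=(0.5)^2
    reps = 50
    rng = np.random.default_rng(36)
    y = 1.0 * design.matrix[:, 0][None, :] + rng.normal(
        0, 0.5, (reps, design.n_samples))
    s = init_state(5, cfg, n_channels=reps)
    for k in range(design.n_samples):
        step_all_channels(s, y[:, k], design.row(k), None, cfg)
    assert s.x_hat[:, 0].mean() == pytest.approx(1.0, abs=0.1)
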