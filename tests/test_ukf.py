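"""Unscented Kalman filter: sigma-point algebra, oracles, and the ML path."""

import numpy as np
import pytest

from neuroassim import models, ukf
from neuroassim.params import HOPF, SNIC


def random_spd(rng, n, scale=1.0):
    A = rng.normal(size=(n, n))
    return scale * (A @ A.T + n * np.eye(n))


def test_sigma_weights_sum_to_one():
    for n, lam in [(2, 5.0), (10, 5.0), (10, -9.0), (3, 0.5)]:
        w = ukf.sigma_weights(n, lam)
        assert len(w) == 2 * n + 1
        assert np.sum(w) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("n_dim", [2, 5, 10])
def test_sigma_points_reproduce_moments(rng, n_dim):
    mean = rng.normal(size=n_dim)
    cov = random_spd(rng, n_dim)
    ens = ukf.sigma_points(mean, cov, lam=5.0)
    m, P = ukf.ensemble_moments(ens.points, ens.weights)
    np.testing.assert_allclose(m, mean, atol=1e-9)
    np.testing.assert_allclose(P, cov, atol=1e-8)


def test_unscented_transform_exact_for_linear_map(rng):
    n = 4
    mean = rng.normal(size=n)
    cov = random_spd(rng, n)
    F = rng.normal(size=(n, n))
    Q = random_spd(rng, n, scale=0.01)
    ens = ukf.sigma_points(mean, cov, lam=3.0)
    fm, fP, _ = ukf.unscented_forecast(ens, lambda x: F @ x, Q)
    np.testing.assert_allclose(fm, F @ mean, atol=1e-9)
    np.testing.assert_allclose(fP, F @ cov @ F.T + Q, atol=1e-8)


def test_ukf_matches_linear_kf_oracle(rng):
    """On a linear-Gaussian system the UKF must equal the classical KF."""
    n = 3
    F = 0.9 * np.eye(n) + 0.05 * rng.normal(size=(n, n))
    H = np.zeros(n)
    H[0] = 1.0
    Q = random_spd(rng, n, scale=1e-4)
    R = 0.04
    x_true = rng.normal(size=n)
    obs = np.zeros(80)
    for k in range(80):
        obs[k] = x_true[0] + rng.normal(scale=np.sqrt(R))
        x_true = F @ x_true + rng.multivariate_normal(np.zeros(n), Q)
    x0 = np.zeros(n)
    P0 = np.eye(n)
    hist_ukf = ukf.run_ukf_generic(obs, lambda x: F @ x, x0, P0, Q, R, lam=3.0)
    hist_kf = ukf.linear_kf_oracle(F, H, Q, R, x0, P0, obs)
    assert not hist_ukf.failed
    np.testing.assert_allclose(hist_ukf.means, hist_kf.means, atol=1e-8)
    np.testing.assert_allclose(hist_ukf.cov_diag, hist_kf.cov_diag, atol=1e-8)


def test_unscented_moments_match_monte_carlo(rng):
    """Unscented mean/cov of the model map vs a large simulated cloud."""
    p = SNIC
    mean = np.array([-25.0, 0.3])
    cov = np.array([[4.0, 0.1], [0.1, 0.01]])

    def step(x):
        return models.modified_euler_step(x, p, 0.1)

    ens = ukf.sigma_points(mean, cov, lam=1.0)
    um, uP, _ = ukf.unscented_forecast(ens, step, np.zeros((2, 2)))

    cloud = rng.multivariate_normal(mean, cov, size=100_000)
    mapped = np.array([step(x) for x in cloud[:20000]])
    mc_mean = mapped.mean(axis=0)
    mc_cov = np.cov(mapped.T)
    # Monte-Carlo standard error sets the comparison scale
    se = np.sqrt(np.diag(mc_cov) / len(mapped))
    assert np.all(np.abs(um - mc_mean) < 6 * se + 1e-3)
    np.testing.assert_allclose(uP, mc_cov, rtol=0.1, atol=1e-5)


def test_default_process_noise_recipe():
    y = np.array([-40.0, 10.0, -20.0])
    theta0 = np.array([0.1, -4.0])
    q = ukf.default_process_noise(y, theta0, n_states=2, scale=1e-7)
    np.testing.assert_allclose(q, 1e-7 * np.array([50.0, 1.0, 0.1, 4.0]))


def test_run_ukf_noise_free_truth_guess_parameters_drift_little():
    traj = models.simulate(SNIC, t_end=500.0, dt=0.1)
    series = models.observe_with_noise(traj, 0.0, seed=None)
    q = ukf.default_process_noise(series.y, SNIC.theta(), n_states=2)
    q[2:] = 0.0  # persistence model for the parameters
    hist = ukf.run_ukf(series, SNIC, ukf.UKFConfig(qdiag=q, r=1e-6))
    assert not hist.failed
    theta_path = hist.means[:, 2:]
    rel = np.abs(theta_path - SNIC.theta()) / np.abs(SNIC.theta())
    assert np.max(rel) < 0.01


def test_run_ukf_deterministic(snic_series):
    a = ukf.run_ukf(snic_series, HOPF)
    b = ukf.run_ukf(snic_series, HOPF)
    np.testing.assert_array_equal(a.means, b.means)


def test_run_ukf_recovers_snic_from_hopf_guess(snic_series):
    hist = ukf.run_ukf(snic_series, HOPF)
    assert not hist.failed
    theta = hist.final_theta(2)
    assert theta[0] == pytest.approx(SNIC.phi, rel=0.05)
    assert theta[2] == pytest.approx(SNIC.V3, abs=0.5)
    assert theta[3] == pytest.approx(SNIC.V4, abs=0.5)


def test_filter_failure_is_data_not_exception(snic_series):
    hist = ukf.run_ukf(snic_series, HOPF, ukf.UKFConfig(lam=5.0, alpha_i=100.0))
    assert hist.failed
    assert hist.fail_step >= 0
    # estimates before the failure step are recorded
    assert np.all(np.isfinite(hist.means[: hist.fail_step]))


def test_failure_region_location(snic_series):
    """Small initial covariance completes; very large ones fail."""
    ok = ukf.run_ukf(snic_series, HOPF, ukf.UKFConfig(alpha_i=1e-3))
    assert not ok.failed
    for lam in (-9.0, 5.0, 40.0):
        bad = ukf.run_ukf(
            snic_series, HOPF, ukf.UKFConfig(lam=lam, alpha_i=100.0)
        )
        assert bad.failed


def test_estimator_api(snic_series):
    est = ukf.UnscentedKalmanFilter(guess=HOPF)
    params = est.get_params()
    assert "guess" in params and "lam" in params
    est.set_params(lam=4.0)
    assert est.lam == 4.0
    est.set_params(lam=5.0)
    fitted = est.fit(snic_series)
    assert fitted is est
    assert hasattr(est, "theta_") and hasattr(est, "history_")
    assert est.failed_ is False
    assert est.params_.phi == pytest.approx(SNIC.phi, rel=0.05)
    pred = est.predict()
    assert pred.shape == (len(snic_series.y),)
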