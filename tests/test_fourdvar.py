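"""Weak-constraint variational estimation: cost, gradient, sparsity, runs."""

import numpy as np
import pytest
import scipy.optimize

from neuroassim import fourdvar, models
from neuroassim.params import SNIC, SQUARE_WAVE


def small_problem(n_times=12, params=SNIC, seed=0):
    traj = models.simulate(params, t_end=(n_times - 1) * 0.1, dt=0.1,
                           substeps=4 if params.n_states == 3 else 1)
    series = models.observe_with_noise(traj, 0.01, seed=seed)
    return traj, series


def test_layout_pack_unpack_round_trip(rng):
    lay = fourdvar.DecisionLayout(n_times=7, n_states=2, n_params=8)
    states = rng.normal(size=(7, 2))
    theta = rng.normal(size=8)
    x = lay.pack(states, theta)
    assert x.shape == (lay.size,)
    s2, t2 = lay.unpack(x)
    np.testing.assert_array_equal(s2, states)
    np.testing.assert_array_equal(t2, theta)
    assert x[lay.state_index(1, 3)] == states[3, 1]
    assert x[lay.theta_index(0)] == theta[0]
    with pytest.raises(IndexError):
        lay.state_index(2, 0)


@pytest.mark.parametrize("params", [SNIC, SQUARE_WAVE], ids=["spiking", "bursting"])
def test_gradient_matches_finite_differences(params, rng):
    _, series = small_problem(12, params)
    cfg = fourdvar.VarConfig()
    lay = fourdvar.layout_for(series, params)
    x = fourdvar.initial_guess(series, params)
    x += 0.01 * rng.normal(size=lay.size)
    cost, grad = fourdvar.cost_and_grad(x, series, params, cfg)
    fd = scipy.optimize.approx_fprime(x, lambda z: fourdvar.cost_and_grad(
        z, series, params, cfg, with_gradient=False)[0], 1e-7)
    scale = max(np.max(np.abs(fd)), 1.0)
    assert np.max(np.abs(grad - fd)) / scale < 1e-5


@pytest.mark.parametrize("params", [SNIC, SQUARE_WAVE], ids=["spiking", "bursting"])
def test_compiled_kernel_matches_numpy_reference(params, rng):
    _, series = small_problem(40, params)
    cfg = fourdvar.VarConfig()
    lay = fourdvar.layout_for(series, params)
    x = fourdvar.initial_guess(series, params)
    x += 0.01 * rng.normal(size=lay.size)
    c1, g1 = fourdvar.cost_and_grad(x, series, params, cfg)
    c2, g2 = fourdvar.cost_and_grad_reference(x, series, params, cfg)
    assert c1 == pytest.approx(c2, rel=1e-12)
    np.testing.assert_allclose(g1, g2, rtol=1e-10, atol=1e-12)


def test_cost_zero_model_error_on_exact_trajectory():
    traj, series = small_problem(30)
    cfg = fourdvar.VarConfig()
    lay = fourdvar.layout_for(series, SNIC)
    x = lay.pack(traj.states, SNIC.theta())
    cost, _ = fourdvar.evaluate_cost(x, series, SNIC, cfg)
    # the trajectory satisfies the discrete model exactly, so the whole cost
    # is the measurement term
    merr = series.y - traj.V
    expected = 0.5 * (1.0 / series.R) * merr @ merr
    assert cost == pytest.approx(expected, rel=1e-10)


def test_hessian_sparsity_matches_fd_support():
    _, series = small_problem(10)
    cfg = fourdvar.VarConfig()
    lay = fourdvar.layout_for(series, SNIC)
    x = fourdvar.initial_guess(series, SNIC)
    pattern = fourdvar.hessian_sparsity(lay.n_times, lay.n_states, lay.n_params)
    assert pattern.shape == (lay.size, lay.size)

    eps = 1e-5
    H = np.zeros((lay.size, lay.size))
    for i in range(lay.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        _, gp = fourdvar.cost_and_grad(xp, series, SNIC, cfg)
        _, gm = fourdvar.cost_and_grad(xm, series, SNIC, cfg)
        H[i] = (gp - gm) / (2 * eps)
    H = 0.5 * (H + H.T)
    support = np.abs(H) > 1e-6 * np.max(np.abs(H))
    dense_pattern = pattern.toarray()
    # every numerically nonzero entry must be structurally allowed
    assert not np.any(support & ~dense_pattern)
    # and the structure must be used: tridiagonal state blocks + theta border
    assert dense_pattern[lay.state_index(0, 0), lay.state_index(0, 1)]
    assert not dense_pattern[lay.state_index(0, 0), lay.state_index(0, 5)]
    assert dense_pattern[lay.theta_index(0), lay.state_index(1, 3)]


def test_initial_guess_blocks(short_snic_series):
    traj, series = short_snic_series
    x = fourdvar.initial_guess(series, SNIC)
    lay = fourdvar.layout_for(series, SNIC)
    states, theta = lay.unpack(x)
    np.testing.assert_array_equal(states[:, 0], series.y)
    bounds = fourdvar.default_bounds(SNIC)
    for val, (lo, hi) in zip(theta, bounds):
        assert lo <= val <= hi
    # with truth parameters and noiseless forcing, the forced gate tracks
    # the true gate after a transient
    clean = models.observe_with_noise(traj, 0.0, seed=None)
    x0 = fourdvar.initial_guess(clean, SNIC)
    gates, _ = lay.unpack(x0)
    # the initial-condition mismatch decays at the gate relaxation rate
    # (tens of ms in this regime), so allow a 30 ms transient
    rms = np.sqrt(np.mean((gates[300:, 1] - traj.n[300:]) ** 2))
    assert rms < 1e-3


def test_run_weak_4dvar_respects_bounds_and_logs(short_snic_series):
    _, series = short_snic_series
    cfg = fourdvar.VarConfig(maxiter=200)
    x_opt, info = fourdvar.run_weak_4dvar(series, SNIC, cfg)
    lay = fourdvar.layout_for(series, SNIC)
    _, theta = lay.unpack(x_opt)
    for val, (lo, hi) in zip(theta, fourdvar.default_bounds(SNIC)):
        assert lo - 1e-12 <= val <= hi + 1e-12
    assert info["status"] in ("ok", "optimizer_maxiter")
    costs = np.asarray(info["cost_log"])
    assert len(costs) >= 2
    assert costs[-1] <= costs[0]


def test_strong_constraint_limit_recovers_truth():
    """With a near-hard model constraint the optimum returns the truth."""
    traj = models.simulate(SNIC, t_end=80.0, dt=0.1)
    series = models.observe_with_noise(traj, 0.01, seed=3)
    cfg = fourdvar.VarConfig(alpha_q=1e6, maxiter=20000)
    x_opt, info = fourdvar.run_weak_4dvar(series, SNIC, cfg)
    _, theta = fourdvar.layout_for(series, SNIC).unpack(x_opt)
    rel = np.abs(theta - SNIC.theta()) / np.abs(SNIC.theta())
    assert np.max(rel) < 0.05


def test_estimator_api(short_snic_series):
    _, series = short_snic_series
    est = fourdvar.WeakFourDVar(guess=SNIC, maxiter=200)
    assert "guess" in est.get_params()
    est.fit(series)
    assert hasattr(est, "theta_") and hasattr(est, "states_")
    assert est.states_.shape == (len(series.y), 2)
    assert est.status_ in ("ok", "optimizer_maxiter")
    assert est.cost_ == pytest.approx(est.cost_log_[-1])


def test_cost_surface_slice_shape(short_snic_series):
    _, series = short_snic_series
    lay = fourdvar.layout_for(series, SNIC)
    x0 = fourdvar.initial_guess(series, SNIC)
    rng = np.random.default_rng(0)
    xa = x0 + 0.01 * rng.normal(size=lay.size)
    xb = x0 + 0.01 * rng.normal(size=lay.size)
    grid = fourdvar.cost_surface_slice(
        x0, xa, xb, series, SNIC,
        alphas=np.linspace(0, 1, 5), betas=np.linspace(0, 1, 5),
    )
    assert grid.shape == (5, 5)
    assert np.all(np.isfinite(grid))
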