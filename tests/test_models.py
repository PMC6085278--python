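"""Model simulation, observation noise, and event counting."""

import numpy as np
import pytest

from neuroassim import models
from neuroassim.params import (
    BurstingParams,
    HOMOCLINIC,
    HOPF,
    SNIC,
    SQUARE_WAVE,
    SpikingParams,
    get_regime,
)


def test_gate_functions_at_half_activation():
    # at V = V3 the K gate sits at its half-activation with unit time scale
    m_inf, n_inf, tau_n = models.gate_functions(SNIC.V3, SNIC)
    assert n_inf == pytest.approx(0.5)
    assert tau_n == pytest.approx(1.0)
    # m follows its own half-activation voltage
    m_half, _, _ = models.gate_functions(SNIC.V1, SNIC)
    assert m_half == pytest.approx(0.5)


def test_vector_field_hand_value():
    p = SNIC
    V, n = -20.0, 0.3
    m_inf = 0.5 * (1 + np.tanh((V - p.V1) / p.V2))
    n_inf = 0.5 * (1 + np.tanh((V - p.V3) / p.V4))
    dV = (
        p.Iapp
        - p.gL * (V - p.EL)
        - p.gK * n * (V - p.EK)
        - p.gCa * m_inf * (V - p.ECa)
    ) / p.Cm
    dn = p.phi * (n_inf - n) * np.cosh((V - p.V3) / (2 * p.V4))
    out = models.vector_field([V, n], p)
    assert out == pytest.approx([dV, dn], rel=1e-12)


def test_vector_field_shape_mismatch_raises():
    with pytest.raises(ValueError):
        models.vector_field([1.0, 2.0, 3.0], SNIC)


def test_modified_euler_step_matches_two_stage_construction():
    p = HOPF
    x = np.array([-30.0, 0.2])
    dt = 0.1
    f1 = models.vector_field(x, p)
    predictor = x + dt * f1
    f2 = models.vector_field(predictor, p)
    expected = x + 0.5 * dt * (f1 + f2)
    assert models.modified_euler_step(x, p, dt) == pytest.approx(expected, rel=1e-12)


def test_simulate_constant_grid_and_reproducibility():
    a = models.simulate(SNIC, t_end=100.0, dt=0.1)
    b = models.simulate(SNIC, t_end=100.0, dt=0.1)
    assert len(a.times) == 1001
    assert np.allclose(np.diff(a.times), 0.1)
    np.testing.assert_array_equal(a.states, b.states)


def test_simulate_blowup_raises_with_sample_index():
    # an absurdly large step makes the integration diverge
    with pytest.raises(FloatingPointError, match=r"sample index"):
        models.simulate(SNIC, t_end=10000.0, dt=50.0)


def test_bursting_simulation_has_calcium_state():
    traj = models.simulate(SQUARE_WAVE, t_end=100.0, dt=1.0, substeps=40)
    assert traj.states.shape[1] == 3
    assert np.all(np.isfinite(traj.Ca))


def test_observe_with_noise_properties(spiking_trajectories):
    traj = spiking_trajectories["SNIC"]
    clean = models.observe_with_noise(traj, 0.0, seed=1)
    np.testing.assert_array_equal(clean.y, traj.V)
    noisy = models.observe_with_noise(traj, 0.01, seed=1)
    target = (0.01 * np.std(traj.V)) ** 2
    sample = np.var(noisy.y - traj.V)
    assert sample == pytest.approx(target, rel=0.02)
    assert noisy.R == pytest.approx(target, rel=1e-12)
    again = models.observe_with_noise(traj, 0.01, seed=1)
    np.testing.assert_array_equal(noisy.y, again.y)


def test_count_spikes_on_synthetic_trace():
    dt = 0.1
    t = np.arange(0, 100, dt)
    V = np.full_like(t, -40.0)
    for spike_time in (10.0, 30.0, 70.0):
        mask = (t >= spike_time) & (t < spike_time + 1.0)
        V[mask] = 20.0
    assert models.count_spikes(V, dt=dt) == 3
    # crossings closer than the refractory separation merge
    V2 = np.full_like(t, -40.0)
    for spike_time in (10.0, 10.5, 30.0):
        mask = (t >= spike_time) & (t < spike_time + 0.2)
        V2[mask] = 20.0
    assert models.count_spikes(V2, dt=dt, min_separation=2.0) == 2


def test_count_bursts_grouping():
    dt = 0.1
    t = np.arange(0, 3000, dt)
    V = np.full_like(t, -40.0)
    # two bursts of three spikes (50 ms apart) separated by a 800 ms gap
    for start in (100.0, 1500.0):
        for k in range(3):
            mask = (t >= start + 50 * k) & (t < start + 50 * k + 1.0)
            V[mask] = 20.0
    n_bursts, modal = models.count_bursts(V, dt=dt, isi_gap=200.0)
    assert (n_bursts, modal) == (2, 3)


def test_count_bursts_empty_trace():
    V = np.full(1000, -40.0)
    assert models.count_bursts(V, dt=0.1) == (0, 0)


def test_trajectory_and_series_csv_round_trip(tmp_path):
    traj = models.simulate(SNIC, t_end=10.0, dt=0.1)
    series = models.observe_with_noise(traj, 0.01, seed=3)
    path = tmp_path / "obs.csv"
    series.to_csv(path)
    back = models.ObservationSeries.from_csv(path)
    np.testing.assert_allclose(back.y, series.y)
    np.testing.assert_allclose(back.times, series.times)
    assert back.R == pytest.approx(series.R)
    assert back.seed == 3
    traj.to_csv(tmp_path / "traj.csv")
    assert (tmp_path / "traj.csv.json").exists()


def test_params_validation_and_presets():
    with pytest.raises(ValueError):
        SpikingParams(**{**{f: getattr(SNIC, f) for f in (
            "phi", "gCa", "V3", "V4", "gK", "gL", "V1", "V2",
            "Cm", "ECa", "EK", "EL", "Iapp")}, "Cm": -1.0})
    assert isinstance(get_regime("snic"), SpikingParams)
    assert isinstance(get_regime("square-wave"), BurstingParams)
    with pytest.raises(KeyError):
        get_regime("nope")
    # theta round trip
    p2 = SNIC.with_theta(SNIC.theta())
    assert p2 == SNIC


def test_default_initial_state_fires_in_every_spiking_regime():
    for p in (HOPF, SNIC, HOMOCLINIC):
        traj = models.simulate(p, t_end=1000.0, dt=0.1)
        assert models.count_spikes(traj) > 0
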