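"""Morris–Lecar simulation, synthetic observations, and event counting.

This module generates the ground-truth data for twin experiments: it
integrates the spiking or bursting Morris–Lecar equations with a two-stage
modified-Euler (Heun) scheme, corrupts the voltage with additive Gaussian
noise whose standard deviation is a fraction of the signal's own standard
deviation, and counts spike and burst events on voltage traces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from .params import BurstingParams, SpikingParams

__all__ = [
    "Trajectory",
    "ObservationSeries",
    "gate_functions",
    "vector_field",
    "modified_euler_step",
    "simulate",
    "observe_with_noise",
    "count_spikes",
    "count_bursts",
    "default_initial_state",
]


@dataclass(frozen=True)
class Trajectory:
    """Deterministic model trajectory on a constant-step time grid."""

    times: np.ndarray
    states: np.ndarray  # (n_samples, L): columns V, n [, Ca]
    params: SpikingParams
    dt: float
    substeps: int

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states length mismatch")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
                raise ValueError("time grid must have a constant step")

    @property
    def V(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def n(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def Ca(self) -> np.ndarray:
        if self.states.shape[1] < 3:
            raise AttributeError("spiking trajectory has no Ca component")
        return self.states[:, 2]

    def to_csv(self, path: str | Path) -> None:
        cols = ["V", "n", "Ca"][: self.states.shape[1]]
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "t", self.times)
        df.to_csv(path, index=False)
        meta = {
            "dt": self.dt,
            "substeps": self.substeps,
            "params": {f.name: getattr(self.params, f.name) for f in fields(self.params)},
            "model": "bursting" if isinstance(self.params, BurstingParams) else "spiking",
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


@dataclass(frozen=True)
class ObservationSeries:
    """Noisy scalar voltage observations with known noise variance."""

    times: np.ndarray
    y: np.ndarray
    noise_scale: float  # epsilon: noise std as a fraction of signal std
    R: float  # observation-noise variance (epsilon * sigma_true)^2
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.y):
            raise ValueError("times and y length mismatch")
        if self.R < 0:
            raise ValueError("R must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.times, "y": self.y}).to_csv(path, index=False)
        meta = {"noise_scale": self.noise_scale, "R": self.R, "seed": self.seed}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationSeries":
        df = pd.read_csv(path)
        side = Path(str(path) + ".json")
        meta = json.loads(side.read_text()) if side.exists() else {}
        return cls(
            times=df["t"].to_numpy(),
            y=df["y"].to_numpy(),
            noise_scale=float(meta.get("noise_scale", 0.0)),
            R=float(meta.get("R", 0.0)),
            seed=meta.get("seed"),
        )


def gate_functions(V, params: SpikingParams):
    """Steady-state activations and the gate time constant at voltage ``V``.

    Returns ``(m_inf, n_inf, tau_n)`` where ``m_inf`` is the instantaneous
    Ca-channel activation, ``n_inf`` the K-gate steady state and ``tau_n``
    its voltage-dependent relaxation time (before division by ``phi``).
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite voltage")
    m_inf = 0.5 * (1.0 + np.tanh((V - params.V1) / params.V2))
    n_inf = 0.5 * (1.0 + np.tanh((V - params.V3) / params.V4))
    tau_n = 1.0 / np.cosh((V - params.V3) / (2.0 * params.V4))
    return m_inf, n_inf, tau_n


def vector_field(state, params: SpikingParams) -> np.ndarray:
    """Time derivative of the model state.

    ``state`` is ``(V, n)`` for the spiking model or ``(V, n, Ca)`` for the
    bursting model; the variant must match the parameter type.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (params.n_states,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({params.n_states},) "
            f"for {type(params).__name__}"
        )
    if isinstance(params, BurstingParams):
        dV, dn, dCa = _kernels.rhs_bursting(
            state[0], state[1], state[2], params.theta(), params.consts()
        )
        return np.array([dV, dn, dCa])
    dV, dn = _kernels.rhs_spiking(
        state[0], state[1], params.theta(), params.consts(), 0.0
    )
    return np.array([dV, dn])


def modified_euler_step(state, params: SpikingParams, dt: float) -> np.ndarray:
    """One two-stage (Heun / modified-Euler) step of size ``dt``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state")
    if isinstance(params, BurstingParams):
        out = _kernels.heun_bursting(
            state[0], state[1], state[2], params.theta(), params.consts(), dt
        )
    else:
        if state.shape != (2,):
            raise ValueError("spiking state must be (V, n)")
        out = _kernels.heun_spiking(
            state[0], state[1], params.theta(), params.consts(), 0.0, dt
        )
    return np.array(out)


def default_initial_state(params: SpikingParams) -> np.ndarray:
    """Standard data-generation initial condition: ``(V, n) = (-22, 0)``.

    A depolarized state with the K gate closed lies inside the basin of the
    spiking attractor in every preset regime -- including the bistable
    homoclinic regime, where a hyperpolarized start would relax to the
    coexisting stable equilibrium and never fire.  The bursting model adds
    ``Ca = 2``, near the middle of its slow oscillation range.  Long windows
    make the results attractor-dominated, so the transient washes out.
    """
    if isinstance(params, BurstingParams):
        return np.array([-22.0, 0.0, 2.0])
    return np.array([-22.0, 0.0])


def simulate(
    params: SpikingParams,
    x0=None,
    t_end: float = 20000.0,
    dt: float = 0.1,
    substeps: int = 1,
) -> Trajectory:
    """Integrate the model, sampling every ``dt`` ms.

    Each sample interval is covered by ``substeps`` internal Heun steps
    (the bursting protocol uses 1 ms samples with 0.025 ms substeps).
    Raises if the state becomes non-finite, naming the failing sample.
    """
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    n_intervals = t_end / dt
    if abs(n_intervals - round(n_intervals)) > 1e-9 * max(1.0, n_intervals):
        raise ValueError("t_end must be an integral number of dt steps")
    n_samples = int(round(n_intervals)) + 1
    if x0 is None:
        x0 = default_initial_state(params)
    x0 = np.asarray(x0, dtype=float)

    if isinstance(params, BurstingParams):
        V, n, Ca, bad = _kernels.simulate_bursting(
            x0[0], x0[1], x0[2], params.theta(), params.consts(), dt, substeps, n_samples
        )
        states = np.column_stack([V, n, Ca])
    else:
        V, n, bad = _kernels.simulate_spiking(
            x0[0], x0[1], params.theta(), params.consts(), 0.0, dt, substeps, n_samples
        )
        states = np.column_stack([V, n])
    if bad >= 0:
        raise FloatingPointError(f"integration blew up at sample index {bad}")
    times = np.arange(n_samples) * dt
    return Trajectory(times=times, states=states, params=params, dt=dt, substeps=substeps)


def observe_with_noise(
    traj: Trajectory, eps: float, seed: int | None = None
) -> ObservationSeries:
    """Additive Gaussian observation noise on the voltage trace.

    The noise is white with variance ``(eps * std(V_true))**2``, where the
    standard deviation is that of the noiseless simulated voltage over the
    full window; that nominal variance is stored as ``R``.
    """
    if eps < 0:
        raise ValueError("eps must be non-negative")
    sigma_true = float(np.std(traj.V))
    noise_std = eps * sigma_true
    rng = np.random.default_rng(seed)
    eta = rng.normal(0.0, noise_std, size=len(traj.V)) if noise_std > 0 else 0.0
    return ObservationSeries(
        times=traj.times.copy(),
        y=traj.V + eta,
        noise_scale=eps,
        R=noise_std**2,
        seed=seed,
    )


def count_spikes(
    trace, threshold: float = 0.0, min_separation: float = 2.0, dt: float | None = None
) -> int:
    """Count upward threshold crossings separated by a refractory gap.

    ``trace`` may be a Trajectory, an ObservationSeries, or a voltage array
    (in which case ``dt`` must be given).
    """
    V, dt = _voltage_and_dt(trace, dt)
    if len(V) == 0:
        raise ValueError("empty trace")
    return len(spike_times(V, dt, threshold, min_separation))


def spike_times(
    V: np.ndarray, dt: float, threshold: float = 0.0, min_separation: float = 2.0
) -> np.ndarray:
    """Times (ms) of upward threshold crossings with a refractory gap."""
    up = np.flatnonzero((V[:-1] < threshold) & (V[1:] >= threshold)) + 1
    if len(up) == 0:
        return np.empty(0)
    t = up * dt
    keep = [t[0]]
    for ti in t[1:]:
        if ti - keep[-1] >= min_separation:
            keep.append(ti)
    return np.asarray(keep)


def count_bursts(
    trace,
    spike_threshold: float = 0.0,
    isi_gap: float = 200.0,
    min_separation: float = 2.0,
    dt: float | None = None,
) -> tuple[int, int]:
    """Group spikes into bursts by inter-spike-interval gap.

    Consecutive spikes closer than ``isi_gap`` ms belong to the same burst.
    Returns the burst count and the modal number of spikes per burst
    (``(0, 0)`` when there are no spikes).
    """
    V, dt = _voltage_and_dt(trace, dt)
    if len(V) == 0:
        raise ValueError("empty trace")
    t = spike_times(V, dt, spike_threshold, min_separation)
    if len(t) == 0:
        return 0, 0
    # split where the ISI reaches the gap
    breaks = np.flatnonzero(np.diff(t) >= isi_gap)
    sizes = np.diff(np.concatenate([[0], breaks + 1, [len(t)]]))
    vals, counts = np.unique(sizes, return_counts=True)
    modal = int(vals[np.argmax(counts)])
    return len(sizes), modal


def _voltage_and_dt(trace, dt):
    if isinstance(trace, Trajectory):
        return trace.V, trace.dt
    if isinstance(trace, ObservationSeries):
        return trace.y, trace.dt
    V = np.asarray(trace, dtype=float)
    if dt is None:
        raise ValueError("dt required when passing a bare voltage array")
    return V, dt
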