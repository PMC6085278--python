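"""Augmented-state unscented Kalman filtering for joint state/parameter estimation.

The filter promotes the unknown model parameters to state components with
artificial random-walk dynamics (noise entering only through the process
covariance ``Q``) and estimates the augmented state ``(V, q, theta)`` from a
scalar voltage series.  Sigma points are drawn as the columns of a lower
Cholesky factor of ``(N + lambda) P``; after the forecast they are, by
default, redistributed about the forecast mean before the measurement
update.  A classical linear Kalman filter is included as an independent
oracle: the unscented transform is exact for affine maps, so the two must
agree on linear systems.

The production path (`run_ukf` / `UnscentedKalmanFilter`) runs a compiled
loop; the numpy building blocks (`sigma_points`, `unscented_forecast`,
`measurement_update`) implement the identical equations and exist for
composition and cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator

from . import _kernels
from .models import ObservationSeries
from .params import BurstingParams, SpikingParams

__all__ = [
    "SigmaEnsemble",
    "UKFConfig",
    "FilterHistory",
    "sigma_points",
    "unscented_forecast",
    "measurement_update",
    "run_ukf",
    "run_ukf_generic",
    "linear_kf_oracle",
    "UnscentedKalmanFilter",
    "default_process_noise",
]


class FilterFailure(RuntimeError):
    """Covariance square root or innovation variance became unusable."""


@dataclass(frozen=True)
class SigmaEnsemble:
    """Deterministic ensemble matching a Gaussian's first two moments."""

    points: np.ndarray  # (2N+1, N)
    weights: np.ndarray  # (2N+1,)


@dataclass
class UKFConfig:
    """Filter settings.

    lam
        sigma-point spread; positive values widen the ensemble, values in
        (-N, 0) shrink it.
    alpha_i
        initial covariance scale, ``P(0) = alpha_i * I`` over the full
        augmented state.
    qdiag
        process-noise diagonal; ``None`` selects the standard recipe
        ``1e-7 * [max(y)-min(y), 1 (per gate/Ca), |theta0|]``.
    r
        observation-noise variance; ``None`` takes the series' known ``R``.
    clamp_gates
        pull the gate variable back into [0, 1] before every integration
        substep (rescues the filter when large initial covariances push
        ``n`` out of its biophysical range).
    redistribute
        redraw sigma points about the forecast mean/covariance before the
        measurement update.
    """

    lam: float = 5.0
    alpha_i: float = 1e-3
    qdiag: np.ndarray | None = None
    r: float | None = None
    clamp_gates: bool = False
    redistribute: bool = True
    q_scale: float = 1e-7


@dataclass
class FilterHistory:
    """Per-observation analysis record of one filter pass."""

    times: np.ndarray
    means: np.ndarray  # (T, N) analysis means of the augmented state
    cov_diag: np.ndarray  # (T, N) analysis covariance diagonals
    innovations: np.ndarray  # (T,)
    failed: bool
    fail_step: int  # -1 when the filter completed
    theta_names: tuple[str, ...] = ()

    @property
    def n_assimilated(self) -> int:
        return len(self.times) if not self.failed else self.fail_step

    def final_theta(self, n_states: int) -> np.ndarray:
        k = self.fail_step - 1 if self.failed else -1
        return self.means[k, n_states:].copy()


# ---------------------------------------------------------------------------
# Building blocks (numpy)


def _sqrt_cov(P: np.ndarray, scale: float) -> np.ndarray:
    """Lower Cholesky of ``scale * sym(P)`` with escalating diagonal jitter."""
    A = 0.5 * (P + P.T) * scale
    jitters = [0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6]
    for j in jitters:
        try:
            return np.linalg.cholesky(A + j * scale * np.eye(len(A)))
        except np.linalg.LinAlgError:
            continue
    raise FilterFailure("covariance square root failed after jitter escalation")


def sigma_weights(n_dim: int, lam: float) -> np.ndarray:
    if lam <= -n_dim:
        raise ValueError("lambda must exceed -N")
    w = np.full(2 * n_dim + 1, 1.0 / (2.0 * (n_dim + lam)))
    w[0] = lam / (n_dim + lam)
    return w


def sigma_points(mean: np.ndarray, cov: np.ndarray, lam: float) -> SigmaEnsemble:
    """2N+1 sigma points whose weighted mean/covariance equal (mean, cov)."""
    mean = np.asarray(mean, dtype=float)
    n = len(mean)
    S = _sqrt_cov(np.asarray(cov, dtype=float), n + lam)
    pts = np.empty((2 * n + 1, n))
    pts[0] = mean
    pts[1 : n + 1] = mean + S.T
    pts[n + 1 :] = mean - S.T
    return SigmaEnsemble(points=pts, weights=sigma_weights(n, lam))


def ensemble_moments(points: np.ndarray, weights: np.ndarray):
    mean = weights @ points
    d = points - mean
    cov = (weights[:, None] * d).T @ d
    return mean, cov


def unscented_forecast(
    ens: SigmaEnsemble, step_map: Callable[[np.ndarray], np.ndarray], Q: np.ndarray
):
    """Propagate an ensemble through ``step_map`` and add process noise.

    Returns the forecast mean, forecast covariance, and the mapped points.
    """
    mapped = np.array([step_map(p) for p in ens.points])
    if not np.all(np.isfinite(mapped)):
        raise FilterFailure("non-finite propagated sigma point")
    mean, cov = ensemble_moments(mapped, ens.weights)
    return mean, cov + Q, mapped


def measurement_update(
    forecast_mean: np.ndarray,
    forecast_cov: np.ndarray,
    mapped: np.ndarray,
    weights: np.ndarray,
    y_obs: float,
    R: float,
    redistribute: bool = True,
    lam: float | None = None,
):
    """Kalman analysis step with a voltage-projection observation operator.

    With ``redistribute`` on, the mapped points are replaced by a fresh
    draw about the forecast mean with the forecast covariance before the
    observation statistics are formed (``lam`` is then required).
    """
    if redistribute:
        if lam is None:
            raise ValueError("lam required when redistributing sigma points")
        ens = sigma_points(forecast_mean, forecast_cov, lam)
        mapped, weights = ens.points, ens.weights
    Y = mapped[:, 0]
    yb = weights @ Y
    dy = Y - yb
    Pyy = weights @ (dy * dy) + R
    if not np.isfinite(Pyy) or Pyy <= 0:
        raise FilterFailure("non-positive innovation variance")
    dX = mapped - forecast_mean
    Pxy = (weights * dy) @ dX
    K = Pxy / Pyy
    mean = forecast_mean + K * (y_obs - yb)
    cov = forecast_cov - np.outer(K, Pxy)
    cov = 0.5 * (cov + cov.T)
    return mean, cov


def run_ukf_generic(
    observations: np.ndarray,
    step_map: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    P0: np.ndarray,
    Q: np.ndarray,
    R: float,
    lam: float,
    redistribute: bool = True,
) -> FilterHistory:
    """Reference UKF loop over an arbitrary step map (numpy, un-jitted).

    Observes the first component of the state.  Used for small problems and
    cross-checks; the Morris–Lecar path goes through `run_ukf`.
    """
    T = len(observations)
    N = len(x0)
    means = np.zeros((T, N))
    covd = np.zeros((T, N))
    innov = np.zeros(T)
    x, P = np.asarray(x0, float).copy(), np.asarray(P0, float).copy()
    means[0], covd[0] = x, np.diag(P)
    for k in range(1, T):
        try:
            ens = sigma_points(x, P, lam)
            xb, Pf, mapped = unscented_forecast(ens, step_map, Q)
            x, P = measurement_update(
                xb, Pf, mapped, ens.weights, observations[k], R, redistribute, lam
            )
        except FilterFailure:
            return FilterHistory(
                times=np.arange(T, dtype=float),
                means=means,
                cov_diag=covd,
                innovations=innov,
                failed=True,
                fail_step=k,
            )
        innov[k] = observations[k] - (xb[0] if not redistribute else xb[0])
        means[k], covd[k] = x, np.diag(P)
    return FilterHistory(
        times=np.arange(T, dtype=float),
        means=means,
        cov_diag=covd,
        innovations=innov,
        failed=False,
        fail_step=-1,
    )


# ---------------------------------------------------------------------------
# Morris–Lecar production path


def default_process_noise(
    y: np.ndarray, theta0: np.ndarray, n_states: int, scale: float = 1e-7
) -> np.ndarray:
    """Process-noise diagonal: ``scale * [range(y), 1 per gate/Ca, |theta0|]``."""
    gates = np.ones(n_states - 1)
    return scale * np.concatenate([[np.max(y) - np.min(y)], gates, np.abs(theta0)])


def run_ukf(
    series: ObservationSeries,
    guess: SpikingParams,
    config: UKFConfig | None = None,
    substeps: int | None = None,
    n0: float = 0.0,
    ca0: float = 1.0,
) -> FilterHistory:
    """Full augmented-state UKF pass over a voltage series.

    ``guess`` supplies the initial parameter estimates and the known
    constants (capacitance, reversals, applied current, and for the
    bursting model the slow-timescale constants, which are not estimated).
    The initial voltage is the first observation and the initial gate guess
    is ``n0`` (0 by default).  Filter failure is recorded in the returned
    history, not raised.
    """
    config = config or UKFConfig()
    bursting = isinstance(guess, BurstingParams)
    L = guess.n_states
    if substeps is None:
        substeps = 40 if bursting else 1
    theta0 = guess.theta()
    x0 = np.concatenate([[series.y[0], n0] + ([ca0] if bursting else []), theta0])
    qdiag = (
        np.asarray(config.qdiag, dtype=float)
        if config.qdiag is not None
        else default_process_noise(series.y, theta0, L, config.q_scale)
    )
    if len(qdiag) != len(x0):
        raise ValueError("qdiag length must match the augmented state")
    R = series.R if config.r is None else config.r
    means, covd, innov, fail = _kernels.ukf_run(
        np.asarray(series.y, dtype=float),
        series.dt,
        substeps,
        x0,
        guess.consts(),
        config.lam,
        config.alpha_i,
        qdiag,
        float(R),
        config.clamp_gates,
        config.redistribute,
        bursting,
        L,
    )
    return FilterHistory(
        times=series.times,
        means=means,
        cov_diag=covd,
        innovations=innov,
        failed=fail >= 0,
        fail_step=int(fail),
        theta_names=guess.theta_names(),
    )


def linear_kf_oracle(F, H, Q, R, x0, P0, observations) -> FilterHistory:
    """Classical Kalman filter on a linear state-space system.

    Independent oracle for the unscented transform: on a linear model the
    UKF must reproduce these means and covariances to machine precision.
    """
    F, H, Q, P = map(np.atleast_2d, (F, H, Q, P0))
    R = np.atleast_2d(R)
    x = np.asarray(x0, float).copy()
    obs = np.atleast_2d(np.asarray(observations, float).T).T  # (T, M)
    T, N = len(obs), len(x)
    means = np.zeros((T, N))
    covd = np.zeros((T, N))
    innov = np.zeros(T)
    means[0], covd[0] = x, np.diag(P)
    for k in range(1, T):
        xf = F @ x
        Pf = F @ P @ F.T + Q
        Py = H @ Pf @ H.T + R
        if abs(np.linalg.det(Py)) < 1e-300:
            raise np.linalg.LinAlgError("singular innovation covariance")
        K = Pf @ H.T @ np.linalg.inv(Py)
        e = obs[k] - H @ xf
        x = xf + K @ e
        P = (np.eye(N) - K @ H) @ Pf
        means[k], covd[k] = x, np.diag(P)
        innov[k] = e[0]
    return FilterHistory(
        times=np.arange(T, dtype=float),
        means=means,
        cov_diag=covd,
        innovations=innov,
        failed=False,
        fail_step=-1,
    )


# ---------------------------------------------------------------------------
# Estimator front end


class UnscentedKalmanFilter(BaseEstimator):
    """Joint state/parameter estimator for Morris–Lecar voltage data.

    Parameters
    ----------
    guess : SpikingParams or BurstingParams
        Initial parameter estimates plus the known constants.
    lam, alpha_i, q_scale, qdiag, r, clamp_gates, redistribute
        See `UKFConfig`.
    substeps : int or None
        Heun substeps per observation interval (1 for the spiking
        protocol, 40 for the bursting protocol when None).
    n0, ca0 : float
        Initial guesses for the unobserved states.

    Attributes
    ----------
    theta_ : ndarray
        Final parameter estimates (analysis mean at the last assimilated
        observation).
    params_ : SpikingParams or BurstingParams
        ``guess`` with the estimated parameters substituted.
    history_ : FilterHistory
    failed_ : bool
    """

    def __init__(
        self,
        guess: SpikingParams | None = None,
        lam: float = 5.0,
        alpha_i: float = 1e-3,
        q_scale: float = 1e-7,
        qdiag=None,
        r=None,
        clamp_gates: bool = False,
        redistribute: bool = True,
        substeps=None,
        n0: float = 0.0,
        ca0: float = 1.0,
    ):
        self.guess = guess
        self.lam = lam
        self.alpha_i = alpha_i
        self.q_scale = q_scale
        self.qdiag = qdiag
        self.r = r
        self.clamp_gates = clamp_gates
        self.redistribute = redistribute
        self.substeps = substeps
        self.n0 = n0
        self.ca0 = ca0

    def fit(self, X: ObservationSeries, y=None) -> "UnscentedKalmanFilter":
        if self.guess is None:
            raise ValueError("guess parameters are required")
        cfg = UKFConfig(
            lam=self.lam,
            alpha_i=self.alpha_i,
            qdiag=self.qdiag,
            r=self.r,
            clamp_gates=self.clamp_gates,
            redistribute=self.redistribute,
            q_scale=self.q_scale,
        )
        self.history_ = run_ukf(
            X, self.guess, cfg, substeps=self.substeps, n0=self.n0, ca0=self.ca0
        )
        self.failed_ = self.history_.failed
        self.theta_ = self.history_.final_theta(self.guess.n_states)
        self.params_ = self.guess.with_theta(self.theta_)
        return self

    def predict(self, X: ObservationSeries | None = None) -> np.ndarray:
        """Analysis voltage track for the fitted series."""
        if not hasattr(self, "history_"):
            raise RuntimeError("call fit first")
        return self.history_.means[:, 0]
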