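"""Weak-constraint 4D-Var trajectory-and-parameter optimization.

The decision vector stacks every state at every observation time plus the
parameters, ``[V_0..V_N, n_0..n_N (, Ca_0..Ca_N), theta_1..theta_D]``, and
the cost balances measurement misfit against one-step model misfit::

    C(x) = 1/2 sum_k R^-1 (y_k - V_k)^2
         + 1/2 sum_l sum_k Q_ll^-1 (x_{l,k+1} - f_l(x_k))^2

where ``f`` is a single modified-Euler (Heun) step between observation
times.  The gradient is assembled analytically from hand-derived Jacobians
of the Heun map (chain rule through its two stages), and the Hessian's
structural sparsity — nearest-neighbour time coupling plus a dense
parameter border — is exposed for sparse Newton-type optimizers.
Optimization uses bound-constrained limited-memory quasi-Newton (L-BFGS-B)
with bounds applied to the parameters only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse
from sklearn.base import BaseEstimator

from . import _kernels
from .models import ObservationSeries
from .params import BurstingParams, SpikingParams

__all__ = [
    "VarConfig",
    "DecisionLayout",
    "evaluate_cost",
    "cost_and_grad",
    "cost_and_grad_reference",
    "hessian_sparsity",
    "initial_guess",
    "run_weak_4dvar",
    "cost_surface_slice",
    "default_bounds",
    "WeakFourDVar",
]

# Parameter box constraints keeping conductances, the rate phi, and the
# activation slopes positive.
SPIKING_BOUNDS = (
    (0.0, 1.0),  # phi
    (0.0, 10.0),  # gCa
    (-20.0, 20.0),  # V3
    (0.1, 35.0),  # V4
    (0.0, 10.0),  # gK
    (0.0, 5.0),  # gL
    (-10.0, 20.0),  # V1
    (0.1, 35.0),  # V2
)
GKCA_BOUNDS = (0.0, 5.0)


def default_bounds(params: SpikingParams) -> tuple[tuple[float, float], ...]:
    if isinstance(params, BurstingParams):
        return SPIKING_BOUNDS + (GKCA_BOUNDS,)
    return SPIKING_BOUNDS


@dataclass
class VarConfig:
    """Weights, bounds, and optimizer settings for the weak-4D-Var problem.

    ``qinv_diag`` are the per-state model weights before scaling by
    ``alpha_q``; the default ``[1, 100^2]`` (plus ``100^2`` for Ca)
    balances the dynamic range of V against the unit-range gates.
    ``rinv=None`` takes ``1/R`` from the observation series.
    """

    alpha_q: float = 100.0
    qinv_diag: np.ndarray | None = None
    rinv: float | None = None
    bounds: tuple | None = None  # parameter bounds; None -> default_bounds
    maxiter: int = 50_000
    gtol: float = 1e-6
    ftol: float = 1e-10

    def resolved_qinv(self, n_states: int) -> np.ndarray:
        if self.qinv_diag is not None:
            q = np.asarray(self.qinv_diag, dtype=float)
        else:
            q = np.array([1.0] + [100.0**2] * (n_states - 1))
        return self.alpha_q * q

    def resolved_rinv(self, series: ObservationSeries) -> float:
        if self.rinv is not None:
            return float(self.rinv)
        # a noiseless series still needs a finite measurement weight
        return 1.0 / series.R if series.R > 0 else 1e12


@dataclass(frozen=True)
class DecisionLayout:
    """Index bookkeeping for the stacked decision vector."""

    n_times: int  # N+1 grid points
    n_states: int  # L
    n_params: int  # D

    @property
    def size(self) -> int:
        return self.n_times * self.n_states + self.n_params

    def state_index(self, l: int, k: int) -> int:
        if not (0 <= l < self.n_states and 0 <= k < self.n_times):
            raise IndexError("state index out of range")
        return l * self.n_times + k

    def theta_index(self, d: int) -> int:
        if not 0 <= d < self.n_params:
            raise IndexError("parameter index out of range")
        return self.n_states * self.n_times + d

    def unpack(self, x: np.ndarray):
        """Split a flat vector into a (T, L) state matrix and theta."""
        T, L = self.n_times, self.n_states
        states = x[: T * L].reshape(L, T).T
        return states, x[T * L :]

    def pack(self, states: np.ndarray, theta: np.ndarray) -> np.ndarray:
        return np.concatenate([states.T.ravel(), theta])


def layout_for(series: ObservationSeries, params: SpikingParams) -> DecisionLayout:
    return DecisionLayout(
        n_times=len(series.y),
        n_states=params.n_states,
        n_params=len(params.theta_names()),
    )


# ---------------------------------------------------------------------------
# Vector field values + derivatives, vectorized over time


def _field_terms(V, n, Ca, th, c, bursting):
    """f, df/dstate, df/dtheta at each time point (vectorized).

    Returns ``f`` (T, L), ``A`` (T, L, L) and ``G`` (T, L, D).
    """
    phi, gCa, V3, V4, gK, gL, V1, V2 = th[:8]
    Cm, ECa, EK, EL, Iapp = c[:5]
    T = V.shape[0]
    L = 3 if bursting else 2
    D = 9 if bursting else 8

    u1 = (V - V1) / V2
    t1 = np.tanh(u1)
    sech2_1 = 1.0 - t1 * t1
    minf = 0.5 * (1.0 + t1)
    u3 = (V - V3) / V4
    t3 = np.tanh(u3)
    sech2_3 = 1.0 - t3 * t3
    ninf = 0.5 * (1.0 + t3)
    w = (V - V3) / (2.0 * V4)
    ch = np.cosh(w)
    sh = np.sinh(w)

    dminf = sech2_1 / (2.0 * V2)
    dninf = sech2_3 / (2.0 * V4)

    ICa = gCa * minf * (V - ECa)
    fV = (Iapp - gL * (V - EL) - gK * n * (V - EK) - ICa) / Cm
    fn = phi * ch * (ninf - n)

    f = np.empty((T, L))
    A = np.zeros((T, L, L))
    G = np.zeros((T, L, D))

    A[:, 0, 0] = (-gL - gK * n - gCa * (dminf * (V - ECa) + minf)) / Cm
    A[:, 0, 1] = -gK * (V - EK) / Cm
    A[:, 1, 0] = phi * (sh / (2.0 * V4) * (ninf - n) + ch * dninf)
    A[:, 1, 1] = -phi * ch

    # df/dtheta: columns phi, gCa, V3, V4, gK, gL, V1, V2 (, gKCa)
    G[:, 0, 1] = -minf * (V - ECa) / Cm
    G[:, 0, 4] = -n * (V - EK) / Cm
    G[:, 0, 5] = -(V - EL) / Cm
    G[:, 0, 6] = gCa * (V - ECa) * sech2_1 / (2.0 * V2) / Cm
    G[:, 0, 7] = gCa * (V - ECa) * sech2_1 * u1 / (2.0 * V2) / Cm
    G[:, 1, 0] = ch * (ninf - n)
    G[:, 1, 2] = phi * (-sh / (2.0 * V4) * (ninf - n) - ch * sech2_3 / (2.0 * V4))
    G[:, 1, 3] = phi * (-sh * w / V4 * (ninf - n) - ch * sech2_3 * u3 / (2.0 * V4))

    if bursting:
        gKCa = th[8]
        eps, mu = c[5], c[6]
        z = Ca / (Ca + 1.0)
        zp = 1.0 / (Ca + 1.0) ** 2
        fV = fV - gKCa * z * (V - EK) / Cm
        fCa = eps * (-mu * ICa - Ca)
        A[:, 0, 0] += -gKCa * z / Cm
        A[:, 0, 2] = -gKCa * zp * (V - EK) / Cm
        A[:, 2, 0] = -eps * mu * gCa * (dminf * (V - ECa) + minf)
        A[:, 2, 2] = -eps
        G[:, 0, 8] = -z * (V - EK) / Cm
        G[:, 2, 1] = -eps * mu * minf * (V - ECa)
        G[:, 2, 6] = eps * mu * gCa * (V - ECa) * sech2_1 / (2.0 * V2)
        G[:, 2, 7] = eps * mu * gCa * (V - ECa) * sech2_1 * u1 / (2.0 * V2)
        f[:, 2] = fCa
    f[:, 0] = fV
    f[:, 1] = fn
    return f, A, G


def _heun_map_and_jac(states, theta, params, dt, with_jac):
    """Heun map F(x_k) of each trajectory point, with dF/dx and dF/dtheta.

    ``states`` has shape (T, L); the map acts on rows 0..T-2 conceptually
    but is evaluated at all rows (callers slice as needed).
    """
    bursting = isinstance(params, BurstingParams)
    c = params.consts()
    V, n = states[:, 0], states[:, 1]
    Ca = states[:, 2] if bursting else None
    f1, A1, G1 = _field_terms(V, n, Ca, theta, c, bursting)
    mid = states + dt * f1
    Vm, nm = mid[:, 0], mid[:, 1]
    Cam = mid[:, 2] if bursting else None
    f2, A2, G2 = _field_terms(Vm, nm, Cam, theta, c, bursting)
    F = states + 0.5 * dt * (f1 + f2)
    if not with_jac:
        return F, None, None
    L = states.shape[1]
    eye = np.eye(L)
    # dF/dx = I + dt/2 (A1 + A2 (I + dt A1))
    inner = eye[None, :, :] + dt * A1
    J = eye[None, :, :] + 0.5 * dt * (A1 + np.einsum("tab,tbc->tac", A2, inner))
    # dF/dtheta = dt/2 (G1 + dt A2 G1 + G2)
    Gmap = 0.5 * dt * (G1 + dt * np.einsum("tab,tbd->tad", A2, G1) + G2)
    return F, J, Gmap


# ---------------------------------------------------------------------------
# Cost, gradient, sparsity


def cost_and_grad(
    x: np.ndarray,
    series: ObservationSeries,
    params: SpikingParams,
    cfg: VarConfig,
    with_gradient: bool = True,
):
    """Weak-4D-Var cost and (optionally) its analytic gradient.

    Evaluated by a fused compiled kernel; ``cost_and_grad_reference`` is the
    plain-numpy implementation of the same quantities, kept for cross-checks.
    """
    lay = layout_for(series, params)
    x = np.asarray(x, dtype=float)
    if x.shape != (lay.size,):
        raise ValueError(f"decision vector has length {x.size}, expected {lay.size}")
    bursting = isinstance(params, BurstingParams)
    cost, grad, bad = _kernels.weak4dvar_cost_grad(
        np.ascontiguousarray(x),
        lay.n_times,
        lay.n_states,
        params.consts(),
        series.y,
        series.dt,
        cfg.resolved_qinv(lay.n_states),
        cfg.resolved_rinv(series),
        bursting,
        with_gradient,
    )
    if bad >= 0:
        raise FloatingPointError(f"non-finite model residual at time index {bad}")
    if not with_gradient:
        return float(cost), None
    return float(cost), grad


def cost_and_grad_reference(
    x: np.ndarray,
    series: ObservationSeries,
    params: SpikingParams,
    cfg: VarConfig,
    with_gradient: bool = True,
):
    """Plain-numpy reference for ``cost_and_grad`` (identical quantities)."""
    lay = layout_for(series, params)
    x = np.asarray(x, dtype=float)
    if x.shape != (lay.size,):
        raise ValueError(f"decision vector has length {x.size}, expected {lay.size}")
    states, theta = lay.unpack(x)
    dt = series.dt
    qinv = cfg.resolved_qinv(lay.n_states)
    rinv = cfg.resolved_rinv(series)

    F, J, G = _heun_map_and_jac(states[:-1], theta, params, dt, with_gradient)
    resid = states[1:] - F  # (T-1, L)
    if not np.all(np.isfinite(resid)):
        bad = int(np.argwhere(~np.isfinite(resid))[0][0])
        raise FloatingPointError(f"non-finite model residual at time index {bad}")
    merr = series.y - states[:, 0]
    cost = 0.5 * rinv * merr @ merr + 0.5 * np.sum(qinv * resid * resid)
    if not with_gradient:
        return float(cost), None

    wres = qinv * resid  # (T-1, L)
    gstates = np.zeros_like(states)
    gstates[:, 0] -= rinv * merr
    gstates[1:] += wres
    gstates[:-1] -= np.einsum("tl,tlm->tm", wres, J)
    gtheta = -np.einsum("tl,tld->d", wres, G)
    return float(cost), lay.pack(gstates, gtheta)


def evaluate_cost(
    x, series, params, cfg: VarConfig | None = None, with_gradient: bool = False
):
    """Convenience wrapper returning (cost, gradient-or-None)."""
    return cost_and_grad(x, series, params, cfg or VarConfig(), with_gradient)


def hessian_sparsity(n_times: int, n_states: int, n_params: int) -> scipy.sparse.csr_matrix:
    """Structural nonzero pattern of the cost Hessian.

    Each one-step residual couples the states at time ``k`` with those at
    ``k+1`` and with the parameters, so state blocks are block-tridiagonal
    in time and the parameter rows/columns form a dense border.
    """
    lay = DecisionLayout(n_times, n_states, n_params)
    rows, cols = [], []
    T = n_times
    k = np.arange(T)
    for l1 in range(n_states):
        for l2 in range(n_states):
            for off in (-1, 0, 1):
                kk = k[(k + off >= 0) & (k + off < T)]
                rows.append(l1 * T + kk)
                cols.append(l2 * T + kk + off)
    state_dim = n_states * T
    ti = state_dim + np.arange(n_params)
    all_i = np.arange(lay.size)
    rows.append(np.repeat(ti, lay.size))
    cols.append(np.tile(all_i, n_params))
    rows.append(np.tile(all_i, n_params))
    cols.append(np.repeat(ti, lay.size))
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    pat = scipy.sparse.coo_matrix(
        (np.ones_like(r, dtype=bool), (r, c)), shape=(lay.size, lay.size)
    )
    return pat.tocsr()


def initial_guess(
    series: ObservationSeries,
    params: SpikingParams,
    n0: float | None = None,
    ca0: float | None = None,
    bounds=None,
) -> np.ndarray:
    """Standard starting point for the optimization.

    The voltage block is the observed trace; the gate block is the gate
    equation integrated forward while forced by the observed voltage with
    the guess parameters (and the Ca block likewise for the bursting
    model); the parameter block is the guess.  Parameters are clipped into
    the bounds.
    """
    theta = params.theta()
    y = np.asarray(series.y, dtype=float)
    dt = series.dt
    if n0 is None:
        n0 = 0.5 * (1.0 + np.tanh((y[0] - params.V3) / params.V4))
    n = _kernels.forced_gate(y, float(n0), theta, dt)
    cols = [y, n]
    if isinstance(params, BurstingParams):
        c = params.consts()
        if ca0 is None:
            ICa0 = params.gCa * 0.5 * (1 + np.tanh((y[0] - params.V1) / params.V2)) * (
                y[0] - params.ECa
            )
            ca0 = max(-params.mu * ICa0, 0.0)
        cols.append(_kernels.forced_calcium(y, float(ca0), theta, c, dt))
    if bounds is None:
        bounds = default_bounds(params)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    theta = np.clip(theta, lo, hi)
    lay = layout_for(series, params)
    return lay.pack(np.column_stack(cols), theta)


def run_weak_4dvar(
    series: ObservationSeries,
    guess: SpikingParams,
    cfg: VarConfig | None = None,
    x0: np.ndarray | None = None,
):
    """Minimize the weak-4D-Var cost with bounded L-BFGS.

    Returns ``(x_opt, info)`` where ``info`` carries the iterate cost log,
    optimizer status, iteration count, and the final cost.  Bounds act on
    the parameter block only; state entries are free.
    """
    cfg = cfg or VarConfig()
    lay = layout_for(series, guess)
    pbounds = cfg.bounds if cfg.bounds is not None else default_bounds(guess)
    if x0 is None:
        x0 = initial_guess(series, guess, bounds=pbounds)
    bounds = [(None, None)] * (lay.n_states * lay.n_times) + list(pbounds)
    cost_log: list[float] = []

    def fun(x):
        return cost_and_grad(x, series, guess, cfg, with_gradient=True)

    def cb(xk):
        cost_log.append(cost_and_grad(xk, series, guess, cfg, with_gradient=False)[0])

    res = scipy.optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        callback=cb,
        options={
            "maxiter": cfg.maxiter,
            "gtol": cfg.gtol,
            "ftol": cfg.ftol,
            "maxfun": 10 * cfg.maxiter,
        },
    )
    info = {
        "cost_log": np.asarray(cost_log),
        "status": "ok" if res.success else "optimizer_maxiter",
        "message": res.message,
        "n_iter": res.nit,
        "cost": float(res.fun),
    }
    return res.x, info


def cost_surface_slice(
    x0: np.ndarray,
    x_min_deep: np.ndarray,
    x_min_shallow: np.ndarray,
    series: ObservationSeries,
    params: SpikingParams,
    cfg: VarConfig | None = None,
    alphas: np.ndarray | None = None,
    betas: np.ndarray | None = None,
) -> np.ndarray:
    """log10 cost on the affine 2-plane through a start point and two minima.

    Evaluates ``C(x0 (1-a)(1-b) + a x_deep + b x_shallow)`` on the (a, b)
    grid; at (0,0) the cost is that of ``x0``, at (1,0) that of the deep
    minimum, and at (0,1) that of the shallow one.
    """
    cfg = cfg or VarConfig()
    if alphas is None:
        alphas = np.linspace(-0.2, 1.2, 29)
    if betas is None:
        betas = np.linspace(-0.2, 1.2, 29)
    out = np.empty((len(alphas), len(betas)))
    for i, a in enumerate(alphas):
        for j, b in enumerate(betas):
            x = x0 * (1 - a) * (1 - b) + a * x_min_deep + b * x_min_shallow
            out[i, j] = np.log10(
                cost_and_grad(x, series, params, cfg, with_gradient=False)[0] + 1e-300
            )
    return out


# ---------------------------------------------------------------------------
# Estimator front end


class WeakFourDVar(BaseEstimator):
    """Trajectory-optimization estimator for Morris–Lecar voltage data.

    Parameters mirror `VarConfig`; ``guess`` supplies initial parameter
    values and known constants.  After `fit`:

    Attributes
    ----------
    x_opt_ : ndarray
        Optimal stacked decision vector.
    theta_ : ndarray
        Estimated parameters.
    params_ : SpikingParams or BurstingParams
    cost_log_ : ndarray
        Cost at each accepted iterate.
    status_ : str
        ``"ok"`` or ``"optimizer_maxiter"``.
    """

    def __init__(
        self,
        guess: SpikingParams | None = None,
        alpha_q: float = 100.0,
        qinv_diag=None,
        rinv=None,
        bounds=None,
        maxiter: int = 50_000,
        gtol: float = 1e-6,
        ftol: float = 1e-12,
        x0=None,
    ):
        self.guess = guess
        self.alpha_q = alpha_q
        self.qinv_diag = qinv_diag
        self.rinv = rinv
        self.bounds = bounds
        self.maxiter = maxiter
        self.gtol = gtol
        self.ftol = ftol
        self.x0 = x0

    def _config(self) -> VarConfig:
        return VarConfig(
            alpha_q=self.alpha_q,
            qinv_diag=self.qinv_diag,
            rinv=self.rinv,
            bounds=self.bounds,
            maxiter=self.maxiter,
            gtol=self.gtol,
            ftol=self.ftol,
        )

    def fit(self, X: ObservationSeries, y=None) -> "WeakFourDVar":
        if self.guess is None:
            raise ValueError("guess parameters are required")
        x_opt, info = run_weak_4dvar(X, self.guess, self._config(), x0=self.x0)
        lay = layout_for(X, self.guess)
        self.x_opt_ = x_opt
        self.states_, self.theta_ = lay.unpack(x_opt)
        self.params_ = self.guess.with_theta(self.theta_)
        self.cost_log_ = info["cost_log"]
        self.status_ = info["status"]
        self.n_iter_ = info["n_iter"]
        self.cost_ = info["cost"]
        return self

    def predict(self, X=None) -> np.ndarray:
        """Optimized voltage trajectory."""
        if not hasattr(self, "states_"):
            raise RuntimeError("call fit first")
        return self.states_[:, 0]
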