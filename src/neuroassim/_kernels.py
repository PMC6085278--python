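"""Numba-compiled numerical kernels.

Everything here works on plain float64 arrays so it can be JIT-compiled:
the Morris–Lecar vector fields, the two-stage modified-Euler (Heun) step,
long-trajectory simulation loops, forced gate integration, and the full
augmented-state unscented Kalman recursion.

Estimated-parameter ordering (``th``): phi, gCa, V3, V4, gK, gL, V1, V2
[, gKCa].  Fixed constants (``c``): Cm, ECa, EK, EL, Iapp [, ca_eps, mu].
The spiking kernels accept an extra frozen K(Ca)-type conductance ``gz``
(a constant-gating potassium term ``gz*(V-EK)``) so the same code serves
the bursting model's fast subsystem with the slow variable held fixed;
plain spiking runs use ``gz = 0``.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Vector fields


@njit(cache=True)
def rhs_spiking(V, n, th, c, gz):
    phi, gCa, V3, V4, gK, gL, V1, V2 = (
        th[0], th[1], th[2], th[3], th[4], th[5], th[6], th[7],
    )
    Cm, ECa, EK, EL, Iapp = c[0], c[1], c[2], c[3], c[4]
    minf = 0.5 * (1.0 + np.tanh((V - V1) / V2))
    ninf = 0.5 * (1.0 + np.tanh((V - V3) / V4))
    inv_tau = np.cosh((V - V3) / (2.0 * V4))
    dV = (
        Iapp
        - gL * (V - EL)
        - gK * n * (V - EK)
        - gCa * minf * (V - ECa)
        - gz * (V - EK)
    ) / Cm
    dn = phi * (ninf - n) * inv_tau
    return dV, dn


@njit(cache=True)
def rhs_bursting(V, n, Ca, th, c):
    phi, gCa, V3, V4, gK, gL, V1, V2, gKCa = (
        th[0], th[1], th[2], th[3], th[4], th[5], th[6], th[7], th[8],
    )
    Cm, ECa, EK, EL, Iapp = c[0], c[1], c[2], c[3], c[4]
    eps, mu = c[5], c[6]
    minf = 0.5 * (1.0 + np.tanh((V - V1) / V2))
    ninf = 0.5 * (1.0 + np.tanh((V - V3) / V4))
    inv_tau = np.cosh((V - V3) / (2.0 * V4))
    z = Ca / (Ca + 1.0)
    ICa = gCa * minf * (V - ECa)
    dV = (
        Iapp
        - gL * (V - EL)
        - gK * n * (V - EK)
        - ICa
        - gKCa * z * (V - EK)
    ) / Cm
    dn = phi * (ninf - n) * inv_tau
    dCa = eps * (-mu * ICa - Ca)
    return dV, dn, dCa


# ---------------------------------------------------------------------------
# Modified-Euler (Heun) steps


@njit(cache=True)
def heun_spiking(V, n, th, c, gz, dt):
    dV1, dn1 = rhs_spiking(V, n, th, c, gz)
    Vt = V + dt * dV1
    nt = n + dt * dn1
    dV2, dn2 = rhs_spiking(Vt, nt, th, c, gz)
    return V + 0.5 * dt * (dV1 + dV2), n + 0.5 * dt * (dn1 + dn2)


@njit(cache=True)
def heun_bursting(V, n, Ca, th, c, dt):
    dV1, dn1, dCa1 = rhs_bursting(V, n, Ca, th, c)
    Vt = V + dt * dV1
    nt = n + dt * dn1
    Ct = Ca + dt * dCa1
    dV2, dn2, dCa2 = rhs_bursting(Vt, nt, Ct, th, c)
    return (
        V + 0.5 * dt * (dV1 + dV2),
        n + 0.5 * dt * (dn1 + dn2),
        Ca + 0.5 * dt * (dCa1 + dCa2),
    )


# ---------------------------------------------------------------------------
# Trajectory simulation
#
# The loops return the index of the first sample at which the state became
# non-finite (-1 on success) rather than raising inside compiled code.


@njit(cache=True)
def simulate_spiking(V0, n0, th, c, gz, dt, substeps, n_samples):
    V = np.empty(n_samples)
    n = np.empty(n_samples)
    V[0], n[0] = V0, n0
    h = dt / substeps
    v, g = V0, n0
    for k in range(1, n_samples):
        for _ in range(substeps):
            v, g = heun_spiking(v, g, th, c, gz, h)
        if not (np.isfinite(v) and np.isfinite(g)):
            return V, n, k
        V[k], n[k] = v, g
    return V, n, -1


@njit(cache=True)
def simulate_bursting(V0, n0, Ca0, th, c, dt, substeps, n_samples):
    V = np.empty(n_samples)
    n = np.empty(n_samples)
    Ca = np.empty(n_samples)
    V[0], n[0], Ca[0] = V0, n0, Ca0
    h = dt / substeps
    v, g, ca = V0, n0, Ca0
    for k in range(1, n_samples):
        for _ in range(substeps):
            v, g, ca = heun_bursting(v, g, ca, th, c, h)
        if not (np.isfinite(v) and np.isfinite(g) and np.isfinite(ca)):
            return V, n, Ca, k
        V[k], n[k], Ca[k] = v, g, ca
    return V, n, Ca, -1


@njit(cache=True)
def forced_gate(Vobs, n0, th, dt):
    """Integrate the gate equation with V clamped to an observed trace.

    Heun step with the voltage taken at the surrounding observation times;
    used to build trajectory-optimization initial guesses.
    """
    phi, V3, V4 = th[0], th[2], th[3]
    T = Vobs.shape[0]
    n = np.empty(T)
    n[0] = n0
    for k in range(T - 1):
        Va, Vb = Vobs[k], Vobs[k + 1]
        ninf_a = 0.5 * (1.0 + np.tanh((Va - V3) / V4))
        d1 = phi * (ninf_a - n[k]) * np.cosh((Va - V3) / (2.0 * V4))
        nt = n[k] + dt * d1
        ninf_b = 0.5 * (1.0 + np.tanh((Vb - V3) / V4))
        d2 = phi * (ninf_b - nt) * np.cosh((Vb - V3) / (2.0 * V4))
        n[k + 1] = n[k] + 0.5 * dt * (d1 + d2)
    return n


@njit(cache=True)
def forced_calcium(Vobs, Ca0, th, c, dt):
    """Integrate the slow Ca equation with V clamped to an observed trace."""
    gCa, V1, V2 = th[1], th[6], th[7]
    ECa, eps, mu = c[1], c[5], c[6]
    T = Vobs.shape[0]
    Ca = np.empty(T)
    Ca[0] = Ca0
    for k in range(T - 1):
        Va, Vb = Vobs[k], Vobs[k + 1]
        ICa_a = gCa * 0.5 * (1.0 + np.tanh((Va - V1) / V2)) * (Va - ECa)
        d1 = eps * (-mu * ICa_a - Ca[k])
        Ct = Ca[k] + dt * d1
        ICa_b = gCa * 0.5 * (1.0 + np.tanh((Vb - V1) / V2)) * (Vb - ECa)
        d2 = eps * (-mu * ICa_b - Ct)
        Ca[k + 1] = Ca[k] + 0.5 * dt * (d1 + d2)
    return Ca


# ---------------------------------------------------------------------------
# Weak-constraint 4D-Var cost and gradient
#
# One fused pass over the trajectory: at each interval evaluate the vector
# field and its state/parameter Jacobians at both Heun stages, form the
# one-step residual, and accumulate the cost together with its gradient
# with respect to the states at k, k+1 and the parameters.


@njit(cache=True)
def _field_ad(V, n, Ca, th, c, bursting, f, A, G):
    """Vector field with analytic d/dstate and d/dtheta at one point.

    Fills the preallocated ``f`` (L,), ``A`` (L, L), ``G`` (L, D) in place.
    Theta ordering: phi, gCa, V3, V4, gK, gL, V1, V2 [, gKCa].
    """
    phi, gCa, V3, V4 = th[0], th[1], th[2], th[3]
    gK, gL, V1, V2 = th[4], th[5], th[6], th[7]
    Cm, ECa, EK, EL, Iapp = c[0], c[1], c[2], c[3], c[4]

    u1 = (V - V1) / V2
    t1 = np.tanh(u1)
    sech2_1 = 1.0 - t1 * t1
    minf = 0.5 * (1.0 + t1)
    u3 = (V - V3) / V4
    t3 = np.tanh(u3)
    sech2_3 = 1.0 - t3 * t3
    ninf = 0.5 * (1.0 + t3)
    w = 0.5 * u3
    ch = np.cosh(w)
    sh = np.sinh(w)
    dminf = sech2_1 / (2.0 * V2)
    dninf = sech2_3 / (2.0 * V4)

    ICa = gCa * minf * (V - ECa)
    fV = (Iapp - gL * (V - EL) - gK * n * (V - EK) - ICa) / Cm
    fn = phi * ch * (ninf - n)

    for a in range(A.shape[0]):
        for b in range(A.shape[1]):
            A[a, b] = 0.0
        for d in range(G.shape[1]):
            G[a, d] = 0.0

    A[0, 0] = (-gL - gK * n - gCa * (dminf * (V - ECa) + minf)) / Cm
    A[0, 1] = -gK * (V - EK) / Cm
    A[1, 0] = phi * (sh / (2.0 * V4) * (ninf - n) + ch * dninf)
    A[1, 1] = -phi * ch

    G[0, 1] = -minf * (V - ECa) / Cm
    G[0, 4] = -n * (V - EK) / Cm
    G[0, 5] = -(V - EL) / Cm
    G[0, 6] = gCa * (V - ECa) * sech2_1 / (2.0 * V2) / Cm
    G[0, 7] = gCa * (V - ECa) * sech2_1 * u1 / (2.0 * V2) / Cm
    G[1, 0] = ch * (ninf - n)
    G[1, 2] = phi * (-sh / (2.0 * V4) * (ninf - n) - ch * sech2_3 / (2.0 * V4))
    G[1, 3] = phi * (-sh * w / V4 * (ninf - n) - ch * sech2_3 * u3 / (2.0 * V4))

    if bursting:
        gKCa = th[8]
        eps, mu = c[5], c[6]
        z = Ca / (Ca + 1.0)
        zp = 1.0 / ((Ca + 1.0) * (Ca + 1.0))
        fV -= gKCa * z * (V - EK) / Cm
        f[2] = eps * (-mu * ICa - Ca)
        A[0, 0] += -gKCa * z / Cm
        A[0, 2] = -gKCa * zp * (V - EK) / Cm
        A[2, 0] = -eps * mu * gCa * (dminf * (V - ECa) + minf)
        A[2, 2] = -eps
        G[0, 8] = -z * (V - EK) / Cm
        G[2, 1] = -eps * mu * minf * (V - ECa)
        G[2, 6] = eps * mu * gCa * (V - ECa) * sech2_1 / (2.0 * V2)
        G[2, 7] = eps * mu * gCa * (V - ECa) * sech2_1 * u1 / (2.0 * V2)
    f[0] = fV
    f[1] = fn


@njit(cache=True)
def weak4dvar_cost_grad(x, T, L, c, y, dt, qinv, rinv, bursting, with_grad):
    """Weak-4D-Var cost and analytic gradient in one fused trajectory pass.

    ``x`` is the flat decision vector: L state blocks of length T
    (component-major: all V, then all n[, then all Ca]) followed by the D
    parameters.  ``qinv`` is the per-component model-error precision (L,),
    ``rinv`` the scalar measurement precision.  Returns (cost, grad, bad)
    with ``grad`` in the same flat layout and ``bad`` the first interval
    with a non-finite residual (-1 if none); on failure the cost/gradient
    contents are unusable.
    """
    D = x.shape[0] - T * L
    theta = x[T * L:]
    grad = np.zeros(x.shape[0])
    gtheta = grad[T * L:]

    f1 = np.empty(L)
    f2 = np.empty(L)
    A1 = np.empty((L, L))
    A2 = np.empty((L, L))
    G1 = np.empty((L, D))
    G2 = np.empty((L, D))
    J = np.empty((L, L))
    Gmap = np.empty((L, D))
    resid = np.empty(L)

    cost = 0.0
    # measurement term
    for k in range(T):
        e = y[k] - x[k]
        cost += 0.5 * rinv * e * e
        if with_grad:
            grad[k] -= rinv * e

    half = 0.5 * dt
    for k in range(T - 1):
        V = x[k]
        n = x[T + k]
        Ca = x[2 * T + k] if bursting else 0.0
        _field_ad(V, n, Ca, theta, c, bursting, f1, A1, G1)
        Vm = V + dt * f1[0]
        nm = n + dt * f1[1]
        Cam = Ca + dt * f1[2] if bursting else 0.0
        _field_ad(Vm, nm, Cam, theta, c, bursting, f2, A2, G2)

        bad = False
        for a in range(L):
            Fa = x[a * T + k] + half * (f1[a] + f2[a])
            resid[a] = x[a * T + k + 1] - Fa
            if not np.isfinite(resid[a]):
                bad = True
        if bad:
            return cost, grad, k
        for a in range(L):
            cost += 0.5 * qinv[a] * resid[a] * resid[a]
        if not with_grad:
            continue

        # J = I + dt/2 (A1 + A2 (I + dt A1)); Gmap = dt/2 (G1 + dt A2 G1 + G2)
        for a in range(L):
            for b in range(L):
                s = A1[a, b] + A2[a, b]
                for m in range(L):
                    s += dt * A2[a, m] * A1[m, b]
                J[a, b] = half * s
            J[a, a] += 1.0
        for a in range(L):
            for d in range(D):
                s = G1[a, d] + G2[a, d]
                for m in range(L):
                    s += dt * A2[a, m] * G1[m, d]
                Gmap[a, d] = half * s

        for a in range(L):
            wr = qinv[a] * resid[a]
            grad[a * T + k + 1] += wr
            for b in range(L):
                grad[b * T + k] -= wr * J[a, b]
            for d in range(D):
                gtheta[d] -= wr * Gmap[a, d]

    return cost, grad, -1


# ---------------------------------------------------------------------------
# Unscented Kalman filter


@njit(cache=True)
def _chol_lower(A):
    """Plain lower Cholesky with an explicit success flag."""
    n = A.shape[0]
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0 or not np.isfinite(s):
                    return L, False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return L, True


@njit(cache=True)
def _sqrt_scaled_cov(P, scale):
    """Lower Cholesky of ``scale * sym(P)`` with escalating jitter.

    Jitter starts at 1e-10 on the diagonal of P and grows tenfold up to
    1e-6 before giving up.
    """
    n = P.shape[0]
    A = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = 0.5 * (P[i, j] + P[j, i]) * scale
    L, ok = _chol_lower(A)
    if ok:
        return L, True
    jitter = 1e-10
    while jitter <= 1e-6:
        B = A.copy()
        for i in range(n):
            B[i, i] += jitter * scale
        L, ok = _chol_lower(B)
        if ok:
            return L, True
        jitter *= 10.0
    return L, False


@njit(cache=True)
def _aug_step(x, L_states, th_dim, c, dt, substeps, clamp, bursting):
    """One observation-interval map of the augmented state.

    Model states are integrated with `substeps` Heun substeps; parameter
    components are carried through unchanged.  With ``clamp`` on, the gate
    variable is pulled back into [0, 1] before every substep.
    """
    out = x.copy()
    th = x[L_states:]
    h = dt / substeps
    v = x[0]
    g = x[1]
    if bursting:
        ca = x[2]
        for _ in range(substeps):
            if clamp:
                if g < 0.0:
                    g = 0.0
                elif g > 1.0:
                    g = 1.0
            v, g, ca = heun_bursting(v, g, ca, th, c, h)
        out[0], out[1], out[2] = v, g, ca
    else:
        for _ in range(substeps):
            if clamp:
                if g < 0.0:
                    g = 0.0
                elif g > 1.0:
                    g = 1.0
            v, g = heun_spiking(v, g, th, c, 0.0, h)
        out[0], out[1] = v, g
    return out


@njit(cache=True)
def ukf_run(
    y,
    dt,
    substeps,
    x0,
    c,
    lam,
    alpha_i,
    qdiag,
    R,
    clamp,
    redistribute,
    bursting,
    L_states,
):
    """Full augmented-state UKF pass over a scalar voltage series.

    Returns per-step analysis means, covariance diagonals, innovations and
    the index of the first failed step (-1 if the filter completed).
    Failure modes: covariance square root unrecoverable by jitter,
    non-finite propagated sigma point, or non-positive innovation variance.
    """
    T = y.shape[0]
    N = x0.shape[0]
    th_dim = N - L_states
    nsig = 2 * N + 1

    means = np.zeros((T, N))
    covd = np.zeros((T, N))
    innov = np.zeros(T)

    x = x0.copy()
    P = np.eye(N) * alpha_i
    means[0] = x
    for i in range(N):
        covd[0, i] = P[i, i]

    w0 = lam / (N + lam)
    wj = 1.0 / (2.0 * (N + lam))

    X = np.empty((nsig, N))
    Xp = np.empty((nsig, N))
    Yp = np.empty(nsig)

    for k in range(1, T):
        # -- sigma points about the previous analysis
        S, ok = _sqrt_scaled_cov(P, N + lam)
        if not ok:
            return means, covd, innov, k
        X[0] = x
        for j in range(N):
            for i in range(N):
                X[1 + j, i] = x[i] + S[i, j]
                X[1 + N + j, i] = x[i] - S[i, j]

        # -- forecast
        for j in range(nsig):
            Xp[j] = _aug_step(X[j], L_states, th_dim, c, dt, substeps, clamp, bursting)
            for i in range(N):
                if not np.isfinite(Xp[j, i]):
                    return means, covd, innov, k

        xb = np.zeros(N)
        for j in range(nsig):
            w = w0 if j == 0 else wj
            for i in range(N):
                xb[i] += w * Xp[j, i]

        Pf = np.zeros((N, N))
        for j in range(nsig):
            w = w0 if j == 0 else wj
            d = Xp[j] - xb
            for a in range(N):
                for b in range(N):
                    Pf[a, b] += w * d[a] * d[b]
        for i in range(N):
            Pf[i, i] += qdiag[i]

        # -- optional redistribution of sigma points about the forecast
        if redistribute:
            S2, ok = _sqrt_scaled_cov(Pf, N + lam)
            if not ok:
                return means, covd, innov, k
            Xp[0] = xb
            for j in range(N):
                for i in range(N):
                    Xp[1 + j, i] = xb[i] + S2[i, j]
                    Xp[1 + N + j, i] = xb[i] - S2[i, j]

        # -- measurement update (observation operator: voltage component)
        for j in range(nsig):
            Yp[j] = Xp[j, 0]
        yb = 0.0
        for j in range(nsig):
            w = w0 if j == 0 else wj
            yb += w * Yp[j]
        Pyy = R
        Pxy = np.zeros(N)
        for j in range(nsig):
            w = w0 if j == 0 else wj
            dy = Yp[j] - yb
            Pyy += w * dy * dy
            d = Xp[j] - xb
            for i in range(N):
                Pxy[i] += w * d[i] * dy
        if Pyy <= 0.0 or not np.isfinite(Pyy):
            return means, covd, innov, k

        e = y[k] - yb
        innov[k] = e
        for i in range(N):
            x[i] = xb[i] + Pxy[i] / Pyy * e
        for a in range(N):
            for b in range(N):
                P[a, b] = Pf[a, b] - Pxy[a] * Pxy[b] / Pyy
        # enforce exact symmetry
        for a in range(N):
            for b in range(a):
                m = 0.5 * (P[a, b] + P[b, a])
                P[a, b] = m
                P[b, a] = m

        means[k] = x
        for i in range(N):
            covd[k, i] = P[i, i]

    return means, covd, innov, -1
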