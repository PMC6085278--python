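"""Numerical bifurcation assay for estimated Morris–Lecar models.

Rather than numerical continuation, the assay combines three robust
primitives: dense root solving for equilibria of the voltage nullcline
reduction (at an equilibrium the gate sits on ``n = n_inf(V)``), eigenvalue
tracking of the analytic 2x2 Jacobian along branches (saddle-node events
where the branch count changes, Hopf events where a complex pair crosses
the imaginary axis), and simulation-based detection of stable limit cycles
with continuation-style initial conditions swept upward and downward in the
control parameter.  The control parameter is the applied current for the
spiking model, or the frozen slow gating value ``z`` for the bursting
model's fast subsystem (which sees an extra ``gKCa*z*(V-EK)`` current).

The qualitative output — which bifurcation starts and ends repetitive
firing — is the package's acceptance assay for estimated models: an
estimation run is judged successful when the estimated parameters undergo
the same bifurcations as the model that generated the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .params import BurstingParams, SpikingParams

__all__ = [
    "EquilibriumPoint",
    "CycleSample",
    "BifurcationDiagram",
    "equilibria_at",
    "sweep_equilibrium_branches",
    "limit_cycle_scan",
    "classify_regime",
    "fast_subsystem_diagram",
]

ROOT_TOL = 1e-10


@dataclass(frozen=True)
class EquilibriumPoint:
    control: float
    V: float
    n: float
    eigenvalues: tuple[complex, complex]
    stable: bool


@dataclass(frozen=True)
class CycleSample:
    control: float
    v_min: float
    v_max: float
    period: float


@dataclass
class BifurcationDiagram:
    equilibria: list[EquilibriumPoint]
    cycles: list[CycleSample]
    events: list[tuple[float, str]]  # (control value, type)
    regime: str = "unclassified"

    def event_controls(self, kind: str) -> list[float]:
        return [c for c, k in self.events if k == kind]


def _theta_consts(params: SpikingParams, control: float, control_kind: str):
    """theta/consts/gz for the 2-D flow at one control value."""
    th = params.theta()[:8]
    c = params.consts()[:5].copy()
    if control_kind == "iapp":
        c[4] = control
        gz = 0.0
    elif control_kind == "z":
        if not isinstance(params, BurstingParams):
            raise ValueError("z control requires bursting parameters")
        gz = params.gKCa * control
    else:
        raise ValueError("control_kind must be 'iapp' or 'z'")
    return th, c, gz


def _fV_reduced(V, th, c, gz):
    """Voltage derivative along the gate nullcline n = n_inf(V)."""
    ninf = 0.5 * (1.0 + np.tanh((V - th[2]) / th[3]))
    dV, _ = _kernels.rhs_spiking(V, ninf, th, c, gz)
    return dV


def _jacobian(V, n, th, c, gz):
    phi, gCa, V3, V4, gK, gL, V1, V2 = th
    Cm, ECa, EK, EL, Iapp = c
    t1 = np.tanh((V - V1) / V2)
    minf = 0.5 * (1 + t1)
    dminf = (1 - t1 * t1) / (2 * V2)
    t3 = np.tanh((V - V3) / V4)
    ninf = 0.5 * (1 + t3)
    dninf = (1 - t3 * t3) / (2 * V4)
    w = (V - V3) / (2 * V4)
    ch, sh = np.cosh(w), np.sinh(w)
    return np.array(
        [
            [
                (-gL - gK * n - gCa * (dminf * (V - ECa) + minf) - gz) / Cm,
                -gK * (V - EK) / Cm,
            ],
            [phi * (sh / (2 * V4) * (ninf - n) + ch * dninf), -phi * ch],
        ]
    )


def equilibria_at(
    control: float,
    params: SpikingParams,
    control_kind: str = "iapp",
    v_range: tuple[float, float] = (-90.0, 60.0),
    n_scan: int = 720,
) -> list[EquilibriumPoint]:
    """All equilibria of the 2-D flow at one control value.

    Roots of the reduced scalar equation (voltage derivative along the gate
    nullcline) are bracketed on a dense scan and polished with Brent's
    method; each equilibrium carries the eigenvalues of the analytic
    Jacobian and a stability label.
    """
    th, c, gz = _theta_consts(params, control, control_kind)
    Vs = np.linspace(v_range[0], v_range[1], n_scan)
    fs = _fV_reduced(Vs, th, c, gz)
    roots = []
    for i in range(len(Vs) - 1):
        a, b = fs[i], fs[i + 1]
        if a == 0.0:
            roots.append(Vs[i])
        elif a * b < 0:
            roots.append(brentq(_fV_reduced, Vs[i], Vs[i + 1], args=(th, c, gz), xtol=1e-13))
    if len(fs) and fs[-1] == 0.0:
        roots.append(Vs[-1])
    out = []
    for V in roots:
        n = 0.5 * (1.0 + np.tanh((V - th[2]) / th[3]))
        ev = np.linalg.eigvals(_jacobian(V, n, th, c, gz))
        out.append(
            EquilibriumPoint(
                control=float(control),
                V=float(V),
                n=float(n),
                eigenvalues=(complex(ev[0]), complex(ev[1])),
                stable=bool(np.max(ev.real) < 0),
            )
        )
    return out


def _max_real_stable_branch(control, params, control_kind, branch_v, window):
    """Real part of the leading eigenvalue of the equilibrium nearest branch_v."""
    eqs = equilibria_at(control, params, control_kind)
    if not eqs:
        return np.nan, branch_v
    best = min(eqs, key=lambda e: abs(e.V - branch_v))
    return max(e.real for e in best.eigenvalues), best.V


def sweep_equilibrium_branches(
    params: SpikingParams,
    control_range: tuple[float, float],
    n_grid: int = 200,
    control_kind: str = "iapp",
):
    """Equilibria over a control grid plus saddle-node and Hopf events.

    Saddle-nodes are located by bisection where the equilibrium count
    changes; Hopf events by bisection on the leading real part of a tracked
    branch where it changes sign.
    """
    grid = np.linspace(control_range[0], control_range[1], n_grid)
    all_eq: list[EquilibriumPoint] = []
    per_point = []
    for g in grid:
        eqs = equilibria_at(g, params, control_kind)
        per_point.append(eqs)
        all_eq.extend(eqs)

    events: list[tuple[float, str]] = []
    refine_tol = (control_range[1] - control_range[0]) * 1e-3

    # saddle-node: equilibrium count changes
    for i in range(len(grid) - 1):
        if len(per_point[i]) != len(per_point[i + 1]):
            lo, hi = grid[i], grid[i + 1]
            nlo = len(per_point[i])
            while hi - lo > refine_tol:
                mid = 0.5 * (lo + hi)
                if len(equilibria_at(mid, params, control_kind)) == nlo:
                    lo = mid
                else:
                    hi = mid
            events.append((0.5 * (lo + hi), "saddle-node"))

    # Hopf: leading real part of a matched branch crosses zero with complex pair
    for i in range(len(grid) - 1):
        for eq in per_point[i]:
            nxt = per_point[i + 1]
            if not nxt:
                continue
            mate = min(nxt, key=lambda e: abs(e.V - eq.V))
            if abs(mate.V - eq.V) > 10.0:
                continue
            r0 = max(e.real for e in eq.eigenvalues)
            r1 = max(e.real for e in mate.eigenvalues)
            osc = (abs(eq.eigenvalues[0].imag) > 1e-9) or (
                abs(mate.eigenvalues[0].imag) > 1e-9
            )
            if r0 * r1 < 0 and osc:
                lo, hi = grid[i], grid[i + 1]
                vref = eq.V
                while hi - lo > refine_tol:
                    mid = 0.5 * (lo + hi)
                    rm, vref_m = _max_real_stable_branch(mid, params, control_kind, vref, None)
                    if np.isnan(rm):
                        break
                    if rm * r0 > 0:
                        lo = mid
                        vref = vref_m
                    else:
                        hi = mid
                events.append((0.5 * (lo + hi), "hopf"))
    # deduplicate events closer than the refinement tolerance
    events = _dedupe(events, refine_tol * 2)
    return all_eq, events


def _dedupe(events, tol):
    out = []
    for c, k in sorted(events):
        if not any(k == k2 and abs(c - c2) < tol for c2, k2 in out):
            out.append((c, k))
    return out


def _simulate_fast(V0, n0, th, c, gz, t_end, dt=0.05):
    n_samples = int(round(t_end / dt)) + 1
    V, n, bad = _kernels.simulate_spiking(V0, n0, th, c, gz, dt, 1, n_samples)
    return V, n, dt, bad


def _cycle_at(control, params, control_kind, ic, transient, window, amp_threshold):
    """Detect a stable limit cycle at one control value by simulation.

    Returns (CycleSample | None, final_state) so sweeps can continue from
    the attractor reached at the previous control value.
    """
    th, c, gz = _theta_consts(params, control, control_kind)
    V, n, dt, bad = _simulate_fast(ic[0], ic[1], th, c, gz, transient + window)
    if bad >= 0:
        return None, ic
    k0 = int(round(transient / dt))
    Vs = V[k0:]
    final = (V[-1], n[-1])
    if Vs.max() - Vs.min() < amp_threshold:
        return None, final
    # period from mean interval between upward mean-crossings
    mid = 0.5 * (Vs.max() + Vs.min())
    up = np.flatnonzero((Vs[:-1] < mid) & (Vs[1:] >= mid))
    if len(up) < 2:
        return None, final
    period = float(np.mean(np.diff(up)) * dt)
    # a decaying transient also crosses the midline early on; require the
    # oscillation to persist to the end of the window
    if (len(Vs) - 1 - up[-1]) * dt > 2.0 * period:
        return None, final
    tail = Vs[3 * len(Vs) // 4:]
    if tail.max() - tail.min() < amp_threshold:
        return None, final
    return (
        CycleSample(
            control=float(control),
            v_min=float(Vs.min()),
            v_max=float(Vs.max()),
            period=period,
        ),
        final,
    )


def limit_cycle_scan(
    params: SpikingParams,
    control_range: tuple[float, float],
    n_grid: int = 120,
    control_kind: str = "iapp",
    transient: float = 2000.0,
    window: float = 3000.0,
    amp_threshold: float = 10.0,
):
    """Stable-cycle samples over a control grid, swept in both directions.

    An upward and a downward sweep each reuse the final state at the
    previous control value as the next initial condition, so a cycle is
    followed through bistable windows (needed near subcritical Hopf and
    saddle-node-of-periodic-orbit boundaries).  Samples from both sweeps
    are merged per control value.
    """
    grid = np.linspace(control_range[0], control_range[1], n_grid)
    found: dict[int, CycleSample] = {}

    for order in (range(len(grid)), range(len(grid) - 1, -1, -1)):
        ic = (-22.0, 0.0)
        for i in order:
            cyc, ic = _cycle_at(
                grid[i], params, control_kind, ic, transient, window, amp_threshold
            )
            if cyc is not None and i not in found:
                found[i] = cyc
    cycles = [found[i] for i in sorted(found)]
    return grid, cycles


@dataclass
class _CycleRegion:
    low: float
    high: float
    low_period: float
    mid_period: float
    high_period: float
    low_vmin: float = np.nan  # cycle V-minimum just inside the low edge
    high_vmin: float = np.nan
    low_probe: float = np.nan  # control value where the edge cycle was measured
    high_probe: float = np.nan


def _edge_sweep(
    params,
    control_kind,
    start_control,
    start_state,
    step,
    limit,
    transient,
    window,
    amp_threshold,
    tol,
):
    """Follow a stable cycle in control steps until it disappears.

    Starting from an on-cycle state, the sweep carries the final state of
    each simulation to the next control value (continuation through
    bistable windows), then bisects the disappearance point to ``tol``,
    always probing from the last on-cycle state.  Returns the refined edge
    and the cycle period measured just inside it with a long window.
    """
    control = start_control
    state = start_state
    inside, inside_state = start_control, start_state
    outside = None
    while True:
        nxt = control + step
        if (step < 0 and nxt < limit - 1e-12) or (step > 0 and nxt > limit + 1e-12):
            nxt = limit
        cyc, st = _cycle_at(nxt, params, control_kind, state, transient, window, amp_threshold)
        if cyc is None:
            outside = nxt
            break
        inside, inside_state, state = nxt, st, st
        control = nxt
        if abs(control - limit) < 1e-12:
            # cycle persists to the range edge
            return limit, cyc, limit, inside_state
    while abs(outside - inside) > tol:
        mid = 0.5 * (inside + outside)
        cyc, st = _cycle_at(
            mid, params, control_kind, inside_state, transient, window, amp_threshold
        )
        if cyc is None:
            outside = mid
        else:
            inside, inside_state = mid, st
    # re-measure the cycle just inside the edge with a long window; near a
    # fold of cycles the short-window probe can mistake a slow transient for
    # a cycle, so walk inward until a sustained cycle is found
    edge_cycle, edge_probe = None, np.nan
    back = tol
    for _ in range(10):
        probe = inside + back * (1.0 if step < 0 else -1.0)
        cyc_edge, _ = _cycle_at(
            probe, params, control_kind, inside_state, transient, 4 * window, amp_threshold
        )
        if cyc_edge is not None:
            edge_cycle, edge_probe = cyc_edge, probe
            break
        back *= 2.0
    return 0.5 * (inside + outside), edge_cycle, edge_probe, inside_state


def _cycle_region(params, control_range, control_kind, n_grid=120, transient=2000.0,
                  window=3000.0, amp_threshold=10.0, scan=None):
    """Locate the contiguous control region supporting a stable cycle.

    Returns None when no cycle is found.  Edges are refined by bisection
    while following the cycle (continuation-style), and the period is
    re-measured just inside each edge, where it diverges for
    saddle-node-on-invariant-circle and homoclinic terminations.  ``scan``
    may supply a precomputed ``(grid, cycles)`` pair from
    :func:`limit_cycle_scan` with matching settings.
    """
    grid, cycles = scan if scan is not None else limit_cycle_scan(
        params, control_range, n_grid, control_kind, transient, window, amp_threshold
    )
    if not cycles:
        return None
    controls = np.array([c.control for c in cycles])
    step = grid[1] - grid[0]
    tol = (control_range[1] - control_range[0]) * 1e-4

    mid_target = 0.5 * (controls.min() + controls.max())
    mid_cycle = min(cycles, key=lambda c: abs(c.control - mid_target))

    # land on the cycle at the region midpoint, then sweep both ways
    _, on_state = _cycle_at(
        mid_cycle.control, params, control_kind, (-22.0, 0.0), transient, window,
        amp_threshold,
    )
    low, low_cycle, low_probe, _ = _edge_sweep(
        params, control_kind, mid_cycle.control, on_state, -step, control_range[0],
        transient, window, amp_threshold, tol,
    )
    high, high_cycle, high_probe, _ = _edge_sweep(
        params, control_kind, mid_cycle.control, on_state, step, control_range[1],
        transient, window, amp_threshold, tol,
    )
    # representative interior period, measured at the refined-region midpoint
    # (the grid-scan anchor cycle may sit near an edge where the period is
    # already inflated)
    mid_period = mid_cycle.period
    cyc_mid, _ = _cycle_at(
        0.5 * (low + high), params, control_kind, on_state, transient, window,
        amp_threshold,
    )
    if cyc_mid is not None:
        mid_period = cyc_mid.period
    return _CycleRegion(
        low=low,
        high=high,
        low_period=float(low_cycle.period) if low_cycle else np.nan,
        mid_period=float(mid_period),
        high_period=float(high_cycle.period) if high_cycle else np.nan,
        low_vmin=float(low_cycle.v_min) if low_cycle else np.nan,
        high_vmin=float(high_cycle.v_min) if high_cycle else np.nan,
        low_probe=float(low_probe),
        high_probe=float(high_probe),
    )


def _saddle_touch(params, control_kind, probe_control, cycle_vmin, tol_mv=5.0):
    """True when a cycle's voltage minimum grazes a saddle equilibrium.

    A limit cycle terminating in a homoclinic (or saddle-node-on-invariant-
    circle) bifurcation collides with a saddle, so just inside the edge its
    minimum voltage sits within a few mV of the saddle's voltage; a fold of
    cycles leaves the cycle well clear of every equilibrium.
    """
    if not np.isfinite(probe_control) or not np.isfinite(cycle_vmin):
        return False
    for eq in equilibria_at(probe_control, params, control_kind):
        lam = np.asarray(eq.eigenvalues)
        is_saddle = np.all(np.isreal(lam)) and lam.real.min() < 0.0 < lam.real.max()
        if is_saddle and abs(cycle_vmin - eq.V) < tol_mv:
            return True
    return False


def classify_regime(
    params: SpikingParams,
    control_range: tuple[float, float] = (0.0, 250.0),
    n_grid: int = 120,
) -> str:
    """Label the excitability mechanism of a spiking parameter set.

    Decision rule on the low-current boundary of the stable-cycle region:
    coincidence with a saddle-node of equilibria plus diverging period is a
    SNIC; diverging period away from any saddle-node is a homoclinic
    termination; a finite-period boundary with a subcritical Hopf on the
    equilibrium branch is the Hopf mechanism.  Returns "unclassified" when
    no stable cycle exists in the swept range.
    """
    diagram = build_diagram(params, control_range, n_grid, "iapp")
    return diagram.regime


def build_diagram(
    params: SpikingParams,
    control_range: tuple[float, float],
    n_grid: int = 120,
    control_kind: str = "iapp",
) -> BifurcationDiagram:
    """Assemble equilibrium branches, cycle samples, events, and the label."""
    equilibria, events = sweep_equilibrium_branches(
        params, control_range, n_grid=max(n_grid, 150), control_kind=control_kind
    )
    grid, cycles = limit_cycle_scan(params, control_range, n_grid, control_kind)
    diagram = BifurcationDiagram(equilibria=equilibria, cycles=cycles, events=list(events))
    region = _cycle_region(
        params, control_range, control_kind, n_grid, scan=(grid, cycles)
    )
    if region is None:
        diagram.regime = "unclassified"
        return diagram

    span = control_range[1] - control_range[0]
    cell = span / n_grid
    sn = diagram.event_controls("saddle-node")
    hopf = diagram.event_controls("hopf")
    near_sn_low = any(abs(region.low - s) <= cell for s in sn)
    # a homoclinic termination is identified structurally: the edge cycle's
    # voltage minimum grazes a saddle equilibrium (fold-of-cycles edges stay
    # well clear of every equilibrium)
    saddle_low = _saddle_touch(params, control_kind, region.low_probe, region.low_vmin)
    saddle_high = _saddle_touch(params, control_kind, region.high_probe, region.high_vmin)

    if control_kind == "z":
        # fast-subsystem burst classification: what starts and ends the
        # active phase as the slow variable drifts
        if saddle_high and sn:
            diagram.regime = "square-wave"
            diagram.events.append((region.high, "homoclinic"))
        elif hopf and not saddle_high:
            diagram.regime = "elliptic"
            diagram.events.append((region.high, "snpo"))
        else:
            diagram.regime = "unclassified"
        return diagram

    # spiking classification: what terminates the cycle at its low-current
    # boundary (the onset mechanism as the current increases)
    if near_sn_low:
        diagram.regime = "snic"
        diagram.events.append((region.low, "snic"))
    elif saddle_low:
        diagram.regime = "homoclinic"
        diagram.events.append((region.low, "homoclinic"))
    elif hopf:
        diagram.regime = "hopf"
        diagram.events.append((region.low, "snpo"))
        diagram.events.append((region.high, "snpo"))
    else:
        diagram.regime = "unclassified"
    return diagram


def fast_subsystem_diagram(
    params: BurstingParams,
    z_range: tuple[float, float] = (0.0, 0.99),
    n_grid: int = 120,
) -> BifurcationDiagram:
    """Bifurcation diagram of the (V, n) fast subsystem vs frozen z.

    The slow variable enters only through the K(Ca) current, so freezing
    ``z`` leaves a 2-D flow; the burst class is read off the fast-subsystem
    bifurcations that start (saddle-node vs Hopf) and end (homoclinic vs
    saddle-node of periodic orbits) the spiking phase.  The diagram's
    ``regime`` is "square-wave", "elliptic", or "unclassified".
    """
    if not isinstance(params, BurstingParams):
        raise TypeError("fast_subsystem_diagram requires BurstingParams")
    return build_diagram(params, z_range, n_grid, "z")
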