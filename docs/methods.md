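# Methods

This note records the mathematical choices behind `neuroassim` precisely
enough to reimplement them. Everything empirical stated here is computed by
the package itself (the test suite or `scripts/acceptance.py`).

## Models

### Spiking model

Two states, voltage `V` (mV) and potassium gate `n ∈ [0, 1]`:

```
Cm dV/dt = Iapp − gL (V − EL) − gK n (V − EK) − gCa m∞(V) (V − ECa)
dn/dt    = φ (n∞(V) − n) cosh((V − V3) / (2 V4))
m∞(V) = ½ (1 + tanh((V − V1)/V2))
n∞(V) = ½ (1 + tanh((V − V3)/V4))
```

Calcium activation is instantaneous (`m = m∞(V)`). The estimated parameter
vector is `θ = (φ, gCa, V3, V4, gK, gL, V1, V2)`; `Cm`, the reversal
potentials, and `Iapp` are treated as known. Three presets place the model
in the three excitability regimes (`HOPF`, `SNIC`, `HOMOCLINIC` in
`neuroassim.params`); the names refer to the bifurcation through which
repetitive spiking appears as `Iapp` grows.

### Bursting model

Adds a slow calcium concentration `Ca` gating a K(Ca) current:

```
Cm dV/dt = … − gKCa z (V − EK),   z = Ca / (Ca + 1)
dCa/dt   = ε (−μ ICa − Ca),       ICa = gCa m∞(V) (V − ECa)
```

with `ε = 0.005`, `μ = 0.02` fixed and `gKCa` appended to `θ` (9
parameters). Presets `SQUARE_WAVE` and `ELLIPTIC` produce the two classic
burst types.

### Integration, observation, event counting

Trajectories are integrated with Heun's method (explicit trapezoidal /
modified Euler): a full Euler predictor followed by averaging the slopes at
both ends. Sampling every `dt` may use several internal substeps (the
bursting protocol samples at 1 ms with 0.025 ms substeps). A non-finite
state raises immediately with the failing sample index.

Observations are `y_k = V_k + η_k` with white Gaussian `η`,
`std(η) = eps · std(V)` over the window; the nominal variance is carried as
`R` on the series. Spikes are upward 0 mV crossings with a 2 ms refractory
gap; bursts group spikes whose inter-spike interval is below a gap
threshold (default 200 ms, chosen between the longest within-burst ISI and
the shortest inter-burst silence of the preset regimes).

## Unscented Kalman filter (`neuroassim.ukf`)

The augmented state `x = (V, n[, Ca], θ)` evolves by the model map for the
dynamical part and a random walk for `θ`. For dimension `d` and scaling
`λ`, the `2d+1` sigma points are `m` and `m ± columns of √((d+λ) P)`
(lower Cholesky), with weights `λ/(d+λ)` and `1/(2(d+λ))`. The forecast
propagates every point through the model map and adds process noise `Q`;
the scalar voltage observation then gives the standard Kalman update with
gain `C_xy / (P_yy + R)`.

Defaults follow the study protocol: `λ = 5`, initial covariance
`P0 = α_I · I` with `α_I = 10⁻³`, and
`Q = 10⁻⁷ · diag(range(y), 1[, 1], |θ₀|)` — a deliberately small random-walk
noise that lets parameters drift toward the data. After each update the
sigma ensemble is re-centered on the analysis mean ("redistribution",
default on). Optional gate clamping projects `n` (and `Ca`) sigma points
into their physical ranges.

Failure is data: if the Cholesky factorization loses positive-definiteness
or the state goes non-finite, the filter records the step and returns the
partial history with `failed = True` instead of raising. The
`(λ, α_I)` plane can be swept with `experiments.lambda_alpha_sweep` to map
the failure region; in our implementation the filter survives `α_I` up to
about 3 and begins failing around `α_I ≈ 10` (λ-dependent), with clamping
rescuing part of that band (see `tests/test_ukf.py::test_failure_region_location`).

`UnscentedKalmanFilter` wraps this as a scikit-learn-style estimator
(`fit(series)` → `theta_`, `params_`, `history_`, `failed_`).

## Weak-constraint 4D-Var (`neuroassim.fourdvar`)

Decision vector `x = (V₀..V_N, n₀..n_N[, Ca₀..Ca_N], θ)`. Cost:

```
J(x) = ½ Σ_k (y_k − V_k)² / R
     + ½ Σ_k (x_{k+1} − F(x_k, θ))ᵀ Q⁻¹ (x_{k+1} − F(x_k, θ))
```

where `F` is one Heun step and `Q⁻¹ = α_Q · diag(1, 100²[, 100²])` with
`α_Q = 100` by default — the gate (and calcium) dynamics are trusted 10⁴
times more than the voltage dynamics, and the constraint is *weak*: model
error is penalized, not forbidden. The gradient is analytic: each residual
contributes to `x_{k+1}` directly and to `(x_k, θ)` through the Jacobian of
the Heun step, so one pass costs `O(N)`. It matches finite differences to
~10⁻⁷ (tested). The Hessian support is block-tridiagonal in the states with
a dense border for `θ` (`hessian_sparsity`, verified against a dense
finite-difference Hessian).

Minimization is bound-constrained L-BFGS-B with parameter bounds wide
enough to contain all preset regimes. Initialization: `V` block from the
observations, gate block by integrating the gate equation forced by the
observed voltage, `θ` from the guess regime. Runs return a cost log and a
status (`ok` / `optimizer_maxiter`).

A caution established by the test suite: at the default weighting the MAP
estimate is *not* the true parameter vector — the optimizer finds decision
vectors with lower cost than the truth, trading small model-error residuals
for parameter shifts of several percent. Increasing `α_Q` toward the
strong-constraint limit (e.g. `10⁶`) drives the optimum back to the truth
(`tests/test_fourdvar.py::test_strong_constraint_limit_recovers_truth`);
weak-constraint parameter estimates should therefore be read as
weighting-dependent.

## Bifurcation assay (`neuroassim.bifurcation`)

For spiking parameters the control is `Iapp`; for the bursting fast
subsystem it is the frozen K(Ca) activation `z`. The assay:

1. **Equilibrium branches.** Roots of the scalar voltage equation with
   `n = n∞(V)` (Brent bracketing on a fine voltage grid), stability from
   the analytic 2×2 Jacobian.
2. **Events.** Sign changes of the discriminating quantities along the
   sweep (determinant for saddle-node, trace with negative determinant
   excluded for Hopf) refined by bisection.
3. **Limit cycles.** A grid sweep integrates long windows, discards
   transients, and detects sustained oscillations; continuation carries the
   final on-cycle state to the neighboring control value in both
   directions, which is essential in bistable windows where a cycle
   coexists with a stable equilibrium. Cycle edges are refined by bisection
   and the edge cycle is re-measured from an on-cycle initial state.
4. **Classification.** The regime label comes from the structure at the
   cycle's low-control edge: onset at a saddle-node of equilibria → `snic`;
   the cycle's minimum voltage touching a saddle equilibrium (real
   eigenvalues of both signs) at the edge → `homoclinic`; otherwise, with
   Hopf events present → `hopf`. For the bursting fast subsystem swept in
   `z`: a saddle-touch at the high-`z` edge together with a saddle-node →
   `square-wave`; a Hopf-bounded cycle without saddle contact → `elliptic`.

The saddle-touch test is structural rather than threshold-based: near a
homoclinic connection the periodic orbit passes arbitrarily close to the
saddle, while Hopf-side cycle edges (including saddle-nodes of periodic
orbits) stay far from any saddle.

## Twin-experiment harness (`neuroassim.experiments`)

`TwinExperimentSpec` fixes method, model, true and guess regimes, seed, and
protocol; `run_twin` generates data, estimates, optionally classifies the
estimated model, and returns parameters, RMSE, status, and runtime.
Protocols: UKF spiking 200,001 samples at 0.1 ms; 4D-Var spiking 2,001 at
0.1 ms; UKF bursting 200,001 at 1 ms (40 substeps); 4D-Var bursting 10,000
at 0.1 ms. `multistart_study` randomizes unobserved initial states and
clusters the resulting optima by relative cost; `write_outputs` emits the
parameter table (CSV), a JSON manifest with seeds and versions, and a run
log.
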