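# Methods

## Plant: two dissimilar Hodgkin-Huxley neurons

Each neuron follows the four-state conductance model

    C dV/dt = I_ext - g_K n⁴ (V - V_K) - g_Na m³h (V - V_Na) - g_L (V - V_L)
    dj/dt   = α_j(V)(1 - j) - β_j(V) j,        j ∈ {n, m, h}

with rate functions

    α_n = 0.1 (100-V) / [e^{(100-V)/100} - 1]     β_n = 0.15 e^{-V/100}
    α_m = 0.1 (15-V)  / [e^{(15-V)/5} - 1]        β_m = 4 e^{-V/10}
    α_h = 0.08 e^{-V/10}                          β_h = 1 / [e^{(30-V)/10} + 1]

These rates are deliberately reproduced as used by the study this
package models; they are *not* the canonical 1952 fits (note the
denominators 100 and 5, and β_n's prefactor). Consequences worth
knowing: all six rates are strictly positive for every finite V, so
gating variables remain in [0,1]; n∞ is close to 1 at rest, so the
resting potential sits close to V_K — numerically V ≈ 11.2 for the
master — rather than near 0. All quantities are treated as
dimensionless simulation units carrying the printed parameter values
(master: C=1, g_K=36, g_Na=120, g_L=0.3, V_K=12, V_Na=-115,
V_L=-10.613; slave: each of these scaled by 0.9, in the original
Hodgkin-Huxley sign convention). The removable singularities of α_n
(V=100) and α_m (V=15) are evaluated through `expm1` with a series-limit
branch inside |argument| < 1e-8.

The slave's membrane equation is divided by its own capacitance
C_S = 0.9 by default; a config switch (`slave_capacitance: CM`) restores
the alternative reading in which the master's capacitance appears.

## Stimulus: magneto-acoustic (Lorentz-force) current

An ultrasonic carrier at f = 200 Hz inside a static field B_x = 7 T
induces the current density amplitude σ B_x √(2Γ/(ρ c₀)) ≈ 3.769 A/m²
(σ = 0.5 S/m, Γ = 100 W/cm² converted internally to W/m², ρ = 1120
kg/m³, c₀ = 1540 m/s). The waveform is the amplitude times
sin(2π·MF·t)(sin(2π·f·t)+1), with modulation frequencies MF = 100 Hz
(master) and 104 Hz (slave). Because the study never states the
conversion from A/m² to membrane-current units, an explicit
dimensionless `amplitude_scale` (default 1) makes that bridge visible
instead of baking it in. The stimulus clock equals the solver clock
times `time_scale` (default 1, i.e. solver time is read as seconds).

## Funnel and error transformation

Performance function β(t) = (β₀-β∞)e^{-κt} + β∞ with defaults β₀ = 0.3,
β∞ = 0.02, κ = 0.6, overshoot fraction H = 0.9. The admissible band is
(-Hβ, β) when e(0) ≥ 0 (the bundled initial conditions give
e(0) = 0.2) and mirrors otherwise; the branch is fixed at t = 0, with
e(0) = 0 assigned to the nonnegative branch. The filtered error
ε = ln[(H + e/β)/(1 - e/β)] maps the open band onto ℝ; its slope
φ = 1/(Hβ+e) - 1/(e-β) > 0 diverges at the walls. Contact with a wall
is a structured `FunnelViolationError` that aborts the run and carries
the partial trajectory — clipping would silently void the guarantee the
simulation exists to check. Feasibility of e(0) (strictly inside the
t = 0 band) is enforced at configuration time.

## Controller

    u = -k(t) ε - ŴᵀS(Z) - γ/φ,     dŴ/dt = P[S(Z) ε - ξ Ŵ]

with k₁ + k₂ = 4 (split evenly; only the sum is identified), P = 1,
ξ = 0.001, and a 21×21 Gaussian grid on [-2.5, 2.5]², width η = 0.25,
Ŵ(0) = 0.

**Network input.** The node count 441 = 21² fixes a two-dimensional
input. Feeding the raw pair (V_M, V_S) would silence the network — the
trajectory lives near V ≈ 11, where every Gaussian of width 0.25
centred inside [-2.5, 2.5] underflows to zero — so the default input
map affinely rescales the potentials from their operating range [0, 12]
onto the grid span. This keeps the network persistently excited, which
matters: the weight update then acts as distributed integral action
that cancels the slowly varying drift mismatch between the neurons.
The raw-potential map, an (e, ε) map and the full 8-dimensional state
are selectable alternatives (`rbf.input_map`).

**The gain law and its closure.** The time-varying gain
k(t) = k₁ + k₂ - φ̇/(2φ²) is self-referential: φ̇ depends on ė = f + u,
which depends on k(t). Three resolutions are implemented:

- `algebraic`: the two are jointly linear; the unique solution exists
  while det = 1 - (∂φ/∂e)·ε/(2φ²) ≠ 0. Near a wall that determinant
  behaves like 1 - |ε|/2, so the closure is *structurally* singular
  once |ε| > 2 — a region this plant visits (|ε| reaches ≈ 9.8). A
  configurable guard (`det_guard`, default 0.05) falls back to the
  lagged estimate for such steps, and an optional `gain_floor` clamps
  k(t) from below.
- `fd`: φ̇ from a backward difference of φ across the previous accepted
  step. The one-step lag feeds the wall approach with a destabilizing
  correction; in the study configuration the discretized loop crosses
  the wall at t ≈ 0.074 for every step size tried down to 1e-6.
- `zero` (default): drop the correction, k(t) = k₁ + k₂. This is
  itself a standard funnel-control law — with the Lyapunov candidate
  ε²/2 (instead of ε²/2φ) the same boundedness argument goes through
  without needing the φ̇ term — and it is the only variant that
  completes the full study run. The `fd` and `algebraic` modes remain
  available and are cross-checked against each other in the tests
  (they agree to 4e-5 on a pre-wall window).

γ/φ = (β̇/β)e is the envelope-shrinkage compensation; it is bounded by
κβ and enters with the sign the control law prints.

## Baselines

Two literature comparison controllers, with tuning constants the study
defers to its references; the defaults here were chosen for stable
synchronization of this plant:

- **High-gain observer feedback**: u = η̂ + k ẑ₁ with observer states
  ẑ₁ (error estimate) and η̂ (perturbation estimate) driven by the
  innovation z₁ - ẑ₁ through gains L₀ k₁* and L₀² k₂*. Defaults
  L₀ = 20, k₁* = 2, k₂* = 1, k = -4.
- **Modelling-error compensation (MEC)**: u = -e/τ_c + η with a
  first-order estimator η̇ = -(η - η̄)/τ_e. The reference estimate
  η̄ = u_prev - Δe/Δt reconstructs -f from a backward difference (the
  sign that stabilizes: driving η toward -f leaves ė = -e/τ_c).
  Defaults τ_c = 0.5, τ_e = 0.05: sharper estimators track the drift so
  well that the baseline outperforms the funnel controller, which is
  not the regime the comparison is meant to illustrate — the point of
  the baseline is a synchronizer *without* a transient guarantee.

Both integrate inside the same global ODE (controller states appended
to the state vector), evaluated at every solver stage.

## Numerical design

- **Integrator**: classical fixed-step RK4 (explicit Euler available
  for cross-checks). Fixed stepping keeps runs bit-reproducible and the
  funnel check step-exact; adaptive solvers would trade both away.
- **Step size** dt = 5e-6: during the transient the error rides close
  to the funnel wall, where the local stiffness is ≈ (k₁+k₂)·φ with
  φ up to ~5e4; dt = 5e-6 keeps λ·dt ≈ 1 with margin, and halving the
  step (2e-6, 1e-6) reproduces every reported metric to the printed
  digits. dt = 1e-5 is demonstrably unstable there (wall crossing at
  t ≈ 0.63). A short-window dt-halving test asserts the expected
  self-convergence below 1e-6.
- **Horizon** 30 time units: the slowest system mode is the slave's
  h-gate mismatch (relaxation time ≈ 7), and the funnel itself is
  within 1% of β∞ only after t ≈ 7.7; a steady-state window (final
  20%) must sit beyond both. The weight norm plateaus (≈ 30.3) on a
  still longer scale, ≈ 40 units, so the dedicated boundedness test
  integrates 60 units and checks the final-half growth is under 1%.
- **Recording** every 40th step (150 001 rows); metrics are stable to
  2× decimation within 5% (tested).
- The seed in the configuration is recorded in the metadata only — no
  part of the system draws random numbers.

## What the default conditions do and do not show

The bundled configuration *is* the study condition set: every test and
the acceptance script run it unmodified. Passing runs show that the
funnel controller holds e(t) strictly inside (-0.9β, β), with overshoot
0.2514 < 0.27 and steady-state error 0.0142 < 0.02, on this specific
deterministic plant. They do not show robustness to measurement noise,
input saturation, actuator dynamics, stochastic channel gating, spatial
cell geometry, or networks larger than one master-slave pair — none of
which are modelled. The funnel guarantee itself is conditional on the
network's approximation quality over the visited region; when the
error's excursions leave the region where the network is excited, the
error can approach (though, in a completed run, never touch) the wall.

## Known limitations

- The φ̇-corrected gain as printed cannot be closed consistently on
  trajectories that drive |ε| past 2; the default constant-gain law is
  the package's documented resolution, not an approximation error.
- Baseline parameter values are this package's own stable choices;
  quantitative reproduction of the baselines' original tunings is out
  of scope.
- The A/m² → membrane-current bridge (`amplitude_scale`) is an explicit
  modelling choice; no physical unit calibration is claimed.
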