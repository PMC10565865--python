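# Methods

## Model and assumptions

The platform-plus-participant system is treated as a rigid inverted pendulum
with all mass concentrated at height `L` above the pivot, so the moment of
inertia is `I = m1 L²`. This point-mass idealisation is forced by the
governing equation itself: dividing the moment balance through by `m1`
yields the denominator `L² + 4 C1 r² ρ`, which only follows if `I = m1 L²`.
`L` is therefore an *effective* length — fitted values run above the 55%
anatomical centre-of-mass rule because participants lie on a thick foam
cushion with plantar-flexed ankles and elevated arms.

The counterweight cable wraps four pulleys with wrap angle π each. Following
the capstan (Euler–Eytelwein) relation, each wrap multiplies tension by
`exp(mu_F π)`, and the total force at the counterweight pulley is the sum of
the four wrapped tensions, `F_P = F · C1` with
`C1 = Σ_{k=1..4} exp(k mu_F π)`. Two things about this cascade deserve
honesty:

* **Friction direction.** As implemented, friction *amplifies* the
  resisting force transmitted to the pendulum. A capstan normally
  attenuates the tension on the holding side; whether `mu_F` should enter
  with the opposite sign cannot be settled from the system description, and
  the implementation reproduces the published cascade as printed. `mu_F`
  is best read as a phenomenological drag parameter.
* **Balance consequence.** Because `C1` grows fast (C1(0.18) ≈ 19.9), the
  balance threshold `ρ* = L sin θ0 / (C1 r)` is low: at the fitted
  parameters the heaviest published counterweight level (29.1 %BW) exceeds
  it and the model platform does not fall. The synthetic generator flags
  such trials `balanced` instead of dropping them, and the fit uses only
  falling trials.

One tension equation in the source derivation omits a factor of `g` that
reappears in the next expansion step; the `g`-included form
`F = 4 m2 r θ̈ + m2 g` is used throughout, as dimensional consistency
requires.

Cables are inextensible and never slack, pulleys are massless, and nothing
after mat contact (85°) is modelled — the model readout lives at 70°,
empirically the largest angle before any contact.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `L` | effective pendulum length, m | fitted (bounds 0.5–2.0) | ≈ 0.55 × height when predicted from anthropometrics |
| `r` | counterweight pulley radius, m | 0.1875 | half the 14.76-inch axle sprocket; the outer sprocket radius is not documented, so this is configurable |
| `mu_F` | capstan drag coefficient | fitted (bounds 0–1), 0 for no-counterweight designs | dimensionless |
| `m1` | pendulum mass, kg | body mass + 14.4 | 14.4 kg is the platform's effective mass |
| `g` | gravity, m/s² | 9.81 | configurable |
| readout | observable angle | 70° | largest pre-contact angle |

`m1` enters only through `ρ = m2/m1`, so the platform-mass convention trades
off directly against the fitted `mu_F` and `L`; the body+platform convention
is used consistently in fitting and generation.

## Numerics

* **Integration**: `scipy.integrate.solve_ivp` RK45 at rtol 1e-10 /
  atol 1e-12; landmark crossings located by the solver's event root-finding,
  never the nearest sample. Across a 1,024-point grid of
  (L, r, mu_F, ρ, θ0) the event velocity at 70° agrees with the analytic
  energy balance to <1e-6 rad/s (measured: ~1e-9).
* **Closed form**: the constant-coefficient ODE integrates exactly to
  `½(L² + 4C1 r² ρ) θ̇² = gL(cos θ0 − cos θ) − C1 r g ρ (θ − θ0)`. A
  negative radicand signals that the fall never reaches the requested angle.
  Because θ̈ increases with θ, a fall that starts never stalls, so
  feasibility is decided entirely at release (`θ̈(θ0) > 0`).
* **Fitting**: maximising r² is equivalent to minimising SS_res (SS_tot is
  data-constant); SS_res is better conditioned and is what L-BFGS-B
  minimises, from a multi-start grid (L seeds 0.8–1.8 m step 0.2; mu seeds
  0, 0.1, 0.2, 0.4) to insure against local optima. Configurations that
  cannot reach the readout predict 0 rad/s inside the objective — a finite,
  heavily penalised residual rather than a hole in the parameter space.
* **Inverse design**: readout speed is strictly decreasing in m2 up to the
  balance threshold, so `solve_counterweight` brackets a unique root
  (`brentq`, speed tolerance 1e-6 rad/s). Note the feasible speed range has
  a gap: just under the threshold mass the fall still reaches 70° at a
  strictly positive speed, and slower nonzero targets are reported
  infeasible; a target of exactly 0 maps to the threshold mass itself.
* **Signal pipeline**: dual-pass 2nd-order Butterworth at 10 Hz
  (`filtfilt`, zero phase, DC gain 1), central-difference differentiation
  after filtering (the differentiation scheme of the original workflow is
  undocumented; central differences give O(Δt²) accuracy at 150 Hz), linear
  interpolation of ω at the 70° crossing, impact at the first GRF sample
  strictly above 10 N, release at the first sample 0.5° above the initial
  angle (onset detection from kinematics is likewise undocumented).

## Synthetic data: what it does and does not emulate

The generator reproduces the two validation designs — experiment 1: 14 + 13
participants, 8 falls each, two per lean angle (65, 52, 45, 39°, ±3° set-up
jitter, truncated below the 70° readout), no counterweight; experiment 2: 13
participants, 8 falls from 37 ± 1°, two per counterweight level (6.8, 12.4,
17.9, 29.1 %BW with the published jitter). Anthropometrics are normal
distributions truncated to the published ranges. Counterweight percentages
convert to kilograms against the corrected total mass (body + 14.4 kg
platform) by default, matching the corrected-counterweight convention used
when the device's example trials are reported; a body-mass-only basis is a
flag, since the original %BW basis is ambiguous.

Measurement noise is additive Gaussian on the extracted velocity observable
(default sd 0.05 rad/s, redrawn if a draw is non-positive). No noise model
accompanies the real system, so this is a harness knob, not an empirical
claim: real residuals include participant-generated torques (bracing,
grasping, arm thrust), marker noise that is correlated in time, and
per-participant variation in effective `L`, none of which the generator
produces. Passing the recovery tests therefore shows the estimator is
correct and well-conditioned under the model, not that the model captures
everything in real falls — the published fits account for 60–72% of
experimental variance, far from the ≈98% seen on synthetic data.

Raw traces are synthesised at 150 Hz by cubic-Hermite resampling of the
integrated trajectory (the integrator supplies exact angle/velocity pairs):
a 0.5 s hold at the initial lean (the electromagnet phase), the fall, and
rotation continued to 5° below horizontal where the bumpers stop the
platform. Mat and shock-absorber deceleration (85°–95°) are deliberately not
modelled; keeping the sampled trace smooth past 90° also keeps zero-phase
filtering artefact-free at the 70° readout (measured round-trip error
≤ ~3e-4 rad/s against the integrator's event velocity). The GRF trace is a
bare 0 → 50 N step at the horizontal crossing — only the 10 N threshold rule
is exercised, with no impact-force realism.

## Problem sizes

The test suite and `scripts/acceptance.py` run the oracle grid at 1,024
configurations, threshold checks at 200 random configurations, sweeps at
400 points, and recovery at the published experiment sizes (216 and 104
trials); the whole acceptance script completes in a few seconds.

## Known limitations

* Single global `L` per experiment (an `L = k·height` per-participant mode
  exists for prediction, not fitting); no per-participant random effects.
* No uncertainty quantification on (`L`, `mu_F`) beyond residual reporting.
* The friction-direction question above; at face value the cascade implies
  the heaviest published counterweight condition should not fall, which
  contradicts its experimental use and suggests the fitted `mu_F` partly
  absorbs unmodelled effects.
* Experiment-2 identifiability rests on the three non-balanced
  counterweight levels plus set-up jitter; designs with a single lean angle
  and a single counterweight level leave (`L`, `mu_F`) nearly collinear.
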