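# Methods

This note documents the model, the estimation and assessment procedures,
the synthetic-data generator, and the numerical and design choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Model structure and assumptions

The model is a deterministic, non-pulsatile, lumped-parameter description
of minute-scale hemodynamics under fluid perturbation. Eleven states evolve
under two exogenous piecewise-constant inputs, infusion rate U(t) and loss
rate V(t), both in l/min and both required non-negative (hemorrhage and
infusion are separate channels; clipping negative rates is refused rather
than silent). Time is minutes from experiment start; volumes are liters;
HCT is carried in percent, so the red-cell state RBC has units %·l — the
HCT = RBC/BV relation is scale-invariant to this choice, and the reference
baselines (HCT0 13.8–44.4, BV0 in liters) are consistent with it.

Assumptions worth keeping in mind:

* the fluid-shift mechanism is a pure proportional controller toward
  BV0 + r_BV (no integral term);
* heart rate is the algebraic sum H0 + H_V,T + H_V,L − H_U,T of its
  perturbation components. It is computed algebraically rather than
  integrated as a twelfth state, which is the exact integral of the printed
  rate equation and avoids redundant drift;
* the infusion response term integrates G_U,T·U^{P_U,T} without saturation.
  Under sustained infusion this lowers HR without bound — a real
  extrapolation hazard for subjects calibrated with large G_U,T (see
  "Known limitations");
* power terms V^{P_V,L} and U^{P_U,T} are defined as 0 when the rate is 0,
  whatever the exponent (0⁰ := 0 here): both model perturbation responses
  that must vanish at rest;
* stroke volume falls when heart rate rises: the net coefficient of
  G_HR·Ḣ in the SV equation is −1. The printed equations, read literally,
  double-negate this term into +G_HR·Ḣ, contradicting the stated
  inverse-proportionality physiology (shorter diastolic filling at higher
  rates); the physiological sign is the default and
  `SolverConfig(sv_hr_sign=+1)` selects the literal reading;
* the transient infusion response is implemented as the ODE
  Ḣ_U,T = G_U,T·U^{P_U,T}, the dimensionally consistent reading of an
  equation printed with both a time derivative and a stray differential;
* the long-term hemorrhage reference integrand is read as
  G_V,L·V^{P_V,L} (gain outside the power), parallel to the infusion term.

## Parameters

25 per subject, grouped into the four compartments used by the cohort
generator plus five baselines:

| group | parameters | units |
|---|---|---|
| BV (5) | A_U_BV, A_V_BV ≤ 0 (1/min); alpha_U, alpha_V (–); K_P_BV (1/min) | fluid-shift dynamics |
| HR (7) | G_U_T, G_V_T, G_V_L (bpm per unit rate-power); P_U_T, P_V_L (–); K_P_H (1/min); K_I_H (1/min²) | loss/infusion chronotropy |
| SV (5) | G_BV (–); G_HR (l/bpm); A_SV ≤ 0 (1/min); r_SV (l); K_P_SV (1/min) | Frank–Starling + regulation |
| BP (3) | A_BP ≤ 0 (1/min); K_P_BP (resistance-units/mmHg/min); r_BP (mmHg) | vasoactive TPR control |
| baselines (5) | HCT0 (%), BV0 (l), H0 (bpm), SV0 (l), TPR0 (mmHg·min/l) | initial condition |

Several printed unit annotations in the source material are garbled; the
units above are reconstructed from dimensional consistency with the
reference-table magnitudes. The packaged table
(`hemofluid/data/calibrated_sheep_parameters.csv`) is the authoritative fixture: 27
subjects, bit-identical load, spot-checked in the tests.

## Numerical integration

The default solver is adaptive RK45 (`scipy.integrate.solve_ivp`) with
max step 0.5 min, rtol 1e-8, atol 1e-10, restarted exactly at every
protocol breakpoint so piecewise-constant inputs are never smoothed across
a discontinuity. The system is at most mildly stiff (relaxation rates are
≲ 1/min across the reference table, with an effective TPR feedback rate
|A_BP − K_P_BP·CO| ≲ 3/min), so explicit methods suffice.

Calibration and cohort assessment need tens of thousands of forward runs,
so a compiled (numba) fixed-step RK4 engine with dt = 0.1 min (0.05 min for
fixture generation) handles those paths; steps are aligned to both the
output grid and input breakpoints. The test suite checks the adaptive
solver against an independent plain-numpy Euler oracle at dt = 0.001 min
(agreement within 1e-3 relative on all six outputs for all 27 reference
subjects) and the RK4 engine against the adaptive solver.

Failure handling: blood volume reaching zero or a non-finite state flags
the result unsuccessful and NaN-fills the remaining grid; during
optimization such failures map to a large finite objective (1e12) so line
searches can back off.

## Calibration

Measurement model: v(t_k) = v̂(t_k|Θ) + e(t_k) with i.i.d. zero-mean
Gaussian errors, independent σ per variable (the likelihood is written per
variable and summed over HCT, HR, SV, BP; CO is excluded as the product of
two fitted quantities). σ is concentrated out analytically
(σ̂² = mean e², floored at ε = 1e-6 in the variable's units to keep the
log-likelihood finite on noiseless data) — equivalent at the optimum to
joint optimization and far better conditioned.

Objective: −Σ L*_v(Θ, σ̂_v) + 2β‖Θ_scaled‖², with the penalty on free
parameters divided by per-parameter scale constants (the column-wise
maximum magnitudes of the reference table). The parameters span five
orders of magnitude; an unscaled norm would regularize only the largest.
The squared-norm reading of the penalty is the default; a literal-norm
variant is available (`squared_penalty=False`). β defaults to 1e-3 and is
config-exposed; no canonical value exists.

Search: BV0, HCT0, SV0 fixed at measured values; the remaining 22
parameters are optimized by multi-start bounded L-BFGS-B (default 16
starts, maxiter 300) in scale-normalized space. Bounds are the
reference-table ranges widened 3×, sign-constrained (A-terms ≤ 0, gains
≥ 0, powers in [0, 1], distribution ratios ≥ −0.95 so 1/(1+α) stays
bounded). Starting points are drawn uniformly within the *observed* table
range rather than the widened bounds — most of the widened box is
dynamically unstable and yields a flat failure objective with no usable
gradient — and each gradient start is seeded from the best of 32 cheap
random screening evaluations. On noiseless synthetic data the generating
parameters are a fixed point of this procedure (verified in the tests);
on default-noise data the fitted NRMSE reaches the few-percent noise
floor.

## Synthetic-data generator

The generator emulates two study designs so that calibration and
credibility assessment are testable end to end:

* **sheep-like** (180 min): 25 ml/kg hemorrhage over [0, 15) min, 5 ml/kg
  over [50, 55) and [70, 75) min, infusion from minute 30 produced by a
  stand-in discrete PI law (kp = 0.004 l/min/mmHg, ki = 0.0002, 5-min
  updates, clamp [0, 0.3] l/min) steering simulated BP to the subject's
  baseline. The stand-in includes a 5% deadband around the target and a
  120 ml/kg cumulative volume cap (a finite fluid budget), and it skips an
  infusion window if a preview simulation shows the subject does not
  tolerate it (divergence or a non-positive output). It is a documented
  fixture, not a reconstruction of any particular clinical controller.
* **swine-like**: constant-rate hemorrhage (default 1 ml/kg/min — the
  original rate is not recoverable from the source and is config-exposed,
  never asserted) until simulated BP first reaches a stop target (default
  40 mmHg), then 500 ml per 70 kg boluses over 5 min with 60-min washouts.
  An optional pre-hemorrhage infusion event is supported, with no default.

Body weight, when not supplied, is inferred from BV0 by the standard
60 ml/kg blood-volume rule so per-kg doses scale consistently with the
subject's measured volume. Urine is representable as a constant extra loss
rate but is off by default; the fixtures generate hemorrhage only.

Measurements sample the trajectory every 5 min (configurable to 10) and
add zero-mean i.i.d. Gaussian noise with SD equal to a fraction of each
variable's *baseline* value — defaults 2% for HCT and 5% for HR, SV, CO
and BP, chosen to make parameter recovery nontrivial but feasible.
Non-positive noisy samples are redrawn (truncation), since the measured
quantities are physically positive and several subjects' trajectories
approach zero under severe hemorrhage.

What the generator does *not* emulate: circadian or thermoregulatory
drift, anesthesia effects (the swine emulation shares the conscious-sheep
model structure), measurement dropouts or artifacts, autocorrelated or
heteroscedastic noise, and urine output dynamics. Passing tests therefore
demonstrate internal consistency of model, calibration and assessment —
not fidelity to any real animal's physiology.

## Cohort generation

Compartments: BV (5), HR (7), SV (5), BP (3) — 20 sampled parameters.
Counting functions return N⁴ mixing and N³ average constructions (ordered
donor assignment), matching the printed pool totals 474,552 (N = 26) and
551,124 (N = 27); the runtime sampler enforces distinct donors within a
tuple, and the compartment-to-donor assignment of a mixing subject is
randomly permuted under the seed (the source is silent on ordering).
A draw is mixing with probability N/(N+1), the relative pool size.
Baselines are drawn independently as Normal(measured, 10%·measured),
truncated at zero by redraw. For a test subject known only through
measurements, TPR0 is derived as BP0/(H0·SV0) from the first sample (how
TPR0 is "measured" is otherwise unspecified); BV0 must be supplied, as in
the dye-dilution protocols. Averaging is plain arithmetic, not geometric,
despite log-scale parameter spreads — the construction is defined as the
average.

## Credibility assessment

Physiological screening applies to the full simulated trajectory on a
1-min output grid (not only at measurement times), with closed upper
bounds: HCT ∈ (0, 50] %, HR ∈ (0, 300] bpm, SV ∈ (0, 0.100] l (the 0–100 ml
range converted to internal liters), BP ∈ (0, 150] mmHg; CO is
unconstrained. Relevance requires NRMSE ≤ 25% on every one of the five
variables. The envelope is the pointwise min/max over relevant simulations
at measurement times. Coverage averages per-variable inside-fractions with
equal weights. NIS uses α = 0.05 and is averaged over time points per
variable (the per-point score is defined; the aggregation is a choice).
The best virtual subject is the relevant simulation minimizing average
NRMSE across the five variables, ties broken by maximum NRMSE and then by
cohort index; its −LL uses the concentrated per-variable σ̂ over HCT, HR,
SV and BP, mirroring the calibration likelihood.

## Problem sizes in the tests

The test suite runs the leave-one-out credibility pipeline at cohort size
2,000 per test subject and the calibration check with 16 starts on one
subject — sizes chosen so the whole suite completes in a few minutes on a
laptop-class machine while keeping every pipeline stage statistically
meaningful. The oracle-equivalence check integrates all 27 subjects at
dt = 0.001 min.

## Known limitations

* A minority of reference subjects carry extreme calibrated gains (e.g.
  LR17's G_V,T = 158.7 bpm per l/min, LR18's G_U,T = 47.7) that are
  presumably compensated in the data they were fitted to but extrapolate
  badly under the synthetic protocol: their simulated trajectories dive
  toward zero SV, HR or BP. One subject (LR17) cannot produce a valid
  synthetic measurement series at all, and for a handful of others no
  virtual subject from the remaining donors is relevant (NRMSE ≤ 25% on
  all five variables jointly), so the leave-one-out pipeline reports a
  defined envelope for roughly 20 of the 27 subjects at cohort size 2,000;
  enlarging the cohort to 10,000 recovers only a couple more. Median NIS
  (< 1 in every variable) and median coverage (> 90%) over the defined
  envelopes are robust to this.
* The closed-loop infusion stand-in shapes the synthetic inputs; results
  that depend on the infusion profile (e.g. identifiability of the
  infusion-response parameters when a subject's controller output is zero)
  inherit that choice.
* No formal identifiability or sensitivity analysis is included; with 22
  free parameters against ~150 observations the fit is regularized, and
  recovered parameter values — as opposed to fitted trajectories — should
  not be over-interpreted.
* No pulsatile hemodynamics, arterial tree, baroreflex transfer functions,
  or fluid-type pharmacokinetics: fluid composition enters only through
  parameter values.
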