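# Methods

This note documents the models, parameter choices and numerical decisions
behind `litt`, and what the synthetic experiments do and do not demonstrate
about the real procedure.

## Forward model (bioheat digital twin)

The tissue/laser system is reduced to two coefficients: an apparent
absorption α (°C s⁻¹ W⁻¹) — the initial heating rate per watt at the hottest
voxel, with perfusion losses folded in as an amplitude attenuation — and a
thermal diffusivity D (mm² s⁻¹).  The elevation field obeys
∂T/∂t = D∇²T + α·P·s(r) with no explicit perfusion term; an optional scalar
perfusion sink (`PhantomModel.perfusion_rate`, s⁻¹, default 0) exists only to
probe controller robustness to model mismatch.

**Numerics.**  Explicit forward-time central-space with the 7-point
anisotropic Laplacian on the scan grid (1.4×1.4×3 mm).  The integrator
sub-steps each frame at half the von Neumann bound
dt ≤ 1/(2D(1/dx²+1/dy²+1/dz²)); for D ≈ 0.2 mm² s⁻¹ on this grid one
sub-step per 1 s frame suffices.  A step that would need more than 10⁵
sub-steps raises instead of silently spending unbounded time.

**Deposition profile.**  An anisotropic Gaussian aligned with the fiber,
amplitude 1 at the tip so the hottest voxel heats at exactly α·P.  Defaults:
radial σ 2.5 mm, axial σ 12 mm.  The axial extent is deliberately generous
relative to the physical 1 cm diffuser, and the scenario presets pair it
with the `insulated_z` boundary (cold Dirichlet far field in-plane, zero
flux across the slice stack): the 24 mm-deep stack is treated as a window on
an axially extended heated column.  Both choices keep the hotspot dynamics
close to the in-plane point model that the calibration fits assume — with a
short deposit or an absorbing slice boundary, axial heat loss (invisible to
the fit model) biases the recovered α upward by 10–25 % on this grid, and a
radial σ below ≈ 2 voxels adds several percent of discretization bias.
With the defaults, noiseless test shots generated at (α, D) return both
coefficients within ≈ 5 %.

## Synthetic MR dynamics

A single post-coil-combination complex channel per voxel: magnitude from a
uniform elliptic-cylinder template (signal 100 inside, 0 outside, optional
low-signal catheter void), phase = PRF factor × ΔT plus corruption.  The PRF
factor is 2π·γ·B₀·κ·TE = −0.0792 rad/°C at 1.5 T, TE 21 ms,
κ = −0.0094 ppm/°C, γ = 42.577478518 MHz/T.

**Corruption model.**  Independent complex Gaussian noise per voxel/frame
(`complex_noise_sigma`, image units) and a per-slice phase drift
a₀ + a₁x + a₂y + a₃·frame (rad; defaults 0.01, 2·10⁻⁴/mm, −1.5·10⁻⁴/mm,
5·10⁻⁴/frame — ≈ 0.4 °C/min of apparent drift, a realistic scanner figure),
deliberately of the same first-order form the corrector removes, so removal
is exact in the noiseless limit.

**Noise calibration.**  To emulate a stated thermometry precision the
generator solves std(ΔT) = (σ/m)/|PRF factor| for σ.  The 10-frame
reference's noise is a *static* per-voxel offset — it shifts a voxel's
temperature series but does not fluctuate — so it is excluded from this
temporal-STD budget.  Simulated checks recover the requested STD to within
a few percent.

**Not modelled:** k-space/EPI artifacts, coil sensitivities, motion,
temperature-dependent signal loss (a linear magnitude-loss knob exists to
exercise the SNR-exclusion logic, off by default), phase wrapping beyond the
single-difference wrap (at this TE/B₀ a 30 °C elevation stays well inside
±π, so no unwrapping stage exists — elevations beyond ≈ 40 °C would alias).

## Thermometry pipeline

Per frame: reconstruct → drift-correct → Kalman → masks/dose.

* **Reference:** phase of the complex mean of the first 10 dynamics.
* **SNR mask:** voxels whose 20-frame mean magnitude reaches 5 % of the
  volume maximum of that mean.
* **Drift correction:** per slice, least squares of the wrapped phase
  difference on (1, x, y, frame) over a sliding 20-frame window, restricted
  to SNR-valid voxels with reconstructed ΔT inside the (−5, +5) °C gate; the
  fit at the current frame is subtracted before temperature conversion.
  Slices with fewer than 50 eligible voxels keep their previous
  coefficients and warn.
* **Kalman filter:** per voxel, state (T, Ṫ), transition [[1, Δt], [0, 1]],
  process covariance 0.001 °C²·I₂ (a discretized-white-acceleration
  alternative is selectable), measurement variance = sample variance of the
  20 baseline temperature dynamics, floored at 10⁻⁴ °C² so noiseless data
  cannot zero the gain; initial covariance diag(R, R/Δt²).  Non-finite
  measurements trigger predict-only updates and flag the voxel.
* **Dose:** Sapareto–Dean CEM43 with R = 0.5 above 43 °C and 0.25 below,
  lethal threshold 240 min, accumulated from the filtered field plus the
  scenario body temperature.

**Known limitation — halo bias of the drift fit.**  Voxels heated by less
than the +5 °C gate remain in the drift-fit population.  During long or hot
regulations this warm halo covers a substantial area, the fit attributes
part of it to drift, and the correction over-subtracts: a genuinely
non-heated voxel then reads a slowly growing negative bias (up to ≈ −1 °C
late in the 30 °C/700 s scenario at the default 157 mm field of view; worse
on smaller grids, which is why the presets use 112×112 in-plane).  The bias
is inherent to gate-based drift correction, affects the measured field
coherently, and is invisible to the target-tracking metrics (the controller
regulates the measured temperature); it does inflate the whole-record STD
of the non-heated monitor voxel beyond the injected noise level.

## Calibration

`locate_hotspot_roi` centres the 3×3×3 control ROI on the all-time hottest
voxel (ties → lowest linear index; clipped at borders with a warning;
rejected if the peak is below 3× the baseline STD).  The α fit is a
bounded multi-start nonlinear least squares for (α, τ) of the logarithmic
point model with P, t₀, t₁ known (τ starts {1, 5, 20, 60} s; bounds
α ∈ (0, 10], τ ∈ [0.1, 300] s).  The D fit runs per cooling frame an
isotropic 2D Gaussian (free amplitude and centre, zero offset) on the
hottest slice inside a 15-voxel window, then regresses σ² on time,
D = slope/2 — the dimensionally exact reading of the width-growth law; a
σ-versus-time variant (D = slope·σ̄) is provided for comparison with
width plots.  Cooling frames start 5 s after laser-off.  Presets: gel shot
3 W/20 s, in-vivo shot 2 W/30 s, 110 s recorded.

## Controller

The single tuning parameter q = 0.25 s⁻¹ yields critically damped error
dynamics (double root −q/2) and a response time t_r = 2/q = 8 s, several
times the 1 s measurement latency.  Discretization: rectangle-rule integral
(ξ·Δt per frame, advanced only on unclamped frames — anti-windup), analytic
target slope from the active profile segment, 7-point finite-difference
Laplacian at the control voxel (mirror extension across invalid or off-grid
neighbours) smoothed over 5 frames with binomial weights [1,4,6,4,1]
(estimate centred at t−2; weights truncated and renormalized during
warm-up).  Power computed from frame t is applied over [t, t+Δt) — a
one-frame actuation latency — and the laser is armed only while the target
profile is active.  ROI validity is refreshed every frame: a member voxel
must pass the SNR mask and show a trailing-20-frame Kalman-innovation STD
≤ 1 °C (innovations rather than raw temperatures so a genuinely heating
voxel is not discarded); if no voxel survives, power holds at 0 and an
alarm is recorded.

## Sessions, scenarios and metrics

A session runs 10 reference dynamics, 20 noise-estimation dynamics, then
regulation.  Scenario presets encode the three study conditions: gel
(α 0.35, D 0.23, baseline STD 0.27 °C, 5/10/15 °C × 100 s, body 14 °C) and
two in vivo muscle settings (α 0.65, D 0.18; 0.47 °C with 5/10/15 °C ×
300 s, and 0.69 °C with +30 °C × 700 s; body 38.6 °C), all with 15 °C/min
ramps and 1 s updates.  Default grid 112×112×8 at 1.4×1.4×3 mm (≈ 157 mm
field of view, matching the clinical protocol's); the laser tip sits at the
central voxel and the non-heated monitor voxel 50 mm away in-plane.
A simulated elevation above 60 °C aborts with a diagnostic.

Efficiency metrics follow the study's scoring: error = target − maximal
filtered ROI temperature on frames with target > 0, mean and RMSE per
ramp/plateau segment and overall, plus the monitor-voxel temperature STD.
The mean-over-ROI curve is logged but not scored.

`scripts/acceptance.py` re-runs the three closed-loop scenarios (5 seeds
each, ~2600 regulated frames per scenario set) and the two noiseless
test-shot calibrations; problem sizes were chosen so the whole script
completes in a few minutes on one CPU while keeping the grid and frame
counts at the protocol's native scale.

## What passing tests do and do not show

The twin is near model-matched: the controller's (α, D) equal the
simulator's, the deposit is static, coefficients are
temperature-independent, and there is no motion, charring or signal loss.
Tracking RMSEs under these conditions are therefore *lower bounds* on what
the same pipeline achieves in tissue — they demonstrate correctness of the
pipeline and controller arithmetic, noise robustness at the reported
thermometry precision, and stability over 1000+ frame sessions, not
clinical performance.  Calibration-recovery results likewise certify
self-consistency of fit and simulator, not accuracy against real optical
deposition.
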