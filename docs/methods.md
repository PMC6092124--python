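# Methods

`photokin` models, simulates and analyses the density shaping of
*photokinetic* bacteria — cells whose swimming speed is set by the local
light intensity (proteorhodopsin powering the flagellar motor) — and the
closed-loop control of that density with a projected light pattern.  This
note records the models, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## The inverse-speed law

A self-propelled particle with isotropic reorientation and space-dependent
speed `v(r)` occupies space with stationary density `rho(r) ∝ 1/v(r)`: it
spends more time where it moves slowly.  With a *homogeneous growth law*
`v_i(I) = v_i^sat f(I)` — every cell shares the dimensionless response
`f(I)`, cells differ only in their saturation speed — each cell's density is
proportional to `1/f(I(r))` regardless of its own speed, so the population
density is set by the mean local speed alone even for broad speed
distributions.  With only a fraction `alpha` of scatterers responding to
light, the normalized stationary density is

    rho*(r) = alpha * ( w(r)^-1 / mean(w^-1) - 1 ) + 1,

which plots as a straight line against `1/v` with intercept `1 - alpha`:
the non-responsive baseline.

When estimating that intercept from simulated multi-level data *without*
memory, the regression uses all intensity levels: every level lies on the
line, and the slow levels anchor the fit — restricting to the high-speed
levels alone would extrapolate over several times the fitted `1/v` span
and make the intercept leverage-dominated.  The high-speed-only option
(`n_high`) exists for memory-blurred data, where the low-speed branch
bends below the line and must be excluded.

## Light response

* **Speed curve** `v(I) = v_dark + (v_sat - v_dark) I/(I + I_half)` — a
  rectangular hyperbola with dark baseline and saturation.  The functional
  form is the simplest three-parameter curve with the observed saturation;
  it is kept pluggable (`IntensityResponse`).  Defaults: `v_dark = 2`,
  `v_sat = 8` µm/s (a typical swimming speed of ~5 µm/s sits mid-range),
  `I_half = 50` 8-bit projector levels.  A single calibration scalar
  (default 4·10⁻³ mW/mm² per level, i.e. ~1 mW/mm² at full scale) maps
  projector levels to power density; only `I/I_half` enters the model.
* **Speed spread**: `sigma = r·v` with `r = 0.5` by default, i.e. Schultz
  (gamma) distributed saturation speeds with shape `Z = (v/sigma)² - 1 = 3`.
* **Memory**: the response to an intensity step is a jump covering a
  fraction `beta = 0.44` of the change plus an exponential tail with
  `tau_m = 35 s`, shared between rising and falling branches.  The memory
  kernel is the *normalized* exponential `e^(-t'/tau_m)/tau_m`; without the
  1/τ normalization a constant speed history would not reproduce itself.
* **Identifiability**: a single-step trace sampled only after the step
  determines `(1-beta)(V2-V1)` but not `beta` and `V1` separately;
  `fit_step_response` therefore requires pre-step baseline samples or a
  pinned `V1` in single-step mode.  The square-wave protocol (the default
  here, period 200 s) identifies all four parameters.

## Memory blur of the speed map

A swimmer carries its speed history along its path, so the *actual* speed
map is a blurred version of the instantaneous one:

    w = beta*V + (1-beta) * (gamma ⊛ V),      k⁻¹ = v̄ · tau_m,

where the isotropic 3-D kernel is `Γ(r) = k e^(-kr)/(4πr²)` and, for light
patterns that do not vary with depth, its z-projection has the analytic 2-D
Fourier transform `γ̃(q) = (k/q) arctan(q/k)`.  The projected kernel has no
closed real-space form, so the convolution is evaluated exclusively in
Fourier space (FFT, periodic boundary by default; a mirror-padded option
exists for finite fields of view).  `k` is set from the spatial mean of `V`
unless overridden.  The derivation assumes weak speed modulation and
straight trajectories at the mean speed over the memory time; with
`tau_rot` comparable to `tau_m` real trajectories curve, which shortens the
effective blur — the simulator consequently sits between the blurred and
unblurred predictions, much closer to the blurred one (the model-consistency
test checks exactly this ordering, not a perfect match).

## Agent-based simulator

Independent agents in a periodic (default) or reflecting 2-D box:

* Motile agents: commanded speed `v_i^sat f(I(r))`; per-agent memory state
  updated as a first-order relaxation (`dm/dt = (V - m)/tau_m`, actual
  speed `beta V + (1-beta) m`) — mathematically the normalized exponential
  convolution along the trajectory.  Heading diffuses with decorrelation
  time `tau_rot = 20 s` (smooth swimmer); optional Poisson tumbling with
  mean run time `tau_run` for run-and-tumble comparisons.
* Non-responsive agents take Brownian steps with `D = 0.3` µm²/s (the real
  non-motile background is uncharacterized; a small passive diffusivity is
  assumed rather than immobility).
* Integration: Euler–Maruyama.  The configuration validator enforces
  `dt ≤ tau_rot/20`, `dt ≤ tau_m/20`, and that the 99.9th-percentile speed
  crosses less than one light pixel (2 µm) per step; the default
  `dt = 0.07 s` satisfies all three for the default speeds.
* `projection_3d` option: in-plane swimming gives a planar ISF `J0(qvt)`,
  whereas a thick sample of 3-D swimmers imaged in projection gives
  `sinc(qvt)`.  Setting the flag assigns each agent a fixed polar angle
  (cosine uniform on the sphere) and scales its in-plane displacement by
  `sin ψ`, reproducing the 3-D ISF exactly while everything else stays 2-D.
  It is on when generating DDM stacks and off for planar density studies.
* The 2-D effective diffusivity of the simulated smooth swimmer is
  `D_eff = <v²> tau_rot / 2` (verified against the closed-form MSD).  The
  `estimates` module instead keeps the *prefactor-free* convention
  `D = v² τ` so that its printed order-of-magnitude numbers match the
  standard back-of-envelope forms; the two conventions are intentional and
  documented where they appear.

## DDM

The image structure function `g(q,t) = <|M(q,t') - M(q,t'+t)|²>` is
computed with real-input FFTs and conjugate-symmetry weights (exactly
equivalent to full-plane binning), azimuthally averaged in shells one FFT
step wide, q = 0 and Nyquist excluded, no windowing by default.  It is
fitted per q shell with

    g = A(q) [1 - F(q,t)] + B(q),
    F = (1-alpha) e^(-q²Dt) + alpha e^(-q²Dt) E_P[ sinc(q v' t) ],

with `P` the Schultz density.  Note the `[1 - F]` form: `g(q,0) = B` must be
the camera-noise floor.  The Schultz-averaged sinc uses the gamma-integral
closed form

    E = (Z+1)/(Z q v̄ t) · sin(Z arctan Λ) / (1+Λ²)^(Z/2),  Λ = q v̄ t/(Z+1),

validated against adaptive quadrature to <10⁻⁶ (a second-order series is
used below `x = 10⁻⁴`, and `(1+Λ²)^(Z/2)` is evaluated via `log1p` so the
monodisperse limit is stable).  Fitting uses a bounded trust-region
least-squares per shell in the band `0.45 ≤ q ≤ 1.2` µm⁻¹ (defaults),
initialized from the curve's floor and plateau; failed shells are dropped
with a warning and the band mean is reported.  On rendered stacks
(≥800 frames, 10⁴ agents) the recovery is ~5% in `v`, ~15% in `sigma`,
0.05 absolute in `alpha`.

## Imaging chain

Dark-field rendering deposits each agent with bilinear (cloud-in-cell)
interpolation — nearest-pixel deposition aliases sub-pixel displacements
and visibly biases DDM — then applies a Gaussian PSF (σ = 1 µm), a stray
background, an optional smooth illumination envelope, and Gaussian and/or
Poisson noise.  Bright-field frames are negative-contrast spots on a gray
background.  Analysis follows the standard densitometry chain: flat-field
`rho0` (frame average, wide Gaussian blur, default σ = 100 µm, `nearest`
boundary mode — mean preservation is exact only away from the borders),
`rho* = rho/rho0`, optional 5th-percentile background subtraction (linear
interpolation percentiles, clipped at zero because dark-field intensities
are non-negative), affine rescaling matching the 10th/90th percentiles of
the target histogram, and `dist` = root of the summed squared pixel
differences (normalized variants divide by the initial value).

## Feedback loop

Proportional control, one iteration per 20 s:
`I_{n+1} = clip(I_n + P (rho_s - rho_tar), 0..255)`, quantized to integer
projector levels by default.  The measured map is the position histogram
time-averaged over the iteration (1 s sampling), lightly smoothed (σ = 1
pattern pixel) and percentile-rescaled against the target every iteration.
The default gain `P = 50` intensity levels per unit density keeps the
largest per-iteration change under ~10% of the dynamic range at typical
initial errors.  The open-loop reference is the *naive* pattern: invert
`rho ∝ 1/v` through the response curve with no blur compensation.  Because
the plant includes the memory blur, the converged pattern is a sharpened
version of the naive one (checked as a higher high-spatial-frequency
fraction), and the converged distance falls below the open-loop plateau.
Divergence (distance growing for five consecutive iterations) is flagged
with gain-reduction advice rather than raised.

## Closed-form estimates

The `estimates` module contrasts active patterning with optical forcing of
Brownian colloids at 298 K (`kBT = 4.11·10⁻³ pN µm`): Boltzmann log-contrast
`-ΔU/kBT`, Rayleigh energy `ΔU ≈ a³I/c`, required power `kBT c/a³ ≈ 1.2
W/mm²` for `a = 1 µm`; transport times `τ_drift = l/v` and
`τ_diff = l²/2D` with the prefactor-free active `D = v²τ`; Einstein
diffusivity `D = µ kBT`.  A "Brownian drift time" is sometimes quoted as
`µ kBT / l`, which is dimensionally a velocity; this package implements
`l²/(µ kBT)` and reports only that form.  A nearest-power-of-ten reporting
mode (`10^round(log10 x)`) accompanies every estimate.

## Problem sizes

Simulation protocols are sized for single-CPU runs: the acceptance script
uses 2·10⁴ agents and 15 min of simulated time per density experiment; the
test suite uses 10⁴–1.5·10⁴ agents with 10–12 min simulated, 800-frame
256² DDM stacks, and a 64² feedback grid (4 µm control pixels, 8·10³
agents, 36 + 18 iterations).  All randomness flows from one seed per
protocol through `numpy.random.SeedSequence`.

## What the generators do not emulate

Steric and hydrodynamic interactions, cell growth and death, z-resolved
dynamics, the slow loss of swimmers from the illuminated field of view, and
any optics beyond a Gaussian PSF with a smooth envelope.  Passing tests
therefore demonstrate the internal consistency of model, simulator and
analysis under these assumptions — not that real suspensions are free of
interaction or boundary effects.
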