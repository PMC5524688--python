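# Methods

## The physical model

A photoacid ROH becomes strongly acidic upon photoexcitation. The excited
photoprotolytic cycle is

    ROH*  --k_PT-->  [RO-* ... H+]  --diffusion-->  RO-* + H+
          <--k_a---

The excited protonated form dissociates with rate `k_PT` (1/ns); the geminate
proton can recombine at the contact sphere of radius `a` with intrinsic
recombination velocity `k_a` (Å/ns), or escape by diffusion.  The pair
density p(r, t), normalized per generalized volume, obeys the
Debye–Smoluchowski equation in an effective dimensionality `d`:

    dp/dt = r^(1-d) d/dr [ r^(d-1) D ( dp/dr + p dV/dr ) ],   V(r) = -R_D/r

with V in units of k_B T.  R_D = |Z1 Z2| e² / (4π ε0 ε_r k_B T) is the Debye
radius: the separation at which the Coulomb attraction between the RO⁻*
anion (charge Z1) and the proton (Z2 = 1) equals the thermal energy.  For
water at 20 °C (ε_r = 80.1, T = 293.15 K) and Z1 = 1, 2, 3 this gives
7.12, 14.23, 21.35 Å.

The bound state couples to the density through the back-reaction
(reversible radiation) boundary condition at r = a:

    dP/dt = -k_PT P + k_a A_d(a) p(a, t)

with the same flux entering the diffusion domain, so total probability
P + ∫ p dV_d is conserved identically.  At long times the bound population
relaxes as P(t) ∝ t^(-d/2): the exponent is a direct readout of the
dimensionality of the proton's diffusion space (3 in bulk water, ~2 on a
surface, ~1 along a channel), which is what makes the model informative
about how a probe sits on an amyloid fibril surface.

### Conventions for fractional d

The fractional dimensionality enters only through the metric factor
r^(d-1) in the operator, the generalized surface A_d(r) = σ_d r^(d-1) with
σ_d = 2π^(d/2)/Γ(d/2), and the volume element dV_d = A_d(r) dr.  The
recombination flux is k_a·A_d(a)·p(a,t).  With `k_a` defined as an
intrinsic velocity this is dimensionally consistent for any real d and
makes conservation exact; other solvers may fold σ_d a^(d-1) into the rate
constant, so fitted `k_a` values are comparable across conventions only up
to that constant factor.  All parameter-recovery statements in this
package are round trips within this declared convention.

The closed-form long-time intensity implemented in `asymptotic_roh`,

    I(t) = π a² k_a exp(-R_D/a) / (2 k_PT (π D t)^(d/2)),

is the standard reporting form of the tail law.  Note that its prefactor
carries exp(-R_D/a) with R_D defined non-negative, whereas the solver's
attractive potential produces a tail coefficient proportional to
(k_a A_d(a)/k_PT)·exp(+R_D/a)·(4πDt)^(-d/2) (the Boltzmann factor at
contact; the sign convention for R_D differs between the attractive and
repulsive literature).  The two agree in shape exactly — same power law —
so the solver-versus-asymptotics test fits a single multiplicative
constant and compares shapes.  The solver's absolute tail amplitude was
verified separately against the quasi-equilibrium coefficient above
(within ~1.5% for the parameter sets used here).

## Numerical scheme

* **Spatial discretisation.** Conservative finite volumes on a geometric
  radial mesh from r = a to r_max; the first cell width is a/n_r
  (0.008 Å at the default n_r = 500), clustering resolution at the contact
  boundary layer.  Interface fluxes use Scharfetter–Gummel exponential
  fitting, whose discrete equilibrium is exactly the Boltzmann profile
  e^{-V(r)}; this keeps the scheme accurate and stable for strong Coulomb
  attraction (R_D/a up to ~5.5 here).
* **Bound-state coupling.** The bound population is the first unknown of
  the linear system; it couples only to the contact cell, so the full
  operator stays tridiagonal and each step is a Thomas solve (compiled
  with numba).
* **Time stepping.** TR-BDF2 (L-stable, second order).  Plain
  Crank–Nicolson leaves the stiff contact-cell mode oscillating at large
  steps, which pollutes the contact density in the deep tail; TR-BDF2
  damps it while preserving the conservation identity exactly in both
  stages (mass-balance defect is ~1e-13 in practice, monitored every
  step against a 1e-4 tolerance).  Steps ramp geometrically from
  dt = 1e-4 ns with ~1.5% growth per step, so the local step is ~1.5% of
  elapsed time: accuracy is then scale-invariant across the stiff early
  dissociation and the slow power-law tail.  Halving `GridSpec.dt`
  halves the step everywhere (the growth rate scales with dt), which is
  what the grid-convergence test exercises.
* **Domain.** Reflecting outer boundary at
  r_max = max(20 R_D, 10 √(2 D t_max), 200 Å).  A run is rejected if more
  than 1e-6 of the surviving density sits within 5 cells of r_max.
* **Output.** The bound population is recorded at every internal step and
  interpolated onto the requested output times; interpolation error is
  O((dt/t)²) ≈ 1e-4 relative.

Halving dt and doubling n_r moves P(t) by at most ~0.3% across all eight
published parameter sets (tested bound: 0.5%).

## Validation oracles

* **Closed form.** With R_D = 0, d = 3, no re-dissociation and a strong
  sink (k_a = 1e5 Å/ns, i.e. κa/D ≈ 440 so the radiation boundary is
  within ~0.2% of perfectly absorbing), the separated fraction matches
  the Smoluchowski survival 1 − (a/r0)·erfc[(r0−a)/√(4Dt)] within 1%.
* **Brownian dynamics.** An independent stochastic estimator: radial
  Euler–Maruyama walkers with drift D[(d−1)/r − R_D/r²], exactly sampled
  exponential bound dwells, specular reflection at contact and
  Erban–Chapman reaction probability k_a√(πΔt/D) per attempted crossing.
  With 1e5 walkers the solver lies within 3 binomial standard errors at
  every output time.

## Fitting protocol

The forward model for a TCSPC decay is
amplitude × IRF ⊗ [P(t; θ)·e^{−t/τ_ROH}] + background.  Radiative
lifetimes are not part of the diffusion model; they are treated as known
constants (τ_ROH = 8 ns, τ_RO = 10 ns, naphthol-family magnitudes) in both
generation and fitting, never fitted.

* **Weights.** Neyman weights 1/max(counts, 1); channels before the IRF
  rise (cumulative IRF < 1e-3) are excluded.  The reduced χ² statistic
  optionally excludes channels below a count threshold; Neyman χ² is
  biased for sparse channels (≈1.3 at 10 expected counts), so calibration
  checks use a threshold of 100 counts where the bias is ≲2%.
* **Free/fixed schemes.** Free photoacids in buffer: free {k_PT, k_a,
  amplitude}; fixed d = 3, D = 9e-5 cm²/s, a = 4 Å, and R_D computed from
  the charges.  Fibril-bound: free {k_PT, k_a, d, D, R_D, amplitude};
  a = 4 Å fixed (the contact radius calibrated once on the free species).
* **Optimiser.** Trust-region-reflective least squares (lmfit), with D
  and the amplitude fitted in log space, tight tolerances (1e-12) and
  Jacobian-based variable scaling.  Five seeded multi-starts jittered
  ±30% around the initial guesses; best χ² wins, with ties within 1%
  broken toward the lower k_PT (the conservative choice when the pulse
  width makes fast rates unidentifiable).  Initial guesses are
  data-driven: k_PT from the lifetime-corrected post-peak 1/e time, d
  from the lifetime-corrected log-log tail slope.
* **Smoothness.** The radial domain of the fit forward model is sized
  once per fit from the parameter upper bounds (not per iterate), so
  finite-difference Jacobians see a smooth objective.  A larger domain is
  strictly more accurate, so this does not bias the fit.
* **Standard errors** come from the local quadratic approximation at the
  optimum (delta method for log-space parameters) and are approximate.
* **Multi-exponential reconvolution.** IRF ⊗ Σ aᵢ e^{−t/τᵢ} + baseline
  with non-negative amplitudes and log-space lifetimes; the fastest
  component with ≥2% of the total amplitude estimates τ_PT = 1/k_PT.
  With a ~1 ns FWHM pulse this recovers rates of ~4/ns (τ ≈ 0.26 ns)
  within a few percent at 1e4 peak counts, whereas a diffusion fit
  anchored on the tail alone leaves k_PT unidentified and the tie-break
  reports a lower value — reproducing the known slow-light-source
  artefact qualitatively.

## Synthetic data

The generators emulate the measurement conditions: a Gaussian IRF of
1 ns FWHM (LED excitation) centred at 2 ns on a 0.055 ns channel grid
over 0–200 ns (~3640 channels); Poisson counting noise at a target peak
of >10,000 counts; a flat background of ~1 count/channel.  The window
and channel width are chosen so the t^(-d/2) tail is observable above
background at 1e4 peak counts.  Noiseless round-trip data for
parameter-recovery checks are generated at 1e9 peak with zero background:
"noiseless" then also means free of the integer-rounding floor that
would otherwise truncate the tail (counts remain integers).

Steady-state spectra are two unit-area Gaussian bands (ROH* at the
collection wavelength of each photoacid, 350–370 nm; RO⁻* at 420 nm;
σ = 20 nm) with band-area ratio equal to the RO⁻*/ROH* ratio; the
published ratios are stored in the registry.  The ratio estimator is
non-negative least-squares unmixing on the same two bands, reported as an
area ratio by default (peak-height mode available); whether the published
ratios are area or height ratios is not specified, so the convention is
declared here.  Amyloidogenesis traces are four-parameter logistics from
the free-probe ratio to the bound ratio with the inflection two rate
constants after the lag time, over 0–180 min at 20 min steps.

What the generators do **not** emulate: detector afterpulsing and pile-up,
wavelength-dependent IRFs, solvatochromic band-shape changes beyond a
constant bathochromic shift, ground-state acid-base equilibria, or any
mechanistic oligomer-intermediate model of the lag phase.  Passing the
suite therefore demonstrates internal consistency of solver + estimators
under realistic counting statistics, not agreement with any particular
measured dataset (none is distributed).

## Problem sizes

Default analyses use n_r = 500 radial cells (~700 time steps per solve,
a few ms compiled), 3640-channel histograms, 5 multi-starts per fit
(seconds per buffer fit, tens of seconds for the 6-parameter fibril
scheme), 1e5 walkers for the stochastic oracle, and 400 ns horizons for
tail-law checks.  These sizes were chosen so every validation statement
above is comfortably inside its tolerance while the whole suite runs on
a laptop-class single core.

## Known limitations

* The k_a normalization at fractional d is a declared convention (see
  above); absolute k_a values are not transferable across solvers.
* Exactly at d = 2 the generalized surface is the standard 2πr; no
  logarithmic corrections are applied to the asymptotic law (none are
  expected for the reversible tail).
* The tail law needs the asymptotic regime: windows straddling the
  exponential-to-power-law crossover (t ≈ (1/k_PT)·ln of the
  amplitude ratio) give intermediate slopes by construction.
* Fits assume a single emitting ROH* species with a known lifetime;
  lifetime heterogeneity would bias k_PT.
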