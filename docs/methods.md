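# Methods

## The model

`nanotoxkin` implements a two-reaction kinetic description of how silver
nanoparticles (AgNP) damage the plasma membrane of macrophage-like cells in
suspension.

**Reaction 1 — diffusive encounter.** Nanoparticles (species B, radius
r_B ≈ 35 nm) diffuse toward a much larger cell (species A, radius
r_A ≈ 5 µm). Contact at the reaction radius R = r_A + r_B is treated as
irreversible adsorption (the "black sphere" absorbing boundary). Around a
single cell the nanoparticle concentration field solves the radial
diffusion equation with W(R, t) = 0 and W(∞, t) = W₀, giving the closed
form

    W(r, t) = W₀ [1 − (R/r) · erfc((r − R) / (2√(Dt)))],

and the encounter rate constant

    k₁(t) = 4πRD (1 + R/√(πDt)),   k₁(∞) = 4πRD,

with the mutual diffusion coefficient from Stokes–Einstein,
D = (k_B T / 6πη)(1/r_A + 1/r_B). For the assay geometry the transient
term contributes ≈ 14 % after one minute and < 2 % beyond an hour, so all
downstream kinetics use the stationary constant by default; a
`transient_k1` flag substitutes the time-dependent form (the separable
death ODE then uses ∫k₁ dt, which is finite despite the t → 0 divergence
of k₁ itself).

**Reaction 2 — the ROS / antioxidant-defence outcome.** An adsorbed
particle generates reactive oxygen species; the cell's antioxidant defence
(AOD) opposes them. This contest is lumped into a single probability
P2(T) ∈ (0, 1] that an encounter kills the cell at temperature T. An
Arrhenius argument links the effective death rate constant k₂ to k₁: the
encounter barrier is taken to be the particle's mean kinetic energy,
E_act1 = (3/2) k_B T, the death barrier is E_act2 = E_act1 / P2, and

    k₂ = k₁ exp((E_act1 − E_act2)/(k_B T)) = k₁ exp(3(P2 − 1)/(2 P2)).

This is the package's default sign convention, `corrected`: k₂ ≤ k₁, with
equality when the defence never saves the cell (P2 = 1), and k₂ strictly
increasing in P2 (weaker defence → faster death). The mirrored exponent
(3 − 3P2)/(2P2) is retained as convention `printed` for audit purposes;
under it k₂ ≥ k₁, and with the default assay parameters
(C_B0 k₁ ≈ 16 s⁻¹) damage would saturate within seconds, which is
irreconcilable with hour-scale damage curves — the package documents and
tests this as the discriminating behaviour. The two conventions obey the
exact duality k₂⁽ᵖ⁾ k₂⁽ᶜ⁾ = k₁².

**Dead-cell balance.** With C_A0 cells/m³ and C_B0 particles/m³ initially,
the dead-cell count N(t) obeys

    dN/dt = k₂ (C_A0 − N)(C_B0 − (C_B0/C_A0) N),   N(0) = 0,

whose closed-form solution is the hyperbola

    N(t) = C_A0 · C_B0 k₂ t / (C_B0 k₂ t + 1).

The measured quantity is the damaged fraction N(t)/C_A0 =
x/(x+1), x = C_B0 k₂ t, which is independent of the cell density.

### Assumptions

- Both species are spheres; the medium is water (empirical viscosity law
  η = A·10^{B/(T−C)} with A = 2.414×10⁻⁵ Pa·s, B = 247.8 K, C = 140 K,
  valid ≈ 273–320 K; outside the window the value is extrapolated with a
  warning).
- Cells do not compete for particles; adsorbed particles do not change the
  cell's effective radius or mobility.
- Every encounter is adsorbing (no partially reflecting boundary).
- P2 is constant over the course of one (temperature, dose) series; the
  late-time "oxidative stress" breakdown seen in long 22 °C incubations is
  deliberately *not* part of the fitted model (see the generator below).

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| particle radius | 35×10⁻⁹ | m | AgNP mean radius |
| particle bulk density | 350 | kg/m³ | effective density of the colloidal preparation, used for the µg/mL → particles/m³ conversion; far below solid silver (~10 490 kg/m³), configurable, never hard-coded |
| cell radius | 5×10⁻⁶ | m | macrophage radius |
| cell concentration | 5×10⁵ | cells/mL | assay seeding density |
| P2 floor | 10⁻³ | — | lower admissible bound; keeps exp(g(P2)) finite |
| temperatures | 4–37 | °C | assay range; CLI accepts °C, everything internal is kelvin |

All internal computation is SI (m, s, kg, K, J, particles/m³); µg/mL,
cells/mL, °C and minutes are converted at interfaces. With the defaults,
2.5 µg/mL ↦ 3.98×10¹⁶ particles/m³ and k₁(22 °C) ≈ 4.12×10⁻¹⁶ m³/s.

## Inference

P2 is the single free parameter per (temperature, dose) series.
`MembraneDamageModel.fit()` minimises the unweighted sum of squared
residuals on the fraction scale (0–1, not percent — scale-free and the
hyperbola's natural output), over log P2 in [10⁻³, 1]: a 256-point
log-spaced scan brackets the minimum, then bounded scalar minimisation
(Brent, xatol 10⁻¹²) refines it. The procedure is deterministic —
identical inputs give bitwise-identical estimates — and is checked in the
tests against a 10⁴-point grid-search oracle. Inverse-variance weighting
by binomial counting error is available as an option.

Goodness of fit is R² = 1 − SS_res/SS_tot. The fitted P2 maps to the
death activation energy E_act2 = (3/2) k_B T / P2;
`activation_energy_profile` tabulates it across temperatures and flags the
extremes. A closed-form single-observation inversion (`p2_from_fraction`)
supports scan-style data with one time point per temperature.

**Uncertainty.** The standard error of P2 comes from the delta method with
the analytic Jacobian df/dP2 = t C_B0 k₂ g′(P2)/(x+1)². When per-point
cell counts are available the known binomial variances f(1−f)/n enter a
heteroscedasticity-consistent sandwich and intervals use a normal
quantile; without counts the residual variance (n−1 df) is used with a
Student-t quantile. Simulation shows ≈ 93 % true coverage of the nominal
95 % interval at 8 points × 1500 cells.

**Degenerate inputs.** Fitting needs ≥ 2 points and a positive particle
density; an all-zero series is flagged `at_bound` with P2 reported at the
floor and a warning (P2 is not identified there). Estimates landing on
either boundary are flagged rather than silently clipped. A `time_window`
argument restricts the fit, e.g. to t ≤ 150 min when the late-time excess
regime contaminates the tail.

## Synthetic-data generator

`simulate_assay` emulates the dual-fluorochrome membrane-integrity assay:
at each (temperature, dose, time) design point, cells in 50 microscope
fields (Poisson-distributed around 30 cells/field, ≥ 1500 cells per point,
optionally fixed counts) are each called damaged or intact by a Bernoulli
draw with probability

    f* = b + (1 − b) · f_model,

where b (default 0.02) is a baseline damage fraction mixed in as an
independent competing risk — untreated preparations are not perfectly
intact, and no quantitative control level is available, so 2 % is a
generator choice. An optional breakdown regime multiplies the cumulative
hazard −ln(1 − f_model) by a factor ≥ 1 for t beyond a breakdown time,
reproducing the observed late-time (≳150 min, 22 °C) excess attributed to
oxidative stress. The breakdown is a data-generating extension only; the
fitted model never includes it, which is exactly what makes the
truncation diagnostic (R² on t ≤ 150 min exceeding full-range R²)
meaningful.

One seeded NumPy generator drives each dataset; the seed and all
generating parameters (including the true P2 per temperature) are stored
in the dataset provenance and survive the CSV round trip as `#`-prefixed
header lines.

**What the generator does not emulate:** fluorescence intensities and dye
kinetics, observer miscounting, cell heterogeneity in susceptibility (the
S-shaped dose response of real populations), dose-dependent particle
aggregation, or sedimentation-augmented delivery. Passing recovery tests
therefore shows the inference is correct *given the model*, not that the
model captures every feature of real assays.

## Numerical choices

- **Closed-form field:** erfc arguments above 26 underflow double
  precision; the depletion term is clamped to zero there (W = W₀ exactly).
- **PDE oracle:** the substitution ω = rW reduces the spherical operator
  to a 1-D second derivative. Log-spaced grid of 600 nodes from R to 50 R
  (spacing ≈ 0.01 R at the boundary resolves the depletion layer);
  Crank–Nicolson stepping with 8 backward-Euler startup steps (Rannacher
  smoothing of the initial corner discontinuity at r = R) and a geometric
  ramp of the step size from 10⁻³ of the target step; boundary flux by
  one-sided three-point differencing of ω. Agreement with the closed form
  is ~2×10⁻⁶ (profile, sup norm over W₀) and ~10⁻⁵ (flux) — two orders
  tighter than the 1 %/2 % the validation tests require. The solver
  raises if the profile leaves [0, W₀] or loses monotonicity in r.
- **ODE oracle:** DOP853 at rtol 10⁻¹³ with a 600 s step cap (the cap
  keeps dense-output interpolation error below the 10⁻⁸ comparison band).
- **Optimiser:** log-scale parametrisation enforces P2 > 0; scan + bounded
  refinement avoids bracketing failures; no randomness anywhere in the
  fit.

## Problem sizes

The test suite and the acceptance script use the assay-scale design
throughout: 8–9 time points over 5–210 min, 50 fields × 30 cells per
point, 200 replicates for the coverage simulation, a 3×3 six-decade
(k₂, C_B0) grid for the ODE oracle, and one PDE solve to 10 R²/D. The
full suite runs in a few seconds on one CPU.

## Known limitations

- The effective bulk density 350 kg/m³ is taken as given for the
  mass-to-number conversion; if the true value were closer to solid
  silver, C_B0 — and hence every fitted k₂ and P2 — would shift by the
  density ratio.
- P2 is a lumped probability; the package deliberately contains no
  mechanistic ROS/lipid-peroxidation submodel, no binding-site
  saturation, and no model of the post-breakdown regime.
- Per-temperature fits are independent; there is no joint smooth P2(T)
  model and no bootstrap interval (the Wald/sandwich interval is
  asymptotic).
- Reference pattern series bundled with the package are approximate
  round-number anchors for qualitative checks, not measurements.
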