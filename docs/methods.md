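# Methods

## Problem and modelling strategy

The package compares staged surgical-correction schemes for a trachea with
two stenotic segments by simulating steady inspiratory airflow through the
four possible correction states (M1–M4).  The patient geometry is not
available, so the airway is reduced to an **axisymmetric body of
revolution**: a lumen radius R(s) along the airway axis.  Every read-out
the comparison is judged on — the stenosis-ratio definition, pressure drops
across constrictions, wall shear stress, energy fluxes through cross
sections — is expressible on cross sections and walls of such a body, which
is what makes the reduction serviceable.  What the reduction gives up is
listed under Limitations.

## Governing equations

Steady incompressible RANS with constant properties
(ρ = 1.161 kg/m³, μ = 1.864 × 10⁻⁵ kg/(m·s); humidified inspired air,
body forces omitted), closed with the Wilcox k–ω model:

* eddy viscosity μ_T = ρk/ω,
* k-transport with production τ_ij ∂u_i/∂x_j, destruction β*ρkω and
  effective diffusivity μ + σ*μ_T,
* ω-transport with production α(ω/k)·P_k, destruction βρω² and diffusivity
  μ + σμ_T,
* closure constants α = 5/9, β = 3/40, β* = 9/100, σ = σ* = 1/2 (exact
  rationals, immutable),
* Boussinesq Reynolds stress τ_ij = 2μ_T S_ij − ⅔ρk δ_ij.

The −⅔ρ∇k contribution enters the momentum equations as an explicit
source.  The transpose-gradient part of the viscous stress divergence,
∇·(μ_eff(∇U)ᵀ), is **omitted**: it vanishes identically for
constant-viscosity divergence-free fields, is a small correction under the
eddy-viscosity closure, and an explicit treatment proved destabilizing on
high-aspect wall cells.  The production term uses the axisymmetric strain
invariant (including the hoop component S_θθ = v/r) and is capped at
20 β*ρkω — a standard limiter that only engages in strongly strained
transients.

## Discretization and solution algorithm

Finite volumes on a structured body-fitted grid in the (x, r) half-plane;
all face areas and cell volumes carry the full 2π revolution (Pappus), so
the axisymmetric metric terms are geometric rather than source-term
bookkeeping.  The two that remain explicit are the −2μ_eff v/r² sink and
the p/r correction in the radial pressure force.

* **Collocated arrangement** with Rhie–Chow momentum-weighted face fluxes
  (the commercial-solver practice the pipeline mirrors does not specify an
  arrangement; collocated is the simplest that suppresses checkerboarding).
* **Convection**: implicit first-order upwind plus a deferred second-order
  upwind correction reconstructed from Green–Gauss gradients.  The
  reconstructed face value is clipped to the interval spanned by the two
  adjacent cell values; without this bound the deferred correction
  destabilizes thin tilted wall cells in the stenosis region.
* **Diffusion**: central, with over-relaxed non-orthogonal decomposition;
  the cross-diffusion remainder is explicit.  Face diffusivities use
  harmonic interpolation.
* **SIMPLE**: momentum under-relaxation 0.7, pressure correction 0.3,
  turbulence 0.8.  Both momentum systems and the pressure-correction system
  are solved with a direct sparse factorization each outer iteration, so
  after the face-flux correction the per-cell continuity residual is at the
  linear-solver round-off level (this is what makes the 10⁻⁸-of-inlet-flux
  conservation check trivially tight at every iteration, not only at
  convergence).
* **Convergence**: the run stops when the relative inter-iteration change
  of every field (u, v, p, k, ω) stays below 10⁻⁵ for three consecutive
  iterations, after at least 40 iterations.  Which variables enter such a
  criterion and in which norm is an open choice; this package uses the
  max-norm over all fields and records the full history.  Non-convergence
  raises a diagnostic error carrying the history; the pipeline records the
  failure and continues with the remaining cases.
* **Positivity**: k is clipped at 0 and ω floored at 10⁻⁴ s⁻¹ when the
  linearized transport steps undershoot; every clip is counted on the
  returned state.

### Boundary conditions

Uniform (plug) axial inflow scaled to the exact discrete mass flow;
turbulence intensity 5% and length scale 10% of the inlet diameter (the
inflow then develops along the 20 D inlet extension, so the interior
solution is insensitive to these; both are configurable).  Outlets: fixed
zero gauge pressure, zero-gradient outflow for the transported fields.
Walls: no-slip, k = 0, and ω in the wall-adjacent cell fixed to the
smooth-wall asymptote 6μ/(ρβy₁²) — the low-Reynolds wall-resolving
treatment consistent with the boundary-layer meshing strategy.  The axis is
a zero-area face set in the revolved metric, so it needs no explicit
condition.  A validation-only "parabolic" inlet profile exists for
developed-flow oracles.

## Meshing

Structured quadrilateral (axisymmetric) grids replace the tetra-plus-prism
meshes a 3-D workflow would use; the mechanism that matters — a wall stack
of thin layers with first-layer height h and geometric growth ratio g,
defaulting to the three-layer / ratio-1.2 scheme — is retained, because WSS
accuracy is set by wall-normal resolution.  Defaults: 160 × 28 cells,
h = 10⁻⁵ m (the 2.2 µm first-layer preset from wall-unit practice at much
higher element counts is available but unnecessary at this problem's
Reynolds numbers; at the stenotic throat the default gives y⁺ ≈ 1–2).
Cell counts of 20–50 k replace the ~0.5 M of unstructured 3-D practice
since the axisymmetric reduction resolves the same wall physics with one
azimuthal "cell".  The axial budget puts ~55% of cells uniformly in the
anatomy and grades the extensions geometrically.  A refinement study
(`refine`: counts × f, first layer / f) backs the grid-sensitivity driver;
mesh volume converges to the exact solid of revolution at second order.

## Measurement conventions

* **Pressure drop**: static pressure (the governing definition), area-
  averaged per cross-section, stations one local diameter up- and
  downstream of each stenotic extent (clamped to the anatomy); station
  placement is not fixed by the clinical description, so it is a package
  convention.  A total-pressure variant is computed alongside.  Station
  pressures linearly extrapolate past the first/last cell centroid so
  end-of-domain stations do not lose the half-cell gradient.
* **WSS**: μ·u_t/y₁ from the first-cell tangential velocity — the quantity
  the wall stack exists to resolve; maxima are reported point-wise per
  stenotic wall patch (whether a patch maximum should be point-wise or
  averaged is unspecified; point-wise is the conservative choice).
* **Energy flux**: computed with the stored face mass fluxes, so the same
  discrete fluxes that satisfy continuity carry the energy bookkeeping;
  λ = 1 − E_out/E_in holds exactly by construction.  Energy stations sit at
  the anatomical boundaries: the extensions are numerical scaffolding and
  their friction is not charged to the trachea.
* **Throat Reynolds number**: ρUD/μ with U = Q/A_min and D the throat
  diameter.

## Synthetic study conditions

The scenarios module fixes the study conditions.  Reference-case values:
severities 68.7% (S1) and 86.5% (S2), Q = 3 L/min constant, the fluid
properties above, 20 D/40 D extensions.  Values the case description does
not provide are package defaults flagged `synthetic-default` in every
emitted config: healthy caliber D = 6 mm (typical 5-month infant), S1
centred at L/3, S2 at 0.73 L, each extent 20% of the L = 45 mm trachea (the
stenotic region jointly covering 40% > 30% of the length).  The generator
is deterministic; the seed exists for future randomized sweeps and is
recorded in the config.

What the stand-in does **not** emulate: the C-shaped bowing of the real
trachea, the non-circular stenotic cross sections, the 3-D carina and
bronchial branching, wall compliance, and unsteady ventilation waveforms.
Consequently the absolute patient numbers (λ ≈ 15%, WSS of tens of Pa,
throat Re ≈ 3500) are out of reach by design; what the synthetic suite
reproduces — and what the tests assert — are the *relative* findings: the
ordering of losses across M1–M4, the unmasking of the distal stenosis when
the proximal one is corrected, the WSS ordering, and the insensitivity of
the lung flow split.

On the upstream interaction specifically (ΔP at S1 falling when S2 is
corrected): in an axisymmetric duct the upstream influence of a
constriction decays within about one diameter, so the effect here is small
(≈0.01 Pa, 0.07% of ΔP_S1) though of the reported sign — the S1 downstream
station sits at the entry of S2's acceleration region.  In the real,
tightly curved anatomy the stenoses sit closer and interact more strongly.

## Bronchial network

The lung flow split comes from a lumped tree: each branch a cylinder with
Poiseuille resistance 128μL/(πD⁴) plus a minor-loss term ½ρ(Q/A)²K/Q,
outlets at zero gauge, solved by fixed-point iteration on the secant
resistances (relative change < 10⁻¹⁰).  The trachea enters as a series
resistance taken from the CFD solution (EL/Q²).  Because a common series
element cannot change a parallel split, the surgical state leaves the split
invariant — the model-level expression of the clinical observation that
correction does not redistribute flow between the lungs.  Default branch
dimensions are **calibrated, not measured**, to a right-dominant split near
7:3 (the anomalous left pulmonary artery compresses the left side); a
healthy-infant preset near 57:43 is included.  The seven outlet labels
(LMB, LSL, LML, LIL, RSL, RML, RIL) are kept verbatim from the clinical
description even where anatomically loose (a "left middle lobe" outlet);
they are configurable.

## Validation and problem sizes

The suite exercises, at sizes chosen to keep the whole run desk-scale:

* Hagen–Poiseuille pipe (D = 3 mm, L = 0.1 m, Q = 1 L/min, developed
  inflow), three levels from 24 × 8 to 96 × 32 cells: ΔP and WSS to < 0.1%
  / < 0.1% on the finest level, velocity-profile L2 error 0.06%, observed
  order ≈ 2.  Laminar ΔP is measured between stations at 0.1 L and 0.9 L
  (scaled to full length; exact for developed flow) because the outlet
  discretization leaves a local non-converging kink at the very boundary.
* Turbulent pipe at Re = 10⁴, 60 D long, 120 × 36 cells: Darcy friction
  factor within ~3% of the Blasius correlation.
* Severity sweep r ∈ {0.3, 0.5, 0.7, 0.865}: ΔP, peak WSS and λ strictly
  increasing.
* The four-case comparison at the default 160 × 28 resolution
  (≈20 s/case): conservation, metric identities, and the qualitative
  directions above.

## Known limitations

* Axisymmetry: no curvature-induced secondary flows, no carina impingement,
  no azimuthal WSS variation; patient-absolute values are not reproducible.
* Steady RANS: a strongly separated stenotic jet can be physically
  unsteady; the steady solution is the model's time-mean surrogate, and at
  higher severities or flows the outer iterations may limit-cycle instead
  of converging (the solver then raises with its history).
* The Wilcox k–ω closure is sensitive to free-stream ω at low turbulence;
  with the 20 D inlet development and wall-dominated physics here that
  sensitivity is minor.
* The energy-loss rate of the separated flow is not grid-asymptotic at the
  coarse end of the refinement ladder (unlike the laminar benchmarks);
  comparisons are made at a fixed fine resolution across cases.
* The bronchial tree is one conduit generation plus lobar outlets; it
  carries no gas-exchange or compliance physics and its dimensions are
  calibrated to the reported split, so only split *differences* across
  surgical states are meaningful.
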