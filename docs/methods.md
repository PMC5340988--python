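# Methods

`aaafsi` is a desk-scale computational model of abdominal aortic aneurysm
(AAA) mechanics built to compare three modeling techniques on one idealized
vessel: two-way fluid–structure interaction (FSI), rigid-wall flow-only
simulation (CFD), and wall-only simulation under a uniform time-varying
pressure (CSS, "computational solid stress"). The package trades the full
3-D finite-element/finite-volume machinery of such studies for reduced-order
components that keep every *comparative* quantity computable on a laptop in
minutes. This note records the models, the parameters that matter, the
numerical choices, and what the reductions do and do not preserve.

## Parametric vessel geometry

The vessel is 190 mm long with a uniform 1.5 mm wall and an asymmetric
mid-length bulge. Its boundary is defined by five curves — lateral near-end,
lateral middle, anterior near-ends, anterior middle, posterior — each of the
form

    y(x) = C0 + A · exp(−P1 (x − x_c)² / C2),     A = κ · C1 · C3 · P2,

with the published coefficient table (C0 ≈ 10 mm baselines, C1 = 100 mm,
C2 = 7–10 mm², C3 = 0.8 mm², P1 ≈ 0.006–0.0095, P2 = 0.39–0.95) as
defaults. "Middle" curves and the posterior curve centre their bump at
mid-length (x_c = 95 mm); "near end" curves carry one bump at each end
station and therefore set the neck diameter. Lateral and anterior edges
blend their near-end and middle curves with a smooth axial weight
(Gaussian, σ = 35 mm, end-dominant at the ends and middle-dominant at the
apex); the posterior edge is a single curve.

**Calibration.** The typeset source formula for these curves is ambiguous
(the roles of π, C3, P2 in the prefactor and of C2, P1 in the exponent
cannot be read off unambiguously), so the per-curve amplitude scales κ are
the one reconstructed element. They are fixed once by solving a 5×5 linear
system that makes the generated shape reproduce the four published overall
dimensions exactly: 64.8 mm maximum lateral inner diameter, 54.6 mm maximum
anterior–posterior inner diameter, 21.6 mm neck diameter at both end
stations, 190 mm length. One ratio constraint (anterior-middle vs posterior
amplitudes keep their tabulated C1·C3·P2 ratio) closes the system. A single
global scale cannot satisfy all four dimensions (the implied lateral and
anterior–posterior scales differ by ~6 %, and the neck diameter is not
reachable from the baselines alone), which is why the calibration is
per-curve. The resulting κ are ≈ 0.37 (lateral middle), ≈ 0.35 (anterior
middle and posterior) and ≈ 0.01–0.02 (near-end corrections).

Cross-sections are ellipses through the four extremal points (±lateral
half-width, anterior and posterior extents); the exponent of the
superellipse family is 2 by default. Coordinates: x axial from the proximal
inlet, y lateral, z anterior (+) / posterior (−); the geometry module works
in mm and the solvers convert to SI.

## Wall constitutive models

Two incompressible hyperelastic strain-energy densities:

* **Anisotropic two-fiber-family model** (neo-Hookean matrix plus two
  exponentially stiffening collagen families in a ±θ double helix about the
  circumferential direction):

      W = c10 (Ī₁ − 3) + Σ_{i=4,6} k/(2k') [exp(k' (Īᵢ − 1)²) − 1]

  with c10 = 110 kPa, k1 = k3 = 210 kPa, k2 = k4 = 1700, θ = 43°. Ī₁ is the
  first deviatoric invariant of the right Cauchy–Green tensor and Ī₄, Ī₆ the
  squared isochoric fiber stretches. Fibers at 43° lie slightly closer to
  circumferential than axial, so the circumferential direction is the
  stiffer one.

* **Isotropic polynomial model**: W = C10 (Ī₁ − 3) + C20 (Ī₁ − 3)², with
  C10 = 0.174 MPa and C20 = 1.881 MPa. At physiological stretch this model
  is markedly softer than the fiber-reinforced one (the fiber exponential
  with k2 = 1700 engages within a few percent stretch).

Incompressibility is enforced exactly (J = 1); the pressure-like Lagrange
term is fixed by a declared traction-free direction — the radial direction
in all membrane use. Cauchy stress is evaluated from the deviatoric
push-forward of the energy gradient; the test suite verifies σ : D against
central differences of W along isochoric paths for both models (work
conjugacy, relative error < 10⁻⁴ over 100 random states).

**Overflow guard.** k2 = 1700 overflows double precision near fiber stretch
1.4. Energy/stress evaluation raises a saturation error carrying the
offending invariant when k (Ī−1)² > 700; root-bracketing code paths use a
clipped variant instead (the clipped value only drives brackets downward,
never enters an accepted solution).

Units: kPa internally; the isotropic constants are entered in MPa and
converted.

## Boundary waveforms and flow regime

The study's driving waveforms are known only by their qualitative structure:
inlet velocity peaking at t = 0.3 s, outlet pressure peaking at t = 0.4 s,
systolic rise over 0.2–0.3 s, deceleration over 0.3–0.5 s, low-flow
diastole. The cardiac period is taken as T = 1.0 s (the description of
diastole as running "from 0.5 s to 0.2 s of the following cycle" is
consistent with that choice). Since no numeric series is published, the
package provides a parametric stand-in: a skew-warped periodic bump

    B(t) = exp(κ(cos φ − 1)),   φ = ωδ + s(1 − cos ωδ),   δ = t − t_peak,

which is exactly periodic, C^∞, attains its maximum exactly at t_peak, and
is asymmetric for s ≠ 0 (negative s gives the fast-rise / slow-fall systolic
shape). Defaults: velocity mean 0.0299 m/s (chosen so that
Re = ρ v d/μ = 191 with the published blood properties ρ = 1035 kg/m³,
μ = 0.0035 Pa·s and the 21.6 mm inlet), peak 0.20 m/s (a resting infrarenal
systolic peak; the magnitude is a declared convention, not a published
value), κ = 12, s = −0.45; pressure 80/120 mmHg (physiological convention),
κ = 7, s = −0.30. Users can substitute digitized data through the sampled-
waveform CSV interface.

Re = 191 is deeply laminar, so the flow solver is laminar; the fully
developed turbulence-intensity estimate I = 0.16 Re^(−1/8) (8.3 % at
Re = 191) is retained as a diagnostic only.

## Fluid solver (2-D sagittal-plane ALE)

**The major deliberate reduction:** the 3-D lumen is reduced to the 2-D
sagittal plane — the plane in which the study reports its velocity fields,
wall-motion and pressure comparisons. All comparative metrics remain
computable; absolute 3-D magnitudes (e.g. the −0.587 Pa minimum WSS or the
70 Pa pressure drop) are not expected to be matched numerically.

Discretization: finite volumes on a structured boundary-fitted grid whose
columns are vertical (uniform x) and whose rows interpolate linearly
between the posterior (j = 0) and anterior (j = nz) wall polylines. Wall
motion displaces nodes vertically only. The scheme is a non-incremental
fractional-step (projection) method:

* explicit advection in ALE form — face fluxes of the previous projected
  velocity minus the mesh flux — with hybrid central/upwind face values
  (upwind where the face Péclet number exceeds 2);
* explicit over-relaxed central diffusion with deferred non-orthogonal
  corrections; wall diffusive fluxes use a second-order one-sided normal
  gradient, which makes the exact parabola a steady state of the
  discretization (plane Poiseuille WSS is reproduced to ~0.01 %);
* an exact discrete projection: the cell-centred pressure Poisson equation
  is solved with a prefactorized sparse LU for the two-point part and the
  non-orthogonal part iterated as a deferred correction until the maximum
  cell divergence falls below 10⁻⁹ of the flux scale (or the round-off
  floor, whichever is reached first);
* mesh fluxes from swept volumes, which satisfies the discrete geometric
  conservation law exactly: a uniform flow on a uniformly translating grid
  is preserved to machine precision.

Boundary conditions: prescribed parabolic inlet velocity scaled by the
waveform (profile shape configurable, flat available), prescribed outlet
pressure (Dirichlet in the projection), no-slip moving walls (impermeable:
relative wall flux is identically zero). Time step 1 ms with automatic
substepping under a CFL/viscous-stability monitor.

Diagnostics: signed wall shear stress per station from a second-order
one-sided normal derivative of the wall-tangential velocity (positive =
forward flow); wall pressure from wall-adjacent cells (this is the FSI
load); recirculation regions as contiguous negative-WSS runs longer than a
configurable minimum (default 5 mm), with strength the integrated |WSS|.

Three cardiac cycles are simulated and the last is analyzed; at the default
desk resolution (96×24 cells) the cycle-3 vs cycle-2 WSS profiles differ by
under 1 % RMS, confirming periodicity.

## Wall solver (membrane rings with tethering)

Each axial station of the wall is an independent incompressible hyperelastic
membrane ring of reference radius b(x) — the anterior–posterior semi-chord,
since the wall response is reported in the sagittal plane — and thickness
h₀ = 1.5 mm. The axial stretch is fixed at λ_z = 1 (tethered artery, both
ends fully constrained), so incompressibility gives the current thickness
h = h₀/λ_θ, and thin-wall (Laplace) equilibrium reads

    σ_θ(λ_θ) · h₀ / (λ_θ² b) = p_transmural.

The monotone residual is solved by vectorized bisection on λ ∈ (0.5, 2.0)
to ~10⁻¹⁰ relative residual; absence of a root is reported as
over-pressurization. External (tissue) pressure is taken as zero, so the
transmural load is the gauge lumen pressure.

Anterior and posterior wall sides are solved separately with a
two-curvature membrane correction: each side's effective pressure is
p − σ_z h κ_z, where κ_z is the signed axial curvature of that side's
reference profile (positive when bulging outward) and σ_z comes from a
symmetric pre-solve. This is what converts the anterior/posterior asymmetry
of the reference shape into a drift of the cross-section centre (the
centre-point metric); because the anterior profile is more strongly curved,
this mechanism drifts the centre slightly posteriorly, whereas the
published 3-D anisotropic result drifts anteriorly via fiber-orientation
effects the ring reduction cannot represent — a known limitation, and the
drift's sign is not one of the checked findings.

The both-ends-fixed condition is applied as a projection: Gaussian
influence functions anchored at the two ends (influence length 20 mm) are
subtracted with coefficients solved so the end displacements vanish
exactly; the map is idempotent and leaves mid-vessel displacements ≥ 95 %
intact. Stresses are evaluated at the tethered stretches, and the membrane
von Mises stress is √(σ_θ² − σ_θσ_z + σ_z²).

**CSS mode** drives this model with the spatially uniform outlet-pressure
waveform at the 5 ms solid time step (quasi-static: wall inertia is
neglected, which is why peak diameter and peak von Mises coincide with the
0.4 s pressure peak).

## Staggered FSI coupling

One exchange window (5 ms, the study's protocol: fluid step 1 ms, solid
step 5 ms, exchange every 5 ms) follows the serial staggered sequence —
fluid first, pressures to the solid, solid step, displacements back — and
is subiterated to convergence:

1. restore the fluid state at the window start; advance five 1 ms fluid
   steps with the wall ramped linearly to the current displacement iterate;
2. load the wall with the fluid wall pressures averaged over the window
   (averaging suppresses staggering noise);
3. solve the quasi-static wall; under-relax the interface displacement,
   d ← d + ω(d_new − d);
4. repeat until the displacement update is below 10⁻³ mm (typically 2–3
   subiterations; each accepted window is therefore a converged two-way
   step, and the fluid boundary matches the wall to the tolerance).

The default under-relaxation is ω = 0.3: the incompressible fluid gives the
staggered fixed point an added-mass gain of roughly −3 during systole, for
which ω = 0.5 is marginal while ω = 0.3 contracts with factor ≈ 0.2. Both ω
and the tolerance are config-exposed. The run starts from the static
diastolic wall state (pre-inflation under the t = 0 outlet pressure), which
removes an artificial pressurization transient from the first window.

Two limits anchor the coupling against the simpler techniques and are
enforced in the test suite: multiplying the wall stiffness by 10⁶
reproduces the rigid-wall CFD flow to < 0.1 % RMS, and forcing the wall
load to the spatially uniform outlet pressure reproduces the CSS wall
history to round-off.

## Comparison metrics

* **Axial WSS profile**: station-wise mean of the two wall-side WSS values
  (the 2-D reduction has no circumferential direction to average over), at
  the four snapshot times 0.2, 0.3, 0.45, 0.5 s of the final cycle.
* **Pressure drop**: mean inlet wall pressure minus mean outlet wall
  pressure, and its fraction of the instantaneous outlet pressure.
* **Proximal-neck WSS ratio (CFD/FSI)**: the median station-wise ratio
  |WSS_cfd(x)|/|WSS_fsi(x)| over the proximal window x/L ∈ [0.05, 0.30].
  Two deliberate choices here. First, the window excludes the
  inlet-adjacent 5 %: both techniques share the *prescribed* inlet
  velocity, so their wall shear there is equal by construction and any
  ratio formed from it measures noise. Second, the ratio is a pointwise
  median rather than a ratio of window peaks: the window's peak |WSS|
  always sits at its attached-flow inlet-side edge, so a peak ratio again
  compares the techniques where they cannot differ, whereas the pointwise
  statistic measures the actual rigid-wall overestimation in the region
  (≈ 5–11 % here at deceleration, versus the published 30 % for the 3-D
  vortex field). Window and noise floor are config-exposed.
* **Wall histories**: maximum inner AP diameter, centre-point offset at the
  maximum-diameter station, peak von Mises, per saved time.
* **Recirculation inventory/strength** per snapshot.
* **compare_models** verifies that all runs share the scenario fingerprint,
  assembles the above, and emits a deterministic key-value summary
  (fixed %.6g formatting; byte-identical across repeated runs) plus CSVs.

## Directional findings and known limitations

At the default desk scale the package reproduces, in direction:

* vortex development during deceleration (recirculation strength at 0.45 s
  exceeds that at 0.3 s, and reversed-flow regions reach the proximal
  side);
* rigid-wall overestimation of deceleration-phase wall shear in the
  proximal window (ratio ≥ 1);
* near-coincidence of FSI and CSS wall response (maximum-diameter RMS
  difference well under 0.5 mm) under the small computed pressure drop
  (< 1 % of outlet pressure at peak systole, the same "minimal pressure
  drop" mechanism the study invokes);
* larger diameters for the isotropic wall (≈ 59.8 mm vs ≈ 56.2 mm peak at
  desk scale; the published 3-D values are 61.5 vs 57.0 mm);
* the length effect: stretching the vessel axially (240/190) increases both
  the peak-systolic pressure drop magnitude and the CSS-vs-FSI peak-stress
  gap.

**Known, deliberate non-reproduction:** the published result that the
isotropic wall carries a *smaller* peak von Mises stress (0.467 vs
0.673 MPa). In a load-controlled membrane, equilibrium forces
σ_θ ≈ p b λ²/h₀, so the softer wall (larger λ, larger current radius,
thinner wall) necessarily carries *more* stress; the published ordering
comes from 3-D shell bending/stress concentration at the shoulders (the
published peaks are 1.5–2.4× the apex membrane estimate), and bending is
explicitly outside this package's structural model. The corresponding
finding is reported honestly as failed in the comparison report, and the
acceptance test for it is expected to fail.

## Problem sizes and determinism

Default study conditions: geometry sampled at 201 stations; fluid grid
96×24 cells; three 1 s cycles at 1 ms fluid / 5 ms solid steps; wall model
on the fluid cell columns. These sizes were chosen so a full
four-run comparison (FSI aniso/iso, CFD, CSS) completes in roughly ten
minutes on one core; the paired length-effect runs use a coarser 48×12,
two-cycle configuration. Halving the resolution changes the comparison
metrics by a few percent and flips none of the directional findings.
Everything is deterministic: there is no randomness anywhere in the
pipeline (test utilities seed their own generators), and identical configs
produce byte-identical reports.

Other limitations, shared with the study or inherent to the reduction:
Newtonian blood, laminar flow, homogeneous single-layer wall, no
surrounding tissue constraint, no intraluminal thrombus, no residual
stress, uniform wall thickness, no bending stiffness, prescribed (rather
than measured) waveform magnitudes.
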