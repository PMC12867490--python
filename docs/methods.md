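# Methods

This note documents the physical model, the unit conventions, the
numerical scheme and the deliberate design choices behind `pwspdt`.
Nothing here is a measured result; every number quoted as an output is
computed by the test suite or by `scripts/acceptance.py`.

## Geometry and discretization

The tissue block is a uniform cell-centered voxel grid, z = 0 at the
air–skin surface and increasing downward.  Layers are assigned by the
depth of the voxel center: stratum corneum 0–10 μm, viable epidermis
10–110 μm, papillary dermis 110–210 μm, reticular dermis to 810 μm.
Two capillaries run along x at 360 μm center depth with 40 μm lumen
diameter, 5 μm wall and 250 μm center-to-center spacing.  The lateral
extents (500 × 500 μm) are a design choice: they center the vessel
pair with 125 μm margins, and the zero-flux lateral boundaries then
emulate a periodically repeating vessel array.

Two working resolutions are provided.  The *fine* grid (5 μm voxels)
resolves the wall as a one-voxel annulus; the *coarse* grid (10 μm,
`coarse_wall=True`) assigns the wall to the nearest voxel shell around
the lumen, which overestimates the wall volume (the region is a mean,
so dose statistics are only mildly affected) and is the default for
the scenario suites, the tests and the acceptance script
(50 × 50 × 81 = 202 500 voxels, 2.5 s steps).  These problem sizes
were chosen as the package's desk-scale default; the fine grid is
available through `GeometryConfig(voxel_size=5.0)`.

The arteriolar inlet is the x = 0 face of each lumen, the venular
outlet the x = Lx face.

## Light transport

The 532 nm fluence rate is solved once per scenario as the steady
state of the diffusion approximation with the optical properties
(μa, μs, g, n) per region listed in `geometry.OPTICAL_TABLE`.  The
speed-of-light factors of the transient formulation cancel in steady
state, so the solver works in the unit-speed convention.  The surface
carries the inward-flux condition `(1−r)P = −D ∂ψ/∂z` with
`r = ((n−1)/(n+1))² = 0.034` for n = 1.45; all other faces are
zero-flux.  Finite volumes with harmonic-mean face diffusivities give
a symmetric positive-definite system solved by Jacobi-preconditioned
conjugate gradients to a relative residual of 1e−10; the solution is
computed for unit irradiance and scaled, so linearity in P is exact.

The stratum corneum is an extreme layer (μa = 181 cm⁻¹,
μs = 2200 cm⁻¹, g = 0.925, taken verbatim from the source data); the
diffusion approximation is formally marginal there, and depth profiles
are normalized to the fluence reconstructed at the z = 0 face so that
the normalization does not depend on the voxel size.

## Oxygen and photosensitizer transport

Both species obey advection–diffusion–reaction equations with uniform
diffusivities (Do = 1500 μm²/s, Dm = 50 μm²/s).  Boundary conditions:

* oxygen — Dirichlet at the skin surface (Henry conversion
  `Co = α·pO2`, α = 1.459×10⁻³ mol/(m³·mmHg), so 159 mmHg ↦ 0.232 and
  100 mmHg ↦ 0.146 mol/m³) and at the arteriolar inlet faces
  (100 mmHg); zero flux elsewhere;
* photosensitizer — Dirichlet at the inlet faces following the
  infusion ramp; no transdermal source.

The infusion input function is a monotone piecewise-cubic (PCHIP)
interpolation of the printed anchor concentrations
(0, 0.018, 0.041, 0.061, 0.067 mol/m³ at 0, 300, 600, 900, 1200 s),
continued after the 20-min infusion by a single exponential with a
configurable half-life (default 3600 s).  The anchors are an emulation
of the slow-bolus blood pharmacokinetics, not a mechanistic PK model;
delayed-illumination scenarios depend on the washout branch and should
be read accordingly.

Blood oxygen is dissolved-only: there is no hemoglobin reservoir.  A
consequence worth stating plainly is that the capillary oxygen content
depletes *axially* — tissue demand drains the dissolved store within
roughly a hundred micrometers of the arteriolar inlet — producing the
inlet-centered oxygen, photosensitizer and ROS patterns characteristic
of this treatment geometry.  A hemoglobin-buffered blood pool would
flatten these axial gradients; it is out of scope here.

The metabolic sink Γ1 = 1.7×10⁻³ mol/(m³·s) applies in tissue (not
lumen) voxels and is multiplied by the smooth cutoff
`Co/(Co + c_eps)`, `c_eps = 10⁻⁴ mol/m³` (≈ 0.07 mmHg), so that
consumption shuts off as oxygen depletes and the anoxic steady state
is well-posed; this replaces a hard nonnegativity clip on the sink.

## Photochemistry and unit closure

The ROS generation rate (taken equal to the photochemical oxygen
consumption) is

    Π_ROS = κ · 2.303 ε Φ · Cm · ψ_mol · Co/(Co + β),

with ε = 9252 L/(mol·cm) (925.2 m²/mol), Φ = 0.6, and
`ψ_mol = ψ·λ/(N_A h c)` the molar photon flux (4.447×10⁻⁶ mol of
532 nm photons per joule).  As printed, the product `2.303 ε Φ Cm ψ`
does not close dimensionally to mol/(m³·s); the photon-molar
conversion restores the units up to one dimensionless calibration
constant κ.  κ is fixed once, on the coarse grid, by requiring the
normoxia baseline's mean vessel-wall cumulative ROS at 1200 s to equal
the 0.222 mol/m³ damage dose; the calibrated default is
κ = 8.793×10⁻⁴.  Because the thresholds are themselves re-calibrated
from the baseline run, every derived metric (damage times, pain times,
PSC, therapeutic-zone masks) is invariant under rescaling κ up to the
weak feedback of Γ2 on the oxygen field; the property suite verifies
this numerically for factors 0.1 and 10.

**The oxygen half-saturation constant β = kp/kot.**  The source table
prints "2.5 mol/L", which is dimensionally unusable (dissolved oxygen
in tissue is ~10⁻¹ mol/m³; 2.5 mol/L exceeds the molarity of pure
oxygen-saturated water a thousandfold).  Reading it as 2.5 mol/m³
makes the oxygen factor linear in Co everywhere, and the simulated
oxygen-regime sensitivities then overshoot all of the reported
kinetics by large factors (the anoxia pain threshold is never even
reached).  The package therefore defaults to the standard
porphyrin-photosensitizer value from the PDT dosimetry literature,
β = 11.9 μM = 0.0119 mol/m³, which places healthy tissue in the
mildly saturating regime; the parameter is exposed in
`PhotochemParams(beta=...)` for sensitivity studies.  This is the one
substantive parameter choice made against the printed table, and it is
the main caveat to quantitative comparisons.

Photobleaching uses the same photon-flux convention,
`Γm = −κ_b Km [Co/(Co+β)] ψ_mol Cm²` with Km = 66.21 (printed unit
"mol/W", likewise not closable; absorbed into κ_b = κ).  At the
calibrated κ the bleaching time scale far exceeds the treatment, so
bleaching is a small correction; the quadratic ODE itself is verified
against its closed form `Cm(t) = Cm0/(1 + k Cm0 t)` in a well-mixed
(0-D) test.

## Time integration

Each species advances per global step (default dt = 2.5 s) with a
Douglas ADI (stabilizing-correction) scheme: the full transport
operator — diffusion on all three axes, first-order upwind plug
advection along the lumen lines, the Dirichlet face couplings — plus
the explicit reaction sources enter the predictor; one implicit
batched-tridiagonal correction per axis follows.  Two properties drove
this choice over sequential operator splitting:

* the fixed point of the scheme satisfies the *unsplit* steady
  equation exactly, so steady fields (notably the pre-illumination
  oxygen field) carry no splitting error and are independent of dt;
* sequentially splitting the sub-cycled lumen advection against the
  implicit diffusion left an O(dt) steady-state error concentrated at
  the lumen, several tens of percent at the wall.

The advective Courant number u·dt/h ≈ 125 is handled implicitly and
unconditionally stably, but above dt ≈ 5 s the iteration toward steady
state develops slowly damped oscillatory modes; defaults are dt =
2.5 s for treatments and 5 s for the dark relaxation that initializes
the oxygen field.  Halving dt changes the vessel-wall cumulative dose
at 1200 s by well under 1% (asserted in the property suite).  Douglas
corrections can undershoot marginally at steep fronts; fields are
floored at zero after each step (the conservation test bounds the
effect at ≤ 10⁻⁸ relative over 1000 steps).

Region time series (mean ROS rate, cumulative ROS, photosensitizer and
oxygen per region) are recorded every 10 s; threshold crossings are
interpolated linearly between samples.

## Metrics and calibration conventions

`calibrate_thresholds` reads the damage threshold off the baseline
wall dose at exactly 1200 s and the pain threshold off the papillary
rate at exactly 600 s, which forces the baseline's damage time, pain
onset and duration to 1200 / 600 / 600 s identically — a convention,
not a prediction.  PSC follows the printed defining equation
(papillary-dermis denominator); the surrounding prose names the
epidermis instead, so `psc(..., denominator_region="epidermis")`
exposes the alternative.  If the damage threshold is not reached
within the horizon, downstream metrics are reported absent rather than
extrapolated.

## What the scenario suite does and does not show

The suites re-create protocol *conditions* (surface-oxygen regimes,
irradiance 100/150/200 mW/cm², lumen diameters 40–100 μm with R²
velocity rescaling, inlet pO2 100/90/80 mmHg, illumination delays
0/600/1200 s).  Within them, the self-calibrated kinetics — damage
times, pain onset and duration shifts under oxygen restriction — track
the reported treatment behavior closely at desk scale.  Two quantities
are known to sit above their reported counterparts and are reported
as-is by the acceptance script: the fluence fraction at the
dermal–epidermal junction (the diffusion approximation with these
coefficients yields ≈ 0.66 of the surface value against a reported
0.59) and the spatial concentration ratios of wall versus superficial
compartments (photosensitizer wall/epidermis ≈ 380% against a reported
240%, and correspondingly PSC magnitudes about twice the reported
ones, with a non-monotone normoxia→hypoxia step).  Both trace to how
strongly the model concentrates photosensitizer and dose at the vessel
relative to the superficial layers; the discrepancy is documented
rather than fitted away, because no printed parameter choice we
consider defensible closes it.

The model also simplifies real tissue in ways the tests cannot probe:
straight rigid vessels, plug flow, no vascular shutdown or coagulation
response, no thermal effects, no type-I/type-II photochemistry split,
and ROS treated as locally deposited dose (no singlet-oxygen
diffusion).  Conclusions about absolute clinical dose therefore rest
on the 0.222 mol/m³ calibration convention, not on first-principles
photochemistry.
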