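# Methods

`pvlsim` models systolic regurgitation through a mitral paravalvular leak
(PVL): with the mitral valve closed, the contracting left ventricle (LV)
drives blood out through the aorta and backward through the leak channel into
the left atrium (LA).  The pressure difference across the leak (~79 mmHg)
forms a millimetre-scale jet whose shear stresses are the package's subject:
stresses above a critical level (300 Pa here, with a 150–800 Pa literature
sweep available) mechanically damage erythrocytes, and the volume of fluid
above that level together with the residence time in it indexes hemolysis
risk.

## Geometry model

The LV is a body of revolution: basal diameter d_LV1 = 45 mm widening to the
maximal diameter d_LV2 = 76.5 mm at 35% of the axial length, then an elliptic
taper to the apex.  The axial length is solved (Brent root find on a
2001-point trapezoid quadrature of the profile) so the chamber volume equals
the 87 mL reference — the mean of the 118 mL end-diastolic and 56 mL
end-systolic volumes.  Mitral (24 × 20 mm) and aortic (20 mm) diameters are
carried for completeness; the flow solver never meshes the full chamber (see
Reduction below).

Leak channels are straight ducts of height 3 mm with a 0.3 mm circular-arc
fillet where the channel meets the upper LV wall.  Cross-sections come in the
four clinically reported families, each parameterized so the realized area
equals the requested CSA exactly:

| preset  | family   | CSA (mm²) | aspect (width/gap) | reduction |
|---------|----------|-----------|--------------------|-----------|
| PVL I   | oval     | 7.9       | 3                  | axisymmetric (equal-area radius) |
| PVL II  | slit     | 1.5       | 8                  | planar |
| PVL III | crescent | 18.5      | 6 (120° sector)    | planar |
| PVL IV  | slit     | 5.0       | 5                  | planar |

Clinical imaging does not pin the aspect ratios; the values above preserve the wide
(untreated: I, III) versus narrow (residual after incomplete closure: II, IV)
dichotomy and are configurable.  The crescent is an annular sector spanning a
fixed 120°; its area R·θ·g is exact and its gap follows from the aspect.

## Reduction to two dimensions

Full-scale clinical-CFD treatments of this configuration solve the 3D chamber
on hundreds of thousands of polyhedral cells in commercial solvers.  Here
each channel is reduced to its meridional/plane
section: round/oval sections become an axisymmetric r–z duct of equal area,
slit and crescent sections a planar gap carrying the section width per unit
depth.  The LV chamber is replaced by an upstream plenum and the LA by a
downstream plenum, each extending at least three channel widths laterally and
axially (`plenum_factor >= 3`).  All reported metrics live in the
channel-entrance jet, which the meridional section captures; what the
reduction cannot represent are the slit's side-wall (end) losses, in-plane
crescent curvature, and chamber-scale swirl — see Limitations.

Rasterization snaps the channel walls onto cell faces (so the lumen area is
exact), resolves the entrance fillet as a quarter-arc staircase whose
boundary cells carry their open-area fraction for volume accounting, and tags
the bottom edge as the inlet, the top edge as the LA outlet, and lateral
edges as walls (or the axis at r = 0).  The default in-lumen cell size is
half-gap/12 capped at 0.25 mm; the axial spacing defaults to twice the
transverse one, capped at 3/4 of the fillet radius.

## Flow solver

Incompressible Navier–Stokes on a staggered (MAC) uniform grid, advanced by
an explicit fractional-step scheme: second-order upwind-biased advection
(first-order fallback through wall ghosts), centered viscous fluxes with the
effective viscosity mu + mu_t, then an exact discrete projection via a sparse
LU factorization of the finite-volume Laplacian (factorized once per grid).
Divergence after projection is at solver precision (~1e-12 scaled), which is
also what makes the global mass balance close to ~1e-10 relative at steady
state.  Axisymmetric metric terms (2πr face areas and volumes, the -u/r²
radial term and the u/r hoop strain) are built into the same operators; the
axis r = 0 is a natural zero-area boundary.

Boundary conditions are the three kinds the leak problem needs:

- mass-flux inlet: a uniform normal velocity over the tagged edge, rescaled
  after discretization so the integrated flux matches the request exactly;
- pressure boundary: fixed static pressure in the projection (Dirichlet on
  the pressure), zero-gradient velocity, with provisional backflow clipped at
  the outlet and the clipped total reported as a diagnostic.  The LV-side
  inlet of a channel run is such a pressure boundary, holding the lumped-model
  chamber pressure;
- no-slip walls on faces, with quadratic tangential ghosts, which is what
  makes plane and axisymmetric Poiseuille converge at second order
  (verified: observed order ≈ 2.0, profiles and wall shear within 1% of the
  closed forms at 64 cells across the duct).

Steady states are reached by pseudo-time marching with a stability-limited
step (CFL 0.4 and the explicit diffusion limit).  Convergence requires both a
normalized residual (peak velocity change per step over the convective
acceleration scale u_ref²/L) below `tol` and a plateau of the mean wall shear
(relative change < 0.1% over 100 steps); hitting `max_iters` returns the
state flagged non-converged.  High-Reynolds jet cases are statistically
steady rather than steady — the jet flutters in the downstream plenum — so
channel runs time-average the fields over a trailing window (`avg_window`,
400–600 steps at desk scale) and report metrics of the mean field.  Inlet
pressure ramps over the first 250 steps to avoid an impulsive start.

A transient mode marches the full 0.68–0.98 s systolic window with the
leak share of the tabulated inflow profile as a time-varying flux inlet
(nominal 1 ms step, automatic stability sub-stepping) and stores snapshots at
the seven reference instants.

## Turbulence closure

Menter's k–ω SST model: eddy viscosity
mu_t = rho·min(k/ω, a1·k/(S·tanh(φ²))) with a1 = 0.31 and
φ = max(2√k/(0.09·ω·y), 500ν/(y²ω)) — tanh(φ²) is the F2 function; k and ω
transport with the 2003 coefficient sets (inner σ_k 0.85, σ_ω 0.5, β 0.075,
α 5/9; outer 1.0, 0.856, 0.0828, 0.44) blended by F1, production limited to
10·β*·ρkω, semi-implicit destruction and floors (k ≥ 1e-12 m²/s²,
ω ≥ 1e-6 s⁻¹) preserving positivity.  Wall treatment is the low-Reynolds
practice consistent with sublayer-resolving grids: k → 0 at walls (Dirichlet
in the wall diffusion flux) and ω = 60ν/(β1·y²) in wall-adjacent cells.
Wall distance is an exact Euclidean distance transform to wall-face centres
on a half-spacing lattice.

Inlet turbulence uses a 5% intensity and a length scale of 10% of the lumen
width, evaluated from the *local* inlet velocity each step: the plenum feed
is slow (cm/s), so inflow turbulence is negligible and the jet's turbulence
is produced by its resolved shear layers.  These inflow settings are
configuration defaults, not clinically measured values.

## Hemolysis metrics

- Interior shear magnitude τ = (μ + μ_t)·√(2 S_ij S_ij) per cell (exactly μγ̇
  in laminar simple shear).
- Wall shear per wall facet from the two nearest cell centres with a
  quadratic one-sided fit through zero at the wall — exact for a parabolic
  sublayer profile.
- V300: summed cell volume in the lumen (channel band including the fillet)
  where τ exceeds the threshold; exceedance carried by the downstream jet in
  the LA plenum is reported separately so V300/V_PVL stays interpretable.
- t300 = V300·ρ/ṁ_PVL with ṁ_PVL the simulated channel mass flow (the
  identity holds to machine precision by construction).
- Backflow ratio from the lumped split model (below); the simulated leak flow
  is reported alongside.
- u_CP: speed interpolated at the lumen centre at mid-height; u_AVG:
  mass-weighted mean speed over the lumen; u_axis_max: peak speed along the
  channel axis.

## Lumped flow split

The 3D chamber's role — dividing the contraction-driven inflow between the
aortic outlet and the leak — is closed by a two-branch lumped model: a linear
aortic resistance q_a = (p_LV − p_ao)/R_a and an orifice law
q_PVL = c_d·A·√(2·max(p_LV − p_LA, 0)/ρ), solved for the chamber pressure
p_LV by bracketed root finding (conservation then holds to ~1e-10 relative by
construction).  Defaults: c_d = 0.80 (typical sharp-entrance orifice range,
calibratable against the channel simulations) and R_a = 7.5e5 Pa·s/m³, chosen
so the chamber pressure buildup at peak flow is of order 10² Pa above the
102 mmHg systolic arterial pressure, matching the qualitative chamber
pressure excess the full simulations display.  The channel runs are driven by
p_LV from this split at the case's flow point against the 23 mmHg LA
pressure.

## Desk-scale problem sizes

The reference channel runs use per-preset lumen cell sizes of 12–35 µm
transversely (8.7k–100k cells per case), 1200 marching steps plus a 400-step
averaging window.  The narrow PVL II slit keeps its 12 µm shear-layer-
resolving grid at every flow point — its centre velocity is still moving with
resolution at coarser grids — while the wide presets use the half-gap/12
default off peak.  These sizes were chosen as the coarsest grids that resolve
the entrance wall-shear peak into the super-critical range; the wall-shear
maximum is the quantity most sensitive to resolution (it grows roughly like
1/Δ until the entrance boundary layer, ~15–30 µm, is resolved) and desk-scale
values are therefore conservative underestimates of the 600–1200 Pa peaks
that wall-layer-resolving 3D simulations reach.  Centre-point and axis velocities are pressure-controlled
and already grid-converged at the default resolution to within a few percent.

## What passing tests do and do not show

The synthetic geometries emulate imaging-derived leak channels only in
family, area, height and fillet; true patient-specific outlines (and aspect
ratios) are not standardized measurements.  The 2D reduction reproduces
pressure-driven jet physics — Bernoulli-limited core velocities, entrance
shear concentration, viscous slit losses — but not 3D effects: slit end-wall
friction (which lowers narrow-channel centre velocities below the planar
prediction), crescent curvature, chamber swirl, or transient LA pressure
fluctuation (boundary pressures are held constant).  Agreement of the
desk-scale velocities with reference centre-point values from full 3D
simulations therefore validates the pressure-driven core physics, not the
full 3D flow field; V300/V_PVL fractions and residence times are reported as
indicators, not as reproductions of any reference values.

## Numerical choices and degenerate inputs

- mmHg → Pa uses 133.322, consistent with the clinical value pairs the model
  is built on (23 mmHg ↔ 3066.4 Pa, 102 mmHg ↔ 13598.8 Pa) to one decimal.
- The systolic profile interpolates the seven tabulated points plus zero
  endpoints with a monotone PCHIP: anchor-exact, non-negative, continuous;
  flow is identically zero outside 0.68–0.98 s and times wrap modulo the 1 s
  cycle.
- Table displays round mass flows to 3 decimals; internal arithmetic is
  unrounded.
- Zero-area leaks, zero inflow, and empty study grids are valid inputs with
  the obvious results; zero-height channels have zero volume; a grid too
  coarse for the fillet drops it with a warning; a domain with no lumen cells
  or no walls is an error.
- Reruns with the same configuration and seed are bit-identical (the only
  randomness is an optional initial perturbation, default off).

## Known limitations

Uniform grids: near-wall resolution at the entrance sets the whole grid
size, which is what bounds desk-scale wall-shear accuracy.  The SST
transport uses first-order upwind advection (the momentum equations are
second order).  The planar reduction's per-unit-width model overestimates
narrow-slit centre velocities by ~10% against full 3D reference values (end
walls are absent).  The lumped aortic branch is linear; no attempt is made to
model diastole, atrial mechanics or moving walls.
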