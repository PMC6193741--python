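# Methods

`oncoflow` is a desk-scale, staggered multiphysics model of solid-tumour
growth, perfusion and cytotoxic drug delivery on a synthetic capillary
network.  This note records the governing model, the numerical choices, the
calibration, and what the synthetic setting does and does not represent.

## Geometry and discretisation

The tissue block is a cube (default 11.9 mm edge, ≈1.7 cm³) discretised
into a structured hexahedral grid (default 12³ elements); a 1 mm diameter
spherical tumour sits at the centre.  The vasculature is a 1D graph of
straight capillary segments embedded non-conformingly in the grid: the
synthetic generator places nodes uniformly at random, guarantees
connectivity by a minimum-spanning backbone of the k-nearest-neighbour
graph, and adds the shortest unused links up to the requested segment count
(default 420 at desk scale; a paper-scale profile uses 2,880).  Inlets and
outlets sit on opposite domain faces.  Segment-to-grid coupling distributes
each segment's wall area 2πRL to the corner nodes of its host elements by
midpoint-rule quadrature with trilinear weights (first-order accurate); the
resulting convex weights serve both to spread transvascular sources and to
sample interstitial fields along segments.

All internal quantities are SI; I/O helpers convert mmHg and μm.

## Fluid problem

One sparse linear solve couples:

* Poiseuille flow on each non-collapsed segment, conductance πR⁴/(8μ_B L);
* Starling filtration Q̇_trv = K_vsc A_vsc (p_eff − p_int), with the pore
  model K_vsc = γ_p r_p²/(8 μ_P h) and
  p_eff = p̄_vsc − σ_o(π_vsc − π_int);
* Darcy flow in the tissue (7-point finite volumes, face conductivity
  averaged between nodes, different K_int in tumour and host);
* a homogeneous lymphatic sink K_lmp S_lmp (p_lmp − p_int) per unit volume
  with p_lmp = 0 and S_lmp = 0 inside the tumour (dysfunctional tumour
  lymphatics).  A discrete Hagen–Poiseuille lymph-segment law is available
  for verification.

The transvascular exchange is assembled as pairwise endpoint-to-node fluxes
½K_vsc A w_si (p_vsc,n − σΔπ − p_int,i).  These sum to the Starling flux per
segment but keep the coupled matrix an M-matrix, so a discrete maximum
principle holds even when the wall conductance exceeds the axial and tissue
conductances (the hyperpermeable regime).  Boundary conditions: Dirichlet
pressures at vascular inlets/outlets (25/10 mmHg defaults; the source
study does not print its values) and far-field p_int = 0 on the tissue
boundary.  Junction mass balance and the global
filtration = drainage + boundary-outflow identity hold to solver precision.

Because the desk-scale network carries ~10³ fewer segments than real
capillary beds, the pore fraction γ_p (0.06) is chosen so that the product
K_vsc·S_vsc lands in the physiological range of tumour filtration
coefficients; K_int values are Baxter–Jain-style literature numbers with
the tumour value at the low (desmoplastic) end.

## Drug delivery

Concentrations are dimensionless fractions of the injected peak c_v-max.
The bolus is a Dirichlet inlet condition c_v(t) = c_v-max·exp[−(t−t_inj)/τ_c];
τ_c is implemented as the e-folding time of that printed exponential (a
helper converts a half-life, τ_c = t½/ln 2).  Intravascular transport is
pure advection with first-order upwind donor-cell fluxes at junctions;
outlets are free outflow, and filtrate leaving through the wall carries the
local concentration.  A few sprout-tip nodes with tiny lumen volumes are
orders of magnitude stiffer than the rest of the network; they are held at
their local flux equilibrium while the bulk advances at its own CFL step.

Extravascularly the free/bound/internalised system follows linear kinetics
with rates k_on, k_off, k_int, δ_i active only in the tumour; free drug
diffuses with the Stokes–Einstein diffusivity D_c = k_B T/(3π μ_I s_c) and
is advected by the Darcy velocity (negligible for this drug class — the
measured interstitial Péclet number is ≪0.1).  Transvascular solute
exchange uses a cylindrical-pore hindered-transport model with
λ_r = s_c/(2 r_p): steric partition Φ = (1−λ_r)², Renkin centreline drag
H(λ_r), diffusive permeability P_vsc,d = γ_p Φ H D_c/h, and solvent-drag
reflection σ_f = 1 − Φ(2−Φ)(1−λ_r²/3).  The correlation is a documented,
swappable choice pinned by its own oracle test.

Numerics: the exchange is written in the affine form Φ = a − b·c_f and the
c_f-proportional part integrated implicitly (unconditionally stable and
positive for hyperpermeable walls); explicit diffusion/upwinding sub-steps
under the combined bound dt ≤ 0.8/(6D_c/h² + 3|v|/h); the reaction block is
integrated *exactly* (closed-form eigen-solution of the 2×2 binding block,
then the forced linear c_i equation), so the only splitting error is in the
transport coupling.  In the coupled loop the intravascular advection is
advanced by one backward-Euler upwind solve per exchange window — the
bolus decays over hours while the network transit time is seconds, so the
implicit step is both accurate and exactly mass-accounted; the explicit
CFL stepper remains available and verified for time-resolved studies.
The lymphatic solute term acts as drainage only; where p_int < p_lmp the
influx is assumed to carry lymph (zero) concentration, since the literal
sink formula would otherwise become a self-amplifying source.  Exchange is
gated on the segment perfusion flag.  Bound/internalised drug in tissue
released by a regressing tumour boundary remains in place as inert debris
(all rates vanish outside the tumour) and is re-engaged if the boundary
sweeps back; zeroing it instead couples the drug budget to grid-level
boundary fluctuations.

## Tissue biochemistry and growth

Oxygen ξ and the matrix-degrading-enzyme (MDE) surrogate μ are quasi-steady
diffusion fields: ξ is sourced by perfused vascular density with
first-order consumption (faster inside the tumour) and normalised to the
healthy-host level at day 0; μ is sourced by the tumour region and sprout
tips with linear decay.  Both are dimensionless in [0, 1]; the full
reaction–transport balances they stand in for are beyond the desk-scale
scope, and only the products δ_ϵ·μ·ϵ and the Gompertz argument γ_g·ξ enter
the dynamics.

ECM structural integrity evolves by
dϵ/dt = λ_ϵ ξ e^{−2ϵ/ϵ̄} − δ_ϵ μ ϵ − C with the drug-depletion term
C = δ_d ϵ (c_i − c̄_i)^{a_d} active only in the tumour where ϵ > ϵ̄_d; the
(c_i − c̄_i) base is clamped at zero.  The law is a smooth node-local ODE
(ξ, μ, c_i frozen over the coupling window), integrated with RK4 sub-steps
(≤ 0.01 day, further reduced when the depletion term is fast) — orders of
magnitude inside the 1e-6 verification tolerance.

Growth is the modified Gompertz strain
ϑ_g = G·e^{−β_g e^{−γ_g ξ}} − G·e^{−β_g}, G = α_g ϵ^{δ_g}, λ_g = √(2ϑ_g+1),
an instantaneous function of state: the slow ECM build-up (λ_ϵ) and the
declining oxygen drive the volume trajectory, and drug-induced ECM
depletion lowers G — that is the regression mechanism.  The realised strain
relaxes toward this target with a first-order lag τ_g (1 day): tissue
cannot remodel instantaneously, and the lag also filters the discrete
vascular noise out of the volume curve.

## Solid mechanics

Multiplicative decomposition F = F_e·F_g with isotropic growth F_g = λ_g I
and the modified Neo-Hookean energy W̄ = m/2(Ī₁ − 3) + κ/2(J − 1)², with
m(ϵ) = μ ϵ^{a_w}.  The default scenario is spherically symmetric, so
equilibrium is solved on a reduced radial grid: total stored energy is
minimised over the deformed radii by damped Newton on the discrete
Euler–Lagrange system (tridiagonal Hessian via coloured finite
differences), started from the volume-matched incompressible profile;
relative force residuals reach ~1e-10.  Tissue hydrostatic pressure is
THP = κ(J_e − 1) (the isochoric Cauchy term is traceless); negative THP is
compressive.  The solution maps back to the 3D mesh by radius, vascular
nodes advect with the material displacement, and the tumour indicator
follows the deformed tumour boundary.  When the boundary sweeps over grid
nodes, entering nodes inherit the tumour-mean state (they are displaced
tumour tissue) and nodes released on regression revert to host — without
this the Eulerian indicator would feed host ECM into G(ϵ) and the growth
law would run away.

Deformed tumour volume comes from the radial solution,
V(t) = 4π r(a₀)³/3 with a₀ the material tumour radius; the reported
quantity is V = Vol(t)/Vol(0) − 1.

## Vessel states, remodelling, sprouting

Each segment's net compressive load is (−THP + p_int) − p_vsc sampled at
its midpoint.  Above 200 Pa the segment is compressed (radius ×0.6,
reversible); above 900 Pa it collapses (conductance zero, permanent — the
conservative reading of the re-assessment loop).  Radii remodel by
dR/dt = gain·R·(WSS − τ_set)/τ_set with WSS = 4μ_B|Q̇|/(πR³), bounded in
[2, 12] μm.  Sprouting is a seeded stochastic surrogate for the full
snail-trail model: parent nodes near hypoxic peri-tumoural tissue fire at
rate·dt, emit 0.3 mm tips down the oxygen gradient with angular jitter,
anastomose within 0.15 mm, and are capped at a few percent of the segment
count per step and 2.5× the initial count overall.

## Architecture metrics

δ_max is the maximum, over a fixed 16³ sample grid spanning the central
analysis subdomain, of the exact distance to the nearest non-collapsed
segment (a KD-tree candidate-pruned search that matches the brute-force
scan bitwise), reported normalised by its day-0 value.  The convexity
index is λ = 1.4 − 4.0·skewness(d) over the same nearest-distance sample:
a uniform space-filling network gives λ ≈ 0.5, and growing avascular voids
fatten the right tail and drive λ negative.  The exact published index it
stands in for is not reproduced in the source study, so every λ-based
check in the package is ordinal, never cardinal.  The perfused fraction is
the length-weighted share of non-collapsed segments with |v| > 0.1 mm/s.

## Coupling loop

Per outer step (6 h; 12 h in the reduced sweep profile):
biochemical solve → solid solve → network update (sprouting, remodelling,
re-embedding) → fluid solve → drug solve (15-min exchange windows with
internal CFL sub-stepping) → vessel-state re-assessment with a fluid
re-solve when any state changed.  Flow is quasi-steady and re-solved after
every geometry or state change.  All randomness flows from the run seed
through one generator; a (config, seed) pair reproduces every output
exactly.

## Calibration

The supplementary parameter tables of the source study are not public, so
the parameter file carries literature-anchored physiological defaults, and
four quantities were fixed once by the shipped seed-deterministic
calibration (`oncoflow calibrate` automates the growth part):

* α_g = 80 — so the low-poresize 40-day control meets the growth anchors
  (day 10–15 rate ≈ 5.3 mm³/day; final diameter < 10 mm);
* γ_p = 0.06 and K_int^T = 5e-15 m²/(Pa·s) — so the peak averaged IFV
  roughly doubles from 10 nm to 150 nm pores while transport stays
  diffusion-dominated;
* k_off = 0.05 s⁻¹ with δ_d = 1/day and c̄_i = 0.05 — so the
  internalisation-versus-washout competition discriminates the affinity
  extremes: at k_on = 0.005 s⁻¹ only a small fraction of the extravasated
  dose internalises before washing back out (regression weak and sensitive
  to timing and pore size), while at 5 s⁻¹ nearly all of it does
  (strong regression at every injection time, and a ≈15–40× contrast in
  peak tumour-targeted concentration);
* λ-index constants (offset 1.4, slope 4.0) — so the uniform baseline
  network scores ≈0.5.

## Problem sizes

Desk profile: 12³ elements, 420 segments, 6 h outer step, 40 simulated
days (~40 s per control run).  Reduced sweep profile: 10³ elements, 260
segments, 12 h outer step — used for the 2×2×3 injection matrix.
Paper-scale profile (15³ elements, 2,880 segments) is provided for
fidelity runs.

## What the synthetic setting does not show

The generator emulates only the statistical character (uniform density,
connectivity, radii) of the original unpublished network, not its layout;
absolute pressure/velocity magnitudes depend on the lumped γ_p and the
desk-scale segment count, so quantitative IFP/THP levels are indicative
only, and the cross-condition *orderings* are the meaningful outputs.
Known limitations carried over from the model class: constant blood
viscosity, deformation-independent hydraulic conductivity, no collagen
deposition, no lymph-angiogenesis or lymphatic mechanics, isotropic
growth, and a radially reduced solid solve that cannot represent strongly
asymmetric tumours.
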