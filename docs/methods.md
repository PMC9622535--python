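# Methods

This note records the model, the numerical choices, and what the test
problems do and do not establish.

## Physical model and assumptions

The simulator solves laminar incompressible flow of blood through a
cavopulmonary junction under the standard lean-CFD assumptions: rigid
vessel walls, spatially uniform ("plug") inlet velocity profiles
carrying prescribed flow rates, a shared zero-pressure reservoir (the
atrium) downstream of all outlets, and no turbulence model. Inlet
Reynolds numbers are computed as Re = ρUD/η(8U/D) — the Carreau
viscosity evaluated at the Poiseuille wall shear rate — and reported so
users can judge the laminar assumption; a warning is raised above
Re ≈ 2000. Typical Fontan/Glenn junctions run at Re 200–900.

Blood follows the Carreau law with defaults η₀ = 0.033 Pa·s,
η∞ = 0.006109 Pa·s, λ = 3.34 s, n = 0.3035, ρ = 1060 kg·m⁻³. The local
shear-rate magnitude is the second invariant γ̇ = √(2 D:D) of the
discrete strain-rate tensor, evaluated at cell centers; η₀ = η∞
reduces every downstream solve to the Newtonian case bit-for-bit in
the viscosity field.

Each outlet lumps its pulmonary vascular bed into a linear resistance
satisfying Δp = R_eff·F. Aortopulmonary collateral flow is not added
as a source; it scales the resistance through k = (pulmonary vein
flow)/(pulmonary artery flow), R_eff = R·k. This proxy reproduces flow
splits but, by construction, not absolute pressures.

## Geometry and meshing

Junctions are unions of capped cylinders. Voxelization is stair-step:
a cell is fluid iff its center lies strictly inside the solid (ties
resolve to solid, except on the anchor disc of a limb — always
interior to the junction — where an epsilon resolves inward; without
it, lattice-aligned cell centers on that plane would carve a spurious
solid sheet). The grid origin is registered to a multiple of Δx so
that the symmetry planes of centered geometries coincide with face
planes; with limb axes through cell centers instead, lattice points
fall exactly on the cylinder surface and the tie rule systematically
shrinks the cross-section by several percent. Axis-aligned limb caps
are snapped outward to the nearest face plane, making every port an
exactly planar disc of boundary faces with area (face count)·Δx².

The recommended spacing is 10 % of the IVC (or first-inlet) diameter —
the lean-mesh operating point; spacings coarser than 1/5 of the
thinnest limb diameter are refused. Voxel volume and port areas
converge to their analytic values at first order in Δx, with the
oscillatory quantization typical of lattice counting; the Poiseuille
benchmark therefore evaluates its analytic oracle with the effective
resolved-area diameter D_eff = 2√(A_voxel/π), isolating scheme error
from this quantization (which the geometry tests bound separately).

STL surfaces are triangulated from the signed-distance field by
marching cubes (the sampling lattice deliberately de-aligned from the
surface so no degenerate zero-crossing triangles break watertightness
after the float32 round trip) and containment of imported meshes uses
an even-odd vertical-ray parity test over the regular grid columns.

## Discretization

Finite volume on a staggered MAC grid: velocities on faces, pressure,
viscosity and scalar at cell centers. Time advance is an explicit
fractional step: upwind convection and central variable-viscosity
diffusion form a provisional velocity; an implicit Darcy drag realizes
the baffles; a pressure projection (7-point Poisson problem,
prefactorized sparse LU — the grid is static) restores
incompressibility to ~10⁻¹⁰ of the inlet flux scale per cell.

* **Convection** is first-order upwind in advective form, the
  advecting components averaged to the face being updated.
* **Diffusion** uses the simplified generalized-Newtonian stress
  div(η∇u): η at cell centers for the face-normal flux and averaged
  over the four adjacent fluid cells for the edge (tangential) fluxes.
  The transpose term ∂ⱼ(η ∂ᵢuⱼ) is omitted: with the projection
  enforcing ∇·u = 0 it vanishes identically for constant viscosity and
  contributes only O(∇η) corrections for Carreau flow. No-slip enters
  through antisymmetric mirror ghosts in the tangential directions
  (the wall plane lies halfway between the face and its solid
  neighbor); face-normal wall velocities are identically zero at the
  wall plane itself.
* **Porous baffles**: one face layer per outlet limb, one limb
  diameter upstream of the port, carries an implicit drag
  u ← u/(1 + Δt·β/ρ) with β = R_eff·A_layer/Δx, whose integral across
  the layer is exactly Δp = R_eff·F for a uniform layer velocity. The
  projection coefficient on those faces is scaled by the same factor so
  the steady momentum balance reduces to the lumped law; the measured
  area-averaged pressure jump across the layer matches R_eff·F to a
  few tenths of a percent. Outlet ports themselves are open faces with
  Dirichlet p = 0 (half-cell stencil) and zero-gradient provisional
  velocity, so global mass balance emerges from the projection rather
  than being imposed.
* **Time step**: Δt = cfl·min(Δx/u_max, ρΔx²/(12 η₀)); the viscous
  constant 12 (vs the nominal 6 of the 7-point Laplacian) covers the
  doubled tangential gradients of the mirror ghosts. Pulsatile runs
  use a fixed step T/steps_per_cycle, validated against this bound
  up front (a violation raises an error carrying the largest stable
  step); `steps_per_cycle: auto` selects the CFL-limited count capped
  at 4000. A runtime guard aborts if the realized CFL exceeds 2.

Steady solves are pseudo-transient from a quiescent state, driving the
time-averaged inlet flow, and declare convergence when the
continuity and velocity-scaled residuals (normalized by the inlet
velocity scale) fall below 10⁻⁵ *and* the monitored quantities (power
loss, outlet flows, pulmonary split) are flat to < 0.1 % over the
final 100 iterations. Pulsatile solves run a configured number of
cycles (defaults: 6 TCPC-like, 3 Glenn-like), report the final cycle,
and expose per-cycle %PFD/%HFD/Ė_loss histories plus a
cycle-periodicity metric (RMS velocity difference between the ends of
the last two cycles over the velocity scale; ~10⁻⁹ in the demos).

## Hepatic tracking

Hepatic blood is a passive scalar, c = 1 on the IVC inlet and 0 on the
others, advected by the same upwind scheme with no explicit
diffusivity (numerical diffusion only): hepatic streaming is
advection-dominated and the upwind scheme keeps c in [0, 1] by the
discrete maximum principle. Steady fields freeze the velocity and
march the scalar to a flux steady state; pulsatile runs advect it
inline and, alternatively, a snapshot-replay mode cycles the stored
final-cycle velocities. Hepatic outlet fluxes are cycle-averaged —
instantaneous values are phase-dependent and meaningless as budgets —
and balance the IVC inflow to well under 1 %.

## Metrics

Power loss integrates total pressure (static + dynamic) over the
discrete port patches, the outlet side evaluated at the zero-pressure
port downstream of the baffle, so baffle dissipation is included in
Ė_loss. Pressure is taken from the port-adjacent cell and the kinetic
term uses the full velocity magnitude at the face. Consequently the
demo-case Ė_loss is dominated by the transpulmonary term R_eff·F² (tens
of mW at physiologic R), not by the junction loss alone.

Wall shear stress uses surface-normal probe sampling: each stair-step
wall face is projected onto the true surface along the
signed-distance-field normal, the wall-tangential speed is
interpolated (trilinear, solid cells excluded) at heights 2Δx and 4Δx
along that normal, and τ_w = η·(slope at 0 of the quadratic through
the origin and both probes). A naive one-sided stencil from the
wall-adjacent cell center has unbounded relative error when that
center sits arbitrarily close to the surface and biased the mean by
tens of percent; the probe estimator lands within a few percent of
8μU/D on the benchmark tube and stays first-order on stair
boundaries. Imported STL grids (no analytic SDF) fall back to the
one-sided stencil over Δx/2. Wall face areas are Δx² per exposed face
(first-order; the stair area of a cylinder exceeds the true lateral
area by ≈ 4/π, which cancels in area-*fractions* such as the low-WSS
area). TAWSS is the trapezoidal time average of |τ_w| over one period
with periodic closure. The low-WSS area fraction (threshold 0.4 Pa,
configurable) accepts WSS or TAWSS.

The weighted pulsatility index normalizes its weights,
C_i = Q_i/ΣQ_i, which guarantees that identical per-vessel PIs
aggregate to that PI; the raw convention C_i = Q_i/mean(Q) is also
reported. By default the wPI covers the prescribed inlet waveforms.

## Synthetic inputs

The waveform generator emulates venous Fontan/Glenn physiology:
biphasic shapes from 2–3 low harmonics (relative amplitudes
1 : 0.45 : 0.2), seed-controlled phases, scaled so the computed
pulsatility index hits its target exactly while the mean is preserved
to machine precision; targets above 100 % are refused (the venous flow
would reverse in mean-relative terms beyond the physiologic regime).
Demo cases use BSA-indexed mean flows around the clinical ranges
(Glenn: SVC 1.5 L·min⁻¹·m⁻² at BSA 0.56 m²; TCPC: IVC 1.2 and SVC
0.82 L·min⁻¹·m⁻² at BSA 1.1 m²), pulsatility near 46–48 %, cycle
lengths 0.55–0.6 s, per-lung resistances 2.4·10⁷ Pa·s·m⁻³ (≈ 3 Wood
units) and k = 1.2 — a transpulmonary gradient of a few mmHg.

What the fixtures do *not* emulate: patient-specific curved
anastomoses (limbs are straight cylinders), MRI segmentation noise,
respiratory variation, vessel compliance, or measured waveform
morphology beyond its first harmonics. Passing tests therefore
demonstrate correctness of the solver and metric pipeline on idealized
junctions in the physiologic parameter range — not clinical accuracy
for any patient.

## Verification problems and their scales

* Poiseuille tube, Re 50, Newtonian, Δx = D/10 (refinement ladder D/5,
  D/8, D/12): velocity-profile RMS error ≈ 1.4 %, pressure-gradient and
  wall-shear errors ≈ 2–3 % against the D_eff oracle; the profile error
  decreases monotonically over the ladder, while the signed dp and τ
  errors cross zero between levels and so are bounded rather than
  ordered.
* Mirror-symmetric TCPC cross at Δx = D/6 (~2100 fluid cells):
  pulmonary and hepatic splits 50.000 %, mass imbalance ~10⁻¹⁵.
* Two-resistor divider limit (baffle drop ≈ 10× junction loss):
  computed splits within 1.5 pp of R_right/(R_left+R_right); scaling k
  is bit-identical to scaling R.
* Energy bookkeeping at Re 15: the baffle raises Ė_loss by R_eff·Q²
  to within 3 %; entrance and kinetic-flux corrections at this Reynolds
  number stay within the tolerance.
* Steady vs pulsatile on the cross: a constant waveform reproduces
  steady metrics to ~10⁻⁴ pp; across wPI = 10/40/70 % the
  |Δ%HFD| and relative Ė_loss differences grow monotonically
  (0.006 → 0.4 pp and 0.4 → 21 % respectively at suite scale).
* Cross refinement is run as Δx = D/6 vs D/10 (a scaled-down pair
  chosen for the one-CPU budget; the finer D/15 level would dominate
  it): %PFD changes 0.24 pp, Ė_loss 2.1 %.
* Low-Womersley oscillatory tube (α² ≈ 1.3): the normalized centerline
  amplitude tracks quasi-steady Poiseuille within 5 %.

Problem sizes throughout (10³–10⁴ fluid cells, 3–6 cycles, a few
hundred steps per cycle) are chosen so the full suite and the
acceptance script each run in minutes on one CPU; every tolerance
above was met at those sizes, and refining toward the recommended 10 %
mesh only tightens the flow-split and energy numbers, as the
refinement pair shows.

## Known limitations

Stair-step boundaries make wall quantities first-order; absolute
pressures are gauge values against the atrial reference and carry no
clinical meaning (the resistance proxy is calibrated for splits, not
pressures); the simplified stress form drops an O(∇η) term for
shear-thinning flow; hepatic transport has no molecular diffusivity,
so its effective mixing is resolution-dependent; the solver is
explicit, so very fine grids need proportionally many steps; no
fluid–structure interaction, exercise states, or Windkessel/closed-loop
circulation models.
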