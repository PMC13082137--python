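# Methods

This note documents the model equations as implemented, the numerical
choices, the parameters that matter, what the desk-scale fixtures do and
do not probe, and the known limitations.

## Geometry and units

All internal arithmetic uses µm, s, nM for fluid concentrations and
fmol/cm² for surface densities (1 M ≡ 1 fmol/µm³, which makes the
conversions exact scale factors).  The channel is a rectangle with the
origin at the bottom-left inlet corner; fields are cell-centred on a
uniform Cartesian grid of spacing h.

The platelet plug is a half-ellipse of semi-axes (a, b) resting on the
bottom wall, filled with disks of diameter d = 2.46 µm on a triangular
lattice of constant d + g, rows parallel to the wall, bottom row at
y = clearance + d/2 (clearance 0.5 µm).  A disk is kept iff its centre
lies inside the ellipse shrunk by one radius per semi-axis — a
conservative "whole disk inside the outline" rule.  The packing is
deterministic; for the full-scale configurations (a = 27, b = 17 µm;
g = 0.1/0.5/1.0 µm) it yields 112/79/59 platelets, within 10% of the
published 114/79/63 (the published packing protocol is not available,
so exact counts are not reproducible).

Rasterization marks a cell solid iff its centre falls inside a disk.
Platelet interface elements are the fluid/solid cell faces; each
carries an effective length h·|n̂_disk·n̂_face| so that the summed
interface length of a disk converges to its true perimeter πd rather
than the 4d staircase limit — this matters because reactive surface
area scales every surface flux.  The SE (injured wall) is a 50-µm strip
of bottom-wall faces centred under the plug (scaled with the plug for
fixtures).

## Flow

Steady incompressible flow on a MAC staggered grid.  Within the plug
Re ≪ 1, so the default solve is the linear Stokes saddle system
(µ∇²u = ∇p, ∇·u = 0) assembled once and solved by sparse LU; the
divergence of the solution is at rounding level (enforced contract:
|div u| ≤ 1e−8·u_max/h per cell).  Boundary conditions: Dirichlet
parabolic inlet u(y) = γ̇y(H−y)/H (wall shear rate γ̇, maximum γ̇H/4),
zero-gradient outflow with zero outlet pressure ghost, no-slip walls
and platelet faces via ghost reflection of the tangential velocity.  A
Picard-iterated Navier–Stokes mode exists for the open channel
(Re ~ 1); at these scales it changes the field by < 1%, and the Stokes
default keeps the operator linear in γ̇ (exploited by a linearity
test).  The channel height H = 72 µm is back-solved from the published
18 mm/s centreline maximum at γ̇ = 1000 s⁻¹ (u_max = γ̇H/4); the height
is otherwise unstated in the source material.

## Coagulation

Fluid species S1, E1, S2, E2 (nM) obey ∂c/∂t = −∇·(uc − D∇c) with a
single diffusivity D = 5×10⁻⁷ cm²/s.  Transport advances implicitly —
first-order upwind advection plus five-point diffusion folded into one
matrix (I/dt + A + D) factorized once per scenario, since the flow is
steady and D shared.  The implicit step removes the advective CFL
limit, which in 0.5-µm gaps under 1000 s⁻¹ shear would force
dt ≈ 3×10⁻⁵ s; the default dt = 0.02 s.  Inlet cells are pinned to
plasma values (substrates S1⁰ = 0.17 µM, S2⁰ = 1.4 µM; enzymes 0),
walls/outlet carry zero diffusive flux, upwind outflow at the outlet.

Surface chemistry lives on SE and platelet interface elements and
advances by forward Euler with 4 substeps per transport step (fastest
surface rate ~30 s⁻¹, so rate·dt_sub ≤ 0.15).  On the SE:
dC0b/dt = kC0⁺S1(E0 − C0b) − (kC0⁻ + kC0cat)C0b, with E1 released to
the fluid at kC0cat·C0b.  On platelets, six densities (S1b, E1b, S2b,
E2b, C1b, C2b) follow mass-action ODEs in which a complex occupies one
P1 and one P2 site, C1b catalysis releases E2b + E1b, and C2b catalysis
releases E1b + E2b.  Only the S1b equation is fully specified in the
source; the other five are reconstructed from the reaction scheme and
are each isolated in one code block for easy replacement.  Occupancy
bounds (P1, P2 sums never exceed N_i(t)) are asserted in tests.
Heterogeneous binding uses volumetric on-rates (M⁻¹s⁻¹ × fmol/cm² × M
is dimensionally a surface flux); surface–surface complex formation
uses the converted k_s = k_v·10⁻¹²·(S/V) rates with
S/V = 1.05×10⁴ cm⁻¹, the single factor that reproduces both published
surface rates from their volumetric counterparts to 1%.

The fluid↔surface exchange constants kS1±, kE1±, kS2±, kE2± are not
published; defaults are k_on = 10⁷ M⁻¹s⁻¹, k_off = 1 s⁻¹ (the order of
magnitude of the published complex rates) and are exposed in the
scenario configuration.

Boundary fluxes (fmol cm⁻² s⁻¹, positive into the fluid) become
volumetric sources via flux × face length × unit depth / cell volume
with unit depth 1 µm; this coupling conserves mass exactly (audited to
1e−6 in closed-box tests).  Fluid E2 decays by antithrombin as an exact
exponential factor e^(−k_AT·dt) per step.

## Fibrin polymerization

Monomer production is k_cat·E2·G/(K_m + G).  The G sink is applied
semi-implicitly and the removed fibrinogen is, by construction, exactly
the monomer source — so G(0) − G(t) = θ(t) holds to rounding in a
closed box.  Only G and c10 are transported (larger oligomers are
stationary); the moment state is stored as R̃ = R − 2c10 and
θ̃ = θ − c10, whose dynamics are purely local:

    dR̃/dt = −k_l R² − (k_b/2) R³ + 2(2k_l R + k_b R²) c10
    dθ̃/dt = (2k_l R + k_b R²) c10
    dB/dt  = (k_b/6) R³
    dY/dt  = k_l Y² + k_b R (R²/2 + RY + Y²)

with R = R̃ + 2c10.  Y is implemented as M02 − R with Y(x,0) = 0: for
purely linear polymerization every oligomer carries exactly two free
sites, so M02 = R and Y ≡ 0 — linear chains never gel — while Y
diverges exactly when the branching second moment does.  Gelation is
declared at the first time Y ≥ Y_max = 5000 nM; the cell's polymer
state then freezes bit-exactly and only monomer transport/production
continue there (the c10 polymerization sink carries the gel-indicator
Kronecker factor).

Reaction updates use an embedded adaptive substep inside each transport
step: the substep is bounded by 0.2 divided by the fastest local rate
(c10 sink, R decay, or relative Y growth), because Y grows
super-linearly approaching the gel point.  Recorded gel times are
interpolated within the crossing substep, giving dt-insensitive t_gel
well below the 0.1-s reporting resolution.

The independent oracle (`clotsim2d.oracle`) integrates the truncated
master equations for the full oligomer table c_mb (an m×b grid, default
200×30), with linking at rate k_l per free-site pair and branching at
k_b per unordered site triple (1/6 symmetry factor), which recovers
dR/dt = −k_l R² − (k_b/2)R³ and dB/dt = (k_b/6)R³ exactly in the
well-mixed limit.  Moments obtained by direct summation agree with the
closed system to < 1% pre-gel on batch problems; truncation overflow is
tracked and bounded.

## Parameters

Stock values (units as published): D = 5×10⁻⁷ cm²/s; µ = 1.2 mPa·s;
ρ = 1.025 g/cm³; k_act = 0.05 s⁻¹ (95% of binding sites available by
60 s); N1 = 23.5, N2 = 17.4 fmol/cm² (2700 and 2000 copies on a
2.46-µm sphere); SE reaction 8.95×10⁶ M⁻¹s⁻¹ / 1 s⁻¹ / 1.15 s⁻¹;
prothrombinase 1.03×10⁸ M⁻¹s⁻¹ (1.08 cm² fmol⁻¹ s⁻¹ on-surface) /
1 s⁻¹ / 30 s⁻¹; tenase 1.73×10⁷ M⁻¹s⁻¹ (1.82×10⁻¹) / 1 s⁻¹ / 0.23 s⁻¹
(the volumetric tenase rate appears in two places in the source with
conflicting exponents; 1.73×10⁷ is adopted as the only value consistent
with the published surface rate under the common S/V factor);
k_AT = 0.0336 s⁻¹; k_l = 8.2×10⁵ M⁻¹s⁻¹; k_b = 1.5×10⁹ M⁻²s⁻¹;
k_cat = 84 s⁻¹; K_m = 7.2 µM; Y_max = 5000 nM; E0 = 0.02 fmol/cm²;
G⁰ = 5.88 µM.

## Desk-scale fixtures

The `mini-*` fixtures shrink the channel to 36×70 µm and the plug to
a = 14, b = 11 µm (26/20/18 platelets) with gaps 0.5/1.0/2.0 µm on an
h = 0.25 µm grid, 60-s horizon, dt = 0.02 s — sized so one coupled run
completes in ~2 minutes on a single CPU.  The gap triple cannot mirror
the full-scale 0.1/0.5/1.0 µm (a 0.1-µm gap requires h ≤ 0.05 µm, i.e.
>10⁶ cells); 0.5/1.0/2.0 preserves what the fixtures are meant to
probe: the monotone intraplug-velocity ordering (192/377/647 µm/s for
dense/medium/loose at γ̇ = 1000 s⁻¹), earlier thrombin onset and
earlier first gelation with denser packing (dense gels at 41 s, medium
at 60 s), wall-adjacent gel initiation, and shrinking gel area with
increasing shear (90.6/63.3/50.4 µm² at 60 s for γ̇ = 0/100/1000 s⁻¹).

What the fixtures do **not** reproduce: the transport-starved interior
of a 0.1-µm-gap plug.  At any desk-resolvable gap the plug stays
permeable enough that intraplug fibrinogen is continuously replenished
and thrombin stays ~100 nM rather than µM; consequently gelation always
initiates next to the injured wall, and the full-scale phenomenon of
periphery-first gelation in densely packed plugs is out of reach of the
fixtures (it requires the full-resolution geometry, which ships as a
long-running stock scenario).  Passing fixture tests therefore
demonstrate the couplings and orderings, not the dense-core transport
limitation itself.

The fixture generator is deterministic end to end — packing, flow,
chemistry and output involve no random numbers, and repeated runs are
byte-identical.

## Numerical notes and degenerate inputs

* Implicit upwind transport is an M-matrix: positivity-preserving at
  any dt; explicit surface/volume coupling restricts dt only through
  accuracy (sink fractions ≤ ~20% per step at defaults).
* An empty plug (ellipse smaller than one platelet) degenerates to an
  open channel with a warning; a plug blocking the full channel raises
  before the flow solve (no fluid path).
* A grid that does not resolve the interplatelet gap with ≥ 2 cells
  triggers a warning, not an error: the flow then under-resolves gap
  jets and intraplug velocities are only indicative.
* γ̇ = 0 short-circuits the solver to the exact zero field.
* First-order upwinding is diffusive at coarse h; the published
  second-order scheme was deliberately not replicated — robustness on
  desk grids was preferred, and the transport-rate diagnostics use the
  same stencils as the solver for internal consistency.

## Known limitations

Platelets are rigid, stationary, pre-adhered disks; no deposition,
contraction, or mechanical bonds.  The gel does not feed back on flow
or solutes (no Darcy resistance, no thrombin–fibrin binding).  The
coagulation network is reduced (no TFPI/protein-C pathways, no
intrinsic pathway).  Surface species do not diffuse along membranes.
Activation clocks start at t = 0 for all platelets.  2D with unit
depth; quantitative totals are per-µm of vessel depth.
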