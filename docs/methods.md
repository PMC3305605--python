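# Methods

This note records the model equations as implemented, the parameter defaults
and where they come from, the numerical schemes, and the design choices made
where the design was genuinely open.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Vascular graph model

The non-capillary pulmonary vasculature is a graph: nodes at bifurcations
and vessel ends, edges as vessel segments with a mean diameter `d`, length
`l` and Strahler order.  Per node `i` the incompressible continuity equation

    Σ_j Q_ij + q_i/ρ = 0,   Q_ij = (p_i − p_j + ρ g Δz_ij) / R_ij

is assembled into a sparse linear system (Dirichlet pressures at the
arterial and venous roots) and solved with a direct sparse LU; the
factorization is cached and reused across time steps because the coupling
sink `q_i` (nonzero only at upscaled nodes) enters the right-hand side only.
The balance is formulated volumetrically; mass and molar flows are `ρQ` and
`ϱ_mol Q`.  Nodal balances are verified to 1e-10 relative after every solve.

Resistance is Hagen–Poiseuille, `R = 8 μ l / (π (d/2)⁴)`.  The apparent
viscosity is `μ = μ_plasma · η_rel(H, d)` with the published in-vitro
relative-viscosity relation (relative viscosity at H = 0.45 and shape
exponent C as closed-form functions of diameter in µm) and a
diameter → discharge-hematocrit lookup table (piecewise linear, constant
extrapolation).  The shipped table is a synthetic representative of in-vivo
microvessel hematocrit reduction at small diameters (0.12 at 8 µm rising to
the systemic 0.45 at ≥100 µm) and is overridable in the `blood:` config
section.  With plasma viscosity 1.2 mPa·s the law gives 1.52 mPa·s at
d = 8 µm, H = 0.45; the capillary continuum instead uses the registry's
constant 2.1 mPa·s (see §6 Limitations).

Node volumes are half the volume of the incident edges,
`V_i = Σ A_ij l_ij / 2`.  Two optional features, both disabled in the
example scenario, are gravity (head correction `ρ g z_i` per node from the
node's signed distance to the pulmonary-artery entry) and cross-sectional
compliance (`A(p) = A_ref + C (p − p_ref)`, floored at 10 % of `A_ref`,
applied through a fixed-point iteration area → resistance → pressure with
relative tolerance 1e-8, at most 50 iterations).

Drug transport on the graph is explicit Euler with first-order upwinding:

    x_i' = x_i + (Δt/V_i)[Σ Q_in x_upstream − Σ Q_out x_i] − Δt k x_i
           − Δt q_x,i/(ϱ_mol V_i)

with degradation `k = ln 2 / t_half` and the time step bounded by the CFL
condition `Δt ≤ C · min_i V_i / (outflow of i)` (default Courant number
0.9).  A Dirichlet boundary node whose edges deliver net inflow sheds that
excess out of the system (venous drainage towards the heart); the drug
carried along is accumulated as effluent.  Moles added at the inlet
Dirichlet node (the bolus), degraded, shed as effluent, or clipped by the
non-negativity floor are all accumulated, so a discrete mole balance holds
to rounding per step.  The bolus is a constant inlet mole fraction (default
1e-6, a required config value since no registry value is available) held
for a configurable duration (default: continuous).

### Tree generation

The example network generator builds a dichotomous tree from Strahler order
4 down to order 1 with per-order diameters and lengths from the printed
human pulmonary arterial and venous morphometry tables.  A strict halving
tree cannot produce 21 order-1 terminals, and the printed figure does not
state its branching rule, so the generator uses a deterministic
Strahler-consistent recursion: balanced (n−1, n−1) splits where feasible,
and order-2 vessels with more than two terminals continue as chains
shedding order-1 side branches (an order-n vessel meeting a lower order
keeps n).  `n_leaves` is a parameter defaulting to 21.  Generated labels
are idempotent under the independent Strahler relabeling operation.  The
three tumorous alveoli default to indices {4, 10, 16} (spread across the
row; the printed layout is not recoverable).  Each order-1 arteriole and
venule connects through an "upscaled edge" to its alveolus' upscaled node;
upscaled edges carry order-1 geometry for volume bookkeeping while their
hydraulic role is replaced by the effective alveolus resistance (§4).

## 2. REV permeability upscaling

The alveolar capillary bed is generated as a planar honeycomb lattice
(edge length 10 µm, vessel diameter 8 µm) in the mid-plane of a
364 × 364 × 112 µm cuboid, clipped at the lateral faces with boundary
nodes placed exactly on the faces.  Geometry bounds the achievable segment
count: the honeycomb edge-length density is `2/(√3 a)` per unit area, i.e.
at most ≈1550 segments of 10 µm in the printed extent, so the requested
1800 (a whole-alveolus morphometric count) is honoured within a documented
20 % tolerance and the exact count (1591 with defaults) is reported in the
bed's metadata.  Interior vertices have degree 3; row orientation
(armchair rows along x) is a config option.

The directional permeability of the cuboid follows the network-flow
procedure: Dirichlet pressures `p_hi`/`p_lo` (arbitrary; linearity is
verified) on all vessel endpoints within 1 nm of the two faces normal to
the probed axis, no-flow on the remaining four faces, solve the capillary
network with the graph flow solver at the constant capillary viscosity, and

    K_axis = Q μ L_axis / (A_axis Δp)

with `A_axis` the cuboid cross-section normal to the axis.  Components of
the clipped lattice not connected to any Dirichlet node are excluded from
the solve.  A planar bed has no endpoint on the z faces, so `K_zz = 0`
exactly.  The cuboid tensor is mapped onto the spherical shell by the
rotation taking the cuboid z-axis onto the local outward normal,
`K' = R K Rᵀ`, which leaves zero radial permeability.  Because the
azimuthal orientation of the bed on a sphere is undefined (and the two
in-plane principal values differ by only ~2 % for the generated lattice),
the face-normal tangential permeability uses the mean of `K_xx` and
`K_yy`.

Auxiliary closed forms: tumor capillary-bed permeability `K = r²/8`
(Poiseuille–Darcy comparison, isotropic, r = 10 µm default), drug
diffusivity `D = k_B T/(6π μ r_mol)` (T = 310.15 K, r_mol = 3.7 nm), and
the capillary surface density of the shell,
`S/V = N·2π r_cap L_cap / ((4/3)π(R_out³ − R_in³))` ≈ 1.9e4 m⁻¹.

## 3. Alveolus double-continuum model

Domain: spherical shell with R_in = 70 µm, R_out = 182 µm (healthy) or
sphere with R_out = 182 µm (tumor).  The mesh is a structured spherical
(r, θ, φ) grid with exact cell volumes and face areas; θ faces at the poles
have zero area (natural no-flow), φ is periodic, and the φ grid is offset
half a cell so cell centers lie on the ±x axis.  Cells whose centroid
direction is within the cap half-angle (default 30°) of −x/+x form the
arterial/venous caps.  Default resolution (n_r, n_θ, n_φ) = (3, 4, 8)
(96 cells) — the working resolution of the example runs, chosen coarse
deliberately; a refinement doubling every direction changes the steady
volume-averaged pressures by <0.1 % (asserted ≤2 % in the tests).

Per cell the unknowns are `p_t, p_c, x_t, x_c` (+ `C_RL` in tumor tissue).
Fluxes use a two-point approximation with face-normal permeabilities
(tissue: isotropic `K_t`; capillary: `K_zz` across radial faces — zero for
the healthy shell — and the tangential mean otherwise) and full upwinding
of advection.  The discrete residuals per cell (molar rates, transfer terms
per unit domain volume, positive capillary → tissue):

- tissue continuity: `ε_t ϱ_t Σ_f F_t + V(q_ly − q_v) = 0`
- capillary continuity: `ε_c ϱ_c Σ_f F_c + V q_v = 0`
- tissue transport: storage `(V/Δt) ε_t φ ϱ_t Δx_t` + upwinded advection +
  diffusion with `D_eff = φ τ D` (τ < 1 multiplicative) + lymph drug sink +
  receptor sink − `V q_x`
- capillary transport: storage + advection + diffusion (porosity and
  tortuosity one) + degradation `V ε_c ϱ_c k x_c` + `V q_x`
- receptor complex (tumor): `V ε_t [(ΔC_RL/Δt) − (k_on c C_R − k_off C_RL)]`
  with `c = x_t ϱ_t` and `C_R = C_R0 − C_RL` (receptor conservation exact).

Transfer functions: effective filtration pressure
`p_eff = (p_c − p_t) − σ(π_c − π_t)`; Starling `J_v = L_p (S/V) p_eff`
(molar rate `J_v ϱ_tr`); Kedem–Katchalsky
`q_x = P (S/V) ϱ_tr (x_c − x_t) + (1 − σ_f) J_v ϱ_tr x̄` with the
arithmetic-mean `x̄ = (x_c + x_t)/2` (replacing the logarithmic mean, which
is singular at `x_c = x_t`).  `ϱ_tr` is the arithmetic mean of the two
fluids' molar densities.  The lymphatic sink
`L_p,ly (S_ly/V) max(p_t − p_ly, 0) ϱ_t` (drug: × `x_t`) acts in healthy
tissue only and is clamped so no reverse lymph flow occurs (a config switch
allows the unclamped linear form); receptor binding acts in tumor tissue
only.  Transfer terms enter the two continua with equal magnitude and
opposite sign, so per-node drug bookkeeping closes exactly at the Newton
tolerance — the test suite asserts this per step and globally.

Boundary conditions: capillary continuum — Dirichlet `p_c`, `x_c` on the
cap cells (values copied from the adjacent graph nodes); no-flow elsewhere
(blood cannot leave the alveolus any other way).  Tissue continuum —
Dirichlet pressure on the outer boundary (−1064 Pa healthy, 133 Pa tumor)
applied through boundary-face transmissibilities, advective drug outflow
where fluid leaves (inflow carries zero drug), no diffusive drug flux.
Inner shell surface (alveolar lumen): no-flow for both continua.  Gravity
is neglected inside the 0.4 mm domain.

A design decision with visible consequences: the capillary continuum
occupies the whole model domain with the registry's domain-wide volume
fractions (ε_c = 0.1/0.2) and the Eq.-(S/V) domain average, rather than
being restricted to a thin vascularized layer.  The capillary localization
enters through the permeability tensor instead: its zero radial component
confines capillary flow to spherical surfaces.  This matches a registry
that states domain-wide fractions and keeps the pressure field defined on
the full cross-section; the alternative (single-layer restriction) would
double-book volume against the domain-wide fractions.

### Time integration and Newton solver

Implicit Euler, fully coupled.  Each step solves the nonlinear residual
with Newton:

- The non-smooth upwind switch never enters the Jacobian: each Newton
  sweep freezes the upwind directions at the current iterate's pressures,
  solves the (smooth) frozen problem, and repeats the sweep if the
  converged state implies different directions (at most 4 sweeps; in
  practice directions settle after the first).
- The Jacobian is a forward-difference approximation assembled by
  distance-2 graph coloring of the cell adjacency (one residual evaluation
  per color and variable, ~50 evaluations), equilibrated with per-row and
  per-variable scales, and factorized with sparse LU.  The factorization is
  cached across steps and across alveoli of the same kind (modified
  Newton); it is rebuilt whenever the residual norm fails to drop by ×5 in
  an iteration or a line search stalls (at most 6 rebuilds per step).
- Convergence: scaled residual ∞-norm ≤ 1e-8, with per-equation scales
  built from transmissibility sums, storage terms and transfer
  coefficients.  A backtracking line search (up to 6 halvings) guards each
  update.  On Newton failure the step is halved and retried, up to 5
  halvings, with the exchange ledger accumulated over the actual substeps.

The one-step self-difference `‖u(Δt) − u(Δt/2, twice)‖` contracts by ≥2×
when Δt is halved (consistent with the first-order scheme's O(Δt²) local
error), asserted in the tests.

## 4. Coupling

Each upscaled node holds its own DCM state; the solver object (mesh,
parameters, cached Jacobian) is shared per kind.  Sequence per graph step:
(1) graph pressures with the previous step's fluid sinks; (2) CFL time
step; (3) explicit drug advection with the previous step's drug sinks;
(4) per upscaled node: Dirichlet values from the adjacent arterial/venous
nodes, the capillary field restarted from the previous final state (first
step: linear profile in x between the caps, drug-free tissue), one implicit
DCM step over the graph Δt (sub-stepping configurable), and
volume-integration of the transfer rates at the end-of-step state (their
implicit-Euler values, so the ledger is discretely exact); (5) the
resulting rates are applied as graph sinks in the next step.  This lagged
(sequential) scheme keeps the graph system linear; refining the step 4×
changes the extracted-drug totals by <1 % (asserted).

The upscaled node's hydraulic footprint is an effective resistance
`R_eff = Δp/Q` from a capillary-continuum-only flow solve with unit
pressure difference across the caps, computed once per run (cached-static)
and split evenly over the node's two upscaled edges.  With default
parameters `R_eff(tumor) ≪ R_eff(healthy)` — the isotropic r²/8 tumor
permeability far exceeds the tangential-only healthy tensor — reproducing
the smaller pressure gradient across tumor-adjacent edges.

A global audit closes the drug bookkeeping: injected = in-graph + degraded
+ effluent + tissue + bound + lymph-cleared + tissue-boundary outflow +
the one-step in-flight lag of the sequential coupling, to well within
0.1 % in the default run.  The DCM capillary continuum itself is a local
mirror of blood already counted in the graph and is deliberately outside
the audit (its degradation is likewise local); only transvascular transfer
moves drug between the ledgers.

## 5. Parameters

All internal units SI; config keys carry unit suffixes.  Registry values
(healthy n / tumor t): tissue porosity 0.13/0.27, tissue fraction 0.9/0.8
(with ε_t + ε_c = 1), tortuosity 0.28/0.71, interstitial density
1030 kg/m³ and 303.5 mol/m³, capillary viscosity 2.1 mPa·s, blood density
1050 kg/m³ and 284 mol/m³, oncotic pressures π_c 3724/2660 Pa and π_t
1862/1995 Pa, σ = 0.8, σ_f 0.91/0.82, transfer molar density 293.75
(arithmetic mean), interstitial pressure BC −1064/133 Pa, lymphatic
S_ly/V = 3 m⁻¹ and p_ly = −1200 Pa, drug half-life 21600 s, molecular
radius 3.7 nm, body temperature 310.15 K.

Values without a usable registry entry are required config fields shipped
with mid-range literature defaults for macromolecular transport and
annotated in `data/default_scenario.yaml`: tissue permeability
K_t = 5e-18/4e-17 m²; wall hydraulic conductivity
L_p = 2.7e-12/2.1e-11 m/(Pa·s); wall diffusive permeability
P = 5e-9/5e-8 m/s; lymphatic wall conductivity 2.6e-9 m/(Pa·s); receptor
parameters C_R0 = 1e-5 mol/m³, k_on = 100 m³/(mol·s), k_off = 1e-4 s⁻¹
(nanomolar-affinity antibody-fragment kinetics at plausible receptor
density); inlet mole fraction 1e-6.  The healthy P default is chosen so the
wall-transfer time scale `P·S/V ≈ 1e-4 s⁻¹` leaves the tissue drug level
two to three orders of magnitude below the capillary level on the ~10 s
horizon of the example run, consistent with the qualitative behaviour the
scenario is meant to demonstrate.  The default simulated horizon is 11 s
(the example's drug-distribution snapshot time); the run costs seconds on
one CPU at the default resolution.

## 6. What the synthetic scenario does and does not emulate

The generated network reproduces counts, orders and per-order morphometry
— not the anatomy of a lung: the graph is planar, gravity and compliance
are off, flow is steady (no cardiac pulsatility), and hematocrit is not
phase-separated at bifurcations.  The honeycomb bed is an idealized planar
lattice, not an image-derived capillary network; its in-plane anisotropy
(~2 %) is a property of this lattice and clipping, so the two in-plane
permeabilities should not be read as physiological.  The tumor is three
relabeled alveoli with altered parameters — no angiogenesis, growth,
necrosis, or moving boundaries.  Tests passing on this scenario establish
internal consistency (conservation, convergence orders, parameter-driven
contrasts between healthy and tumorous alveoli), not predictive accuracy
for real lungs; the registry's constant capillary viscosity 2.1 mPa·s is
likewise adopted as stated even though the in-vitro viscosity law gives
~1.5 mPa·s at 8 µm and H = 0.45.

## 7. Known limitations

- Two-point flux approximation on the spherical grid is exact for radial
  and axisymmetric fields but only first-order accurate for skewed flow;
  the coarse default resolution is for demonstration, not grid-converged
  fields.
- The effective alveolus resistance is static per run; a pressure-dependent
  recomputation is a config hook but off by default.
- The receptor complex is bounded in [0, C_R0] by the dynamics, not by an
  explicit constraint; extreme parameter choices could transiently
  overshoot within Newton tolerance.
- Strong (within-step iterated) VGM↔DCM coupling is not implemented; the
  lagged scheme's first-order-in-Δt coupling error is monitored by the
  step-refinement test.
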