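# Methods

## Model

`qsbiofilm` simulates quorum-sensing (QS) induced dispersal of a growing
biofilm in a 2D hydrostatic domain Ω = [0, L] × [0, H]. Four fields are
evolved:

* `M(t, x)` — sessile biomass as a volume fraction in [0, 1) (EPS subsumed),
* `N(t, x)` — dispersed (motile) biomass, carried on the same
  volume-fraction scale (mass density `N·M∞`),
* `C(t, x)` — growth-limiting nutrient, g/m³,
* `A(t, x)` — autoinducer (QS signal, e.g. AHL), nM.

The governing equations are

    ∂t M = ∇·(D_M(M) ∇M) + μ C/(k₁+C) M − k₄ M − η₁ f(A) M + η₂ g(M) N
    ∂t N = ∇·(d_N(M) ∇N) + μ C/(k₁+C) N − k₄ N + η₁ f(A) M − η₂ g(M) N
    ∂t C = ∇·(d_C(M) ∇C) − (μ/Y) M∞ C/(k₁+C) (M + N)
    ∂t A = ∇·(d_A(M) ∇A) + γ(C) [α + β f(A)] M∞ (M + N)

with the Hill switch `f(A) = Aⁿ/(τⁿ + Aⁿ)` (induction threshold τ, exponent
n = 2.5), the saturating re-attachment factor `g(M) = M/(k₅ + M)`, Monod
growth, first-order lysis `k₄`, and the degenerate–singular biomass motility

    D_M(M) = δ Mᵃ (1 − M)⁻ᵇ ,   a, b > 1, δ > 0 .

`D_M(0) = 0` gives porous-medium behaviour — sharp biofilm/water interfaces
moving at finite speed — while the blow-up at M → 1 acts as a density cap.
Solute and dispersed-cell diffusivities interpolate linearly between their
water (M = 0) and fully developed biofilm (M = 1) values; γ(C) ≡ 1 by
default (a user hook is provided for nutrient-modulated signal production).

Boundary conditions: homogeneous Neumann on the substratum (bottom) and the
lateral symmetry boundaries for all fields; at the top (bulk interface)
C = C∞, N = A = 0 (instantaneous dilution into the bulk), and a no-flux
closure for M, valid because runs terminate before biomass reaches the top.
Initially C = C∞ and N = A = 0 everywhere, with M > 0 only in seeded
pockets on the substratum.

Setting α = β = 0 (no signal) or η₁ = 0 (no dispersal) reduces the system
to the prototype single-species, single-substrate biofilm growth model.

## Parameter choices that need explanation

* **Units of α, β.** The parameter table prints 0.5520 and 5.5200 with unit
  d⁻¹, but dimensional consistency of the A equation against the
  `M∞ (M + N)` factor requires nM·m³/(g·d); the package adopts those
  numeric values in the latter unit.
* **Scale of k₅ (re-attachment half-saturation).** k₅ = 0.7 is printed in
  g/m³ while `g(·)` is evaluated on the biomass field. Read on the mass
  scale (comparing `M·M∞ ≈ 10⁴·M` with 0.7) the factor is saturated in any
  biofilm with M ≳ 10⁻⁴ and a k₅ sweep over 0.1–0.7 is inert; dispersed
  cells then re-attach measurably onto vanishing traces of biomass, which
  in simulations grows a spurious low-density lawn across the substratum.
  The package therefore reads k₅ on the volume-fraction scale
  (half-saturation at M = k₅), which keeps the biofilm region sharp and
  makes the k₅ sweep meaningful; the density-scale reading stays available
  via `k5_scale="density"`.
* **Bulk nutrient C∞** is not part of the published table. Through the
  nutrient-limited biomass ceiling it controls — via signal production —
  which induction thresholds τ can be crossed at all: the ceiling biomass
  M_tot^max scales like Y·d_C·C∞·L/(H·M∞·k₄) and the attainable signal
  like (α+βf)·M∞·M_tot·H/(L·d_A). The default C∞ = 25 g/m³ was fixed once
  so that the whole τ = 10–70 nM window is crossable within the 20 d
  horizon (at ≤ 15 g/m³ the 60–70 nM thresholds are never reached; the
  biomass-loss figure for τ = 70 then reflects lysis only).
* **η₂ = 0.5·η₁** unless overridden; τ defaults to 50 nM and η₁ to 3.6/d
  (the experiments override both).
* **Inoculum.** Six half-disc colonies of density 0.3 seeded on the
  substratum; radii drawn uniformly from 50–100 µm. Larger inocula put the
  domain-average signal near the low thresholds essentially immediately,
  collapsing the maturation phase; the default sizes reproduce an induction
  onset around t ≈ 1–5 d depending on τ. Pockets smaller than one grid cell
  seed the cell under their center, so no colony is lost at coarse
  resolution. Locations and sizes are drawn from a seeded RNG; a run is
  bit-reproducible given (config, seed).

## Discretization

Cell-centered finite volumes on a regular nx × ny grid (cells of size
hx × hy, centers at ((i+½)hx, (j+½)hy)). All four diffusion operators are
five-point stencils, symmetric and conservative, with boundary conditions
folded into matrix and right-hand side (Dirichlet via ghost values at half
a cell: flux = d·(u_bc − u_cell)/(h/2)).

**Face coefficients.** Solute laws are linear in M, so the arithmetic mean
of the two adjacent cell diffusivities is also the exact integral mean. The
biomass equation uses the Kirchhoff form: the face coefficient is the
secant slope `(Φ(M_R) − Φ(M_L))/(M_R − M_L)` of the flux potential
`Φ(M) = ∫₀^M D_M`, evaluated from a cached 4097-node table. This is the
canonical discretization for porous-medium-type fluxes: it reproduces the
degenerate front speed, whereas an arithmetic mean of D overestimates the
flux through the front by an order of magnitude (and, with growth
amplifying the leaked tail, creeps a spurious biomass lawn along the
substratum), and evaluating D at the mean of the M values blocks both the
front and the singular density cap at a sharp interface.

**Singularity guard.** Inside D_M (and Φ) the density argument is capped at
`m_cap = 0.99`. With δ = 10⁻¹², a = b = 4 this bounds D_M by ≈ 10⁻⁴ m²/d —
the solute-diffusivity scale, which already levels any overshoot across a
cell in far less than one time step — while a cap of 1 − 10⁻⁶ would admit
D_M ≈ 10¹² m²/d and make the implicit biomass solve singular to machine
precision. The solver rejects any step in which max M would still reach 1.

**Time stepping.** Semi-implicit, fixed dt (default 10⁻³ d), four linear
solves per step in the order C, A, M, N:

* diffusion implicit, with diffusivities frozen at the old M;
* sinks linear in the solved field implicit: nutrient consumption
  (linearized with the Monod denominator at the old C), lysis, and the
  dispersal sink η₁ f(A_new) M;
* cross-field sources explicit: growth (with the just-solved C), signal
  production (with f(A_old)), the dispersal source into N (using the
  just-solved M, so the exchange cancels identically), and the
  re-attachment exchange η₂ g(M_old) N_old on *both* sides — source into M
  and sink from N — so that it, too, cancels identically in the M+N budget.

This split preserves 0 ≤ M < 1, N ≥ 0, A ≥ 0 and 0 ≤ C ≤ C∞ without
nonlinear iteration; the explicit re-attachment sink requires dt < 1/η₂,
checked up front (three orders of magnitude of slack at the defaults).
Each system is solved with BiCGStab to a relative residual of 10⁻¹⁰
(default), preconditioned by a complete sparse LU factorization that is
refreshed every 25 steps or whenever a solve needs more than 8 iterations —
the operators drift slowly, so a recent factorization keeps iteration
counts at a handful. On solver failure the step is retried as two half
steps (bounded recursion); negative solver noise (below 10⁻⁸ of the field
scale) is projected to zero and tracked.

**Accumulators.** The growth, lysis and top-boundary efflux actually
applied each step are accumulated with that step's dt, so the discrete
budget `Δ(M_tot + N_tot) = growth − lysis − P` closes to solver tolerance
(the tests require ≤ 10⁻⁶ relative over a full run; runs typically close
near 10⁻⁹). The sessile-only production integral `∫∫ μC/(k₁+C) M` feeding
the biomass-loss measure K(T) uses the same rule. K's integrand follows
the printed definition (sessile production only, excluding N's growth).

## Observables

Per sampling interval (default 0.05 d) the package records: relative
biofilm size ω (area of Ω₂ = {M > 10⁻³} over the domain area — a strict
floating-point {M > 0} is not robust), C_avg and A_avg over Ω₂ (A_avg in
units of τ; NaN markers when Ω₂ is empty or τ = 0), M_tot, N_tot, the
cumulative production/growth/lysis integrals, the cumulative top-boundary
efflux P, the biomass loss

    K(T) = [∫∫ μC/(k₁+C) M dx dt − (M_tot(T) − M₀)] / ∫∫ μC/(k₁+C) M dx dt ,

and the re-attachment-to-detachment ratio

    Z(t) = (η₂/η₁) ∫ g(M) N dx / ∫ f(A) M dx .

Z's printed denominator elsewhere appears as Aⁿ/(1+Aⁿ); the package uses
the same Hill form as the dynamics, Aⁿ/(τⁿ+Aⁿ), for dimensional
consistency with the dispersal term (the other variant is selectable).

**Event detection.** A dispersal event is a strict local maximum of the
sampled M_tot series followed, before the next maximum, by a relative drop
exceeding 10%. A series with no events is classified "plateau" when the
relative change over its final quarter is below 5%, else "growing".

**Hollowing.** Colonies are 4-connected components of Ω₂; each colony's
core (cells surviving two binary erosions, with the domain boundary not
counted as colony boundary) is compared with its rim band; `hollow` means
core mean < rim mean (with a 10⁻⁶ relative margin so uniform colonies are
never flagged). Colonies without a core (< 5×5 cells) report NaN.

## Verification

* Pointwise kinetics against hand-evaluated values and exchange/sign
  identities (property-tested over the full state space).
* Diffusion operators: symmetry, discrete conservation (all-Neumann row
  sums), positive semidefiniteness, the exact bulk steady state, and O(h²)
  convergence to the 1D quadratic profile under a uniform sink.
* The degenerate biomass solver against the Barenblatt self-similar
  solution of the porous medium equation (b = 0, reactions off): interface
  position within 2% and L1 profile error within 2% at 256 cells.
* Global M+N budget closure ≤ 10⁻⁶ relative over full dispersal runs;
  bounds preserved at every step; t_end = 0 and sterile-domain fixed
  points; dt-refinement consistency; η₁ → 0 continuity against a
  no-dispersal reference.

## Problem sizes

Acceptance-style simulations in the test suite run on a 64×32 grid over the
default 4 mm × 1.6 mm domain to t = 20 d (dt = 10⁻³ d); the acceptance
script runs the headline τ = 70 nM biomass-loss scenario at 128×64. The
preset runner defaults to 256×128 for production use. Grid, dt and horizon
are ordinary settings; all qualitative checks were verified at both 64×32
and 128×64.

## What the synthetic inoculum does and does not emulate

The generator reproduces the *kind* of initial data the model is posed
with — a few small, randomly placed, uniform-density colonies wetting the
substratum, bulk nutrient, no signal — not any measured colony geometry.
Real inocula have irregular shapes, heterogeneous density and possibly
surface conditioning films. Conclusions drawn from passing tests therefore
concern the model's mechanisms (threshold-controlled dispersal regimes,
hollowing, negligible re-attachment), not quantitative predictions for a
specific experimental system.

## Known limitations

* 2D only (the operators are dimension-agnostic in design, but no 3D
  assembly is provided).
* No bulk flow or shear detachment; the aqueous phase is hydrostatic.
* γ(C) forms beyond the constant and a user hook are reserved but not
  implemented (k₂, k₃, eps are carried in the parameter set for them).
* The semi-implicit scheme is first-order in time; statements about
  trajectories are made under dt-refinement checks, not error bounds.
* **Regime assignment across τ.** Both dispersal regimes are produced:
  stable continuous shedding with persistently hollow colony cores, and
  almost-periodic discrete events with post-event core refill. Because the
  signal field equilibrates with the biomass quasi-instantly
  (H²/d_A ≈ 0.03 d), the deciding quantity is where the ignition biomass
  for a given τ sits relative to the nutrient ceiling: thresholds crossed
  at small biomass (low τ at the default C∞) settle into the continuous
  state after a single ignition transient, while thresholds crossed near
  the ceiling (high τ) produce relaxation oscillations — events whose
  crashes undershoot the signal-sustain level. Descriptions of this model
  family associate the discrete-event phenotype with *low* thresholds and
  the continuous phenotype with *high* ones; reproducing that assignment
  would require a several-fold smaller signal-per-biomass coefficient than
  the stated production law and parameter values give, and no bulk
  nutrient level in 5–50 g/m³ changes the ordering. The package reports
  what the stated equations produce.
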