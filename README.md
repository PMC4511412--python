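# qsbiofilm

A 2D reaction–diffusion simulator of **quorum-sensing induced biofilm
dispersal**, for microbial ecologists and biofilm modellers who want to
study how a cell–cell signalling threshold turns colony growth into
discrete sloughing events or continuous shedding of cells.

## The model

Four coupled fields on Ω = [0, L] × [0, H] (substratum at the bottom, bulk
liquid above):

```
∂t M = ∇·(D_M(M) ∇M) + μ C/(k₁+C) M − k₄ M − η₁ f(A) M + η₂ g(M) N
∂t N = ∇·(d_N(M) ∇N) + μ C/(k₁+C) N − k₄ N + η₁ f(A) M − η₂ g(M) N
∂t C = ∇·(d_C(M) ∇C) − (μ/Y) M∞ C/(k₁+C) (M + N)
∂t A = ∇·(d_A(M) ∇A) + γ(C) [α + β f(A)] M∞ (M + N)
```

`M` is the sessile biomass volume fraction, `N` the dispersed-cell pool,
`C` the nutrient (g/m³) and `A` the autoinducer (nM). Dispersal switches on
through the Hill function `f(A) = Aⁿ/(τⁿ+Aⁿ)` as `A` approaches the
induction threshold τ; the same switch up-regulates signal production from
the constitutive rate α to α+β. Re-attachment saturates with the local
biofilm density, `g(M) = M/(k₅+M)`. Biomass motility
`D_M(M) = δ Mᵃ(1−M)⁻ᵇ` is degenerate at M = 0 (sharp fronts, finite
propagation speed) and singular at M = 1 (density cap).

The solver is a semi-implicit cell-centered finite-volume scheme: per time
step four sparse linear systems (one per field, order C, A, M, N) are
solved with LU-preconditioned BiCGStab; Kirchhoff integral-mean face
coefficients handle the degenerate–singular biomass flux. The scheme
preserves 0 ≤ M < 1, N, A ≥ 0, 0 ≤ C ≤ C∞ and closes the discrete
M+N mass budget to solver tolerance. See `docs/methods.md` for the
numerical details and parameter discussion.

## Worked example

Simulate six seeded colonies at a low induction threshold (τ = 20 nM) on a
coarse grid and count dispersal events:

```python
import qsbiofilm as qb

params = qb.default_parameters(tau=20.0, eta1=3.6)      # eta2 = 1.8/d
settings = qb.default_settings(nx=64, ny=32, t_end=20.0, seed=1)
grid = qb.Grid(nx=64, ny=32, L=params.L, H=params.H)
initial = qb.generate_inoculum(qb.InoculumSpec(n_colonies=6, density=0.3,
                                               seed=1), grid, params)
result = qb.run(initial, grid, params, settings)

last = result.timeseries.data.iloc[-1]
det = qb.dispersal_event_detector(result.timeseries["t"],
                                  result.timeseries["M_tot"])
print(f"K(T) = {last['K']:.3f}  omega = {last['omega']:.3f}  "
      f"events = {det.n_events} ({det.label})")
```

This prints (exact trailing digits depend on BLAS):

```
K(T) = 0.981  omega = 0.096  events = 1 (discrete)
```

meaning 98.1% of the sessile biomass produced over 20 days was lost from
the biofilm (dispersed into the bulk or lysed), the biofilm region covers
10% of the domain, and after an early sloughing event the colony settles
into continuous shedding. `result.timeseries.to_csv(...)` writes the full
observable record (ω, C_avg, M_tot, N_tot, A_avg, K, Z, P, …);
`qsbiofilm.write_fields` exports VTK snapshots readable by ParaView.

A command-line interface wraps the same machinery:

```sh
qsbiofilm run --config scenario.yaml --outdir out/      # single scenario
qsbiofilm preset tau_sweep --seed 1 --outdir sweeps/    # canonical experiments
qsbiofilm sweep --config scenario.yaml --key k5 --values 0.1,0.4,0.7
```

Presets cover the four canonical experiments: the τ sweep (7 thresholds +
non-QS control), constant dispersal (τ = 0) vs QS-induced (τ = 50 nM),
the four (τ, η₁) re-attachment corner scenarios plus the k₅ sweep, and the
hollowing pair (τ = 20 vs 60 nM on a shared inoculum).

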