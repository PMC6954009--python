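# Methods

## Model

The local dynamics are the classic harvested-resource balance

    f(N) = r N (1 − N/K) − c N² / (N² + H²),

logistic regrowth minus a sigmoidal (type III) harvest term. At the
standard parameters (r = 1 day⁻¹, K = 10 g m⁻², H = 1 g m⁻²) the model is
bistable for c between the two saddle-node folds, which `scan_folds`
locates at c ≈ 1.7872 and c ≈ 2.6044 g m⁻² day⁻¹. The dynamics are
gradient with potential V(N) = −∫₀ᴺ f(s) ds (closed form in
`local_model.potential`); the Maxwell point — equal depth of the two
wells, computed by bisection on ∫ f dN between the outer stable states —
sits at c ≈ 2.3487. Between the Maxwell point and the upper fold the
degraded state has the deeper well, which is why a sufficiently large
local pulse can nucleate a travelling front that collapses the entire
landscape before the fold itself is reached.

Two spatial embeddings carry these local dynamics:

* **Continuous**: method-of-lines reaction–diffusion on a square domain
  (default 100 m × 100 m on a 50 × 50 lattice, cell 2 m), 5-point
  Laplacian, dispersal as diffusion with D = 2.5 (low) or 12.5 (high)
  m² day⁻¹.
* **Patchy**: n = 100 well-mixed 1 m² patches on an Erdős–Rényi graph
  with edge probability 0.04, coupling d Σⱼ(Nⱼ − Nᵢ) over graph
  neighbours, d = 0.02 (low) or 0.1 (high) day⁻¹.

## Numerical choices

* **Boundaries**: zero-flux (mirror ghost cells), so the diffusion term
  conserves biomass exactly on the closed domain; periodic boundaries are
  available as an option for sensitivity checks.
* **Integrator**: scipy's adaptive embedded Runge–Kutta 4(5)
  (`solve_ivp`, RK45) with terminal events for recovery, collapse and
  steady state, so event times come from the solver's root finder rather
  than snapshot spacing. Defaults rtol 1e-8 / atol 1e-10: near an
  attractor the numerical residual floor is roughly rtol × the biomass
  scale, and these values keep that floor (~1e-7 g m⁻² day⁻¹) safely
  below the steady-state criterion; at rtol 1e-6 the steady-state event
  can never fire.
* **Steady state**: max-norm of the time derivative below
  ε = 1e-6 g m⁻² day⁻¹ (about 1e-5 of the scale of f over the bistable
  range). t_max = 10 000 days (≥10³ local timescales 1/r); runs still
  transient at t_max are flagged `unresolved` and excluded from
  statistics, never silently folded into another class.
* **Settling**: homogeneous landscapes are placed exactly on the upper
  root of f. Heterogeneous ones start from per-cell Newton estimates of
  the local high root and relax until the steady-state criterion is met;
  if the settled spatial mean has fallen below the basin boundary of the
  mean-r local model, no high-biomass attractor exists at that c and the
  level is recorded as `beyond_fold` (the analogue of the region past the
  fold in the homogeneous case, where the sweep has nothing to disturb).
* **Root finding**: equilibria from a 10⁴-point scan of [0, 1.5K]
  bracketing sign changes, refined by Brent's method to |f| < 1e-10;
  stability from the sign of f′, with |f′| < 1e-7 reported as "marginal"
  (exactly at a fold). Folds by bisection on the equilibrium-count
  transition (1e-6); Maxwell point by bisection in c with adaptive
  quadrature (1e-8).

## Disturbance protocol

Pulses zero biomass in a square whose side is the nearest whole-cell
rasterization of the requested area fraction (1 % → 10 m ≡ 5 × 5 cells;
5 % → ~22.4 m nominal ≡ 11 × 11 cells at the default lattice); the
*realized* rasterized area is the covariate A used downstream, not the
nominal fraction. Patchy pulses zero the focus patch (degree 4 in the
standardized protocol, matching the 5-patch variant that also zeroes all
four neighbours), or a uniformly random patch in the random campaign.
Recovery is first crossing of |N(t) − N(t₀)| < 0.1 g m⁻² at the monitored
site (center cell / focus patch / landscape mean for global pulses);
collapse requires the spatial mean to cross the mean-r basin boundary
*and* settle within 0.1 g m⁻² of the low state, because the mean can dip
transiently before a successful recovery. The affected-area metric is the
maximum over time of the area deviating ≥ 0.1 g m⁻² from the
pre-disturbance state.

## Experimental campaigns

Standardized sweeps run one pulse of fixed size and location per harvest
rate (default grid 1.8–2.8, step 0.05) on a homogeneous landscape; the
patch network and its degree-4 focus are drawn once per sweep so only c
varies along a curve. Random campaigns draw, per replicate, one
heterogeneous growth-rate landscape — 25 blocks of U[0.8, 1.2] day⁻¹
smoothed with a truncated, edge-renormalized Gaussian (σ = 10 m, half a
block; the kernel is a convex combination, so the field stays inside the
bounds) for the grid, i.i.d. patch rates for the network — and one fresh
random pulse per (replicate, c): square size ~ U[1 %, 5 %] at a uniform
position, or a uniform random patch. Aggregation reports, per c, the mean
and 10th/90th percentiles (linear order-statistic interpolation) of
recovery rate over recovered replicates only, outcome-class fractions
over resolved replicates, and residuals of an OLS fit of recovery rate on
the covariate (A or degree k), grouped per c level — pooling across c
would absorb the very trend the indicator is meant to show; a pooled fit
remains available via `per_c=False`.

Reproducibility: one root seed feeds named substreams (network, r-field,
disturbance × replicate × c-level), so varying one component never
perturbs another's draws, and full sweeps are bit-reproducible.

## What the generator emulates — and what it does not

The synthetic landscapes reproduce the study conditions: homogeneous or
block-heterogeneous growth rates, ER patch networks conditioned on being
connected and containing a degree-4 node (dispersal-mediated recovery is
undefined for unreachable patches, and the focus-patch protocol needs
one), and pulse disturbances of the standard sizes. They do not include
demographic or environmental stochasticity, anisotropic or
distance-weighted dispersal, non-ER topologies, or press perturbations —
so passing tests demonstrate the deterministic disturbance–recovery logic
under idealized dispersal, not robustness of the indicator to noise or to
realistic landscape structure.

## Design notes and degenerate cases

* With d = 0 the zeroed patch sits exactly on the extinction equilibrium
  and the disturbed state is stationary at t₀; the outcome (`no_recovery`)
  is classified analytically without integration.
* In partially coexisting heterogeneous landscapes near the collapse, a
  random pulse can land on a patch already in the degraded state; its
  biomass trivially returns to the (low) pre-disturbance value and is
  recorded as a fast recovery. This inflates mean recovery rates in the
  last one or two c levels before systemic collapse, where recovered runs
  are a minority; trend statements are therefore evaluated over the c
  range where recovery is the majority outcome.
* A constant covariate makes the OLS correction degenerate; residuals
  fall back to deviations from the group mean, with a logged warning.
* Problem sizes used in the automated end-to-end checks: sweeps on a
  20 × 20 grid / 50-patch network (edge probability 0.08 keeps the mean
  degree ≈ 4 of the 100-patch standard) with c step 0.1, and 20
  replicates for the heterogeneous campaigns; front-propagation
  comparisons (recovery-time ordering, grid refinement) use the standard
  50 × 50 lattice, where a 100 × 100 refinement changes a reference
  recovery time by under 2 %. Discretization matters physically: on
  coarse lattices a pulse can pin or nucleate at slightly different c
  than on the standard grid, which is why front-sensitive checks are not
  run at reduced resolution.

## Known limitations

Explicit RK45 only (no stiff solver; fine at these diffusion numbers but
a very fine grid would force small steps); spatially uniform D and d; the
"recovery length" statistic of press-perturbation experiments is out of
scope; no network-topology targeting experiments.
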