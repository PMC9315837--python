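# Methods

## Scope and model structure

`memchrom` implements two descriptions of band broadening in frontal
membrane chromatography and the machinery to convert either into an axial
dispersion coefficient:

1. a **continuum convection–dispersion model** with lumped local-equilibrium
   adsorption (`transport`, `isotherms`), driven by `D_L` or by the
   dispersivity `α = D_L/⟨v⟩`;
2. a **polydisperse parallel-pore model** (`pore_model`): straight
   cylindrical pores, truncated-Gaussian radii, Hagen–Poiseuille laminar
   flow, breakthrough by flow-weighted residence-time superposition.
   Intra-pore (Taylor–Aris) dispersion, tortuosity and pore connectivity are
   deliberately outside this model;
3. the **method-of-moments** route (`peakfit`, `moments`): staircase
   breakthrough → anchored-logistic regularization → analytic derivative
   peak → first/second central moments → `D_L`, `α`.

Washing/elution stages, binding kinetics (no rate constants are available —
only equilibrium parameters), competitive adsorption, Freundlich/Temkin
isotherms and temperature effects are out of scope.

## Parameters that matter

| parameter | units | default | role / why this default |
|---|---|---|---|
| `µ`, `σ` | cm (accepted in µm) | — | Gaussian PSD location/width; σ/µ is the sole driver of bundle dispersion |
| `r_min`, `r_max` | cm | 0.5, 6.5 µm | catalogue truncation bounds; `r_max` sets the fastest pore when it binds |
| `θ` | — | 1e-5 | relative-density support cutoff: radii where `f` falls below θ·mode are dropped, i.e. support `µ ± σ√(2 ln 1/θ)` ≈ µ ± 4.8σ intersected with `[r_min, r_max]`. This reproduces the reference lag time for σ = 0.10 µm (2.95 vs 2.94 s); the raw catalogue bounds alone do not |
| `n_bins` | — | 600 | uniform radius bins, midpoint rule; the pipeline's D_L changes < 0.5% on doubling |
| time grid | — | `T/4000`, `T` = 1.2 × (time of first crossing of c/c0 = 0.999) | the plateau-quantile rule scales the grid with 1/⟨v⟩, keeping the fitted α nearly flowrate-invariant; an absolute-step grid is available (`sweep --fixed-time-grid`) to expose the artifact it causes |
| `δ` | mg/mL | 1e-3 | regularization substituted for an exactly-zero K_d inside the capacity factor (an irreversible site makes `dq/dc` a Dirac spike at c = 0). Halving δ moves the simulated half-breakthrough time by ≈ 0.05% (< the 1% acceptance we impose on ourselves) |
| `ε` in the 2nd-moment relation | — | off | see Conventions |
| `n_cells`, `rtol`, `atol` | — | 400, 1e-8, 1e-10 | PDE discretization/integration; grid-convergence of the half-rise time < 0.5% on halving the cell size |

## Sigmoid regularization

`t_lag` is not fitted: it is the residence time of the largest retained
pore, known exactly from the bundle, leaving three unknowns (a, b, c). The
least-squares problem is solved over all samples with `t > t_lag`,
unweighted, initialized at a = final value, c = time-to-half-plateau,
b = 4·(max slope)/a, with up to 5 log-normally jittered restarts under a
fixed seed (1234) — every workflow is therefore bit-reproducible. A fit
whose plateau strays more than 5% from the curve's final value is rejected.
The pulse peak is the *analytic* derivative of the fit sampled on the same
grid; moments use plain trapezoidal quadrature on the native grid (no
interpolation), so grid density is the only quadrature knob.

Because the logistic is symmetric while the bundle's residence-time density
is increasingly right-skewed as σ grows, the fit systematically trims the
slow-pore tail: the fitted `µ̄2` falls below the exact flow-weighted
`Var(τ)` by ~2% at σ = 0.10 µm and by ~35% at σ = 0.35 µm. This is the main
reason results for broad distributions depend on the (otherwise arbitrary)
fit window, and why our self-imposed tolerances widen with σ.

## Conventions

Adsorbed concentration `q` is per unit volume of **solid** membrane, so
`(1−ε)` multiplies `q` in all balances. The second-moment relation is used
in its ε-free form `µ̄2 = 2 L D_L/⟨v⟩³` by default (the standard result for
a peak expressed against interstitial velocity); the variant with an extra
`ε` is implemented, every `MomentSummary` records which convention produced
it, and comparisons across conventions raise. Internally everything is CGS
(cm, s, mg, mL); bench units (mL/min, µm) appear only at named
constructors/arguments.

## Numerics

- **Spatial scheme**: finite volumes; convective face values by 4th-order
  central interpolation and dispersive fluxes by the 4th-order
  face-gradient formula (2nd-order at the boundary faces). First-order
  upwinding was rejected: its numerical diffusion (~`⟨v⟩Δz/2`) swamps the
  physical `D_L` at the Péclet numbers the validation covers.
- **Time integration**: LSODA with a banded Jacobian (bandwidth 3).
- **Boundary closures**: Danckwerts (flux inlet, zero-gradient outlet) is
  the physical default. A `semi_infinite` closure (Dirichlet inlet, domain
  extended 2×, outlet read by interpolation at z = L) exists for validation
  against the classical closed-form step response, which is a semi-infinite
  solution; the two closures differ by a grid-independent O(1/Pe) amount
  (~3×10⁻³ in c/c0 at Pe = 50), larger than the 10⁻³ validation budget.
  With matched closure the solver meets L∞ < 3×10⁻⁴ at 400 cells for
  Pe 50–2000.
- **Closed-form oracle**: the `exp(⟨v⟩L/D_L)·erfc(·)` term is evaluated via
  `erfcx` (scaled complement); the naive product underflows above Pe ≈ 700
  while still contributing O(1/√(πPe)) near the front.
- **Degenerate inputs**: monodisperse PSDs are handled as σ → 0 limits
  (all flow in one class; zero residence-time variance); `D_L = 0` runs
  warn (pure advection on a fixed grid); empty PSD supports, negative
  concentrations, non-increasing time axes and mixed moment conventions
  all raise with the offending field named.
- **Extra-column chain**: plug-flow delay + exact piecewise-linear update
  for the stirred tank, with breakpoints inserted at delayed sample times
  so ideal steps stay sharp; mass is conserved to the interpolation error
  of the output grid (≲10⁻⁶ relative).

## Synthetic inputs and what tests show

There is no external data: all inputs are printed parameter sets (geometry,
isotherm, extra-column volumes, PSD ranges), and test fixtures are
generated in code. The synthetic tracer peak generator
(`moments.synthetic_pulse`) draws from the closed-form advection–dispersion
residence-time density with *known* `D_L`, which makes parameter recovery a
true round-trip test (2% over Péclet 50–5000). What these fixtures do not
emulate: detector noise, baseline drift, extra-column tailing of measured
peaks, or real PSDs (which are neither Gaussian nor composed of straight
independent cylinders). Passing tests therefore certify the numerics and
the internal consistency of the two models — not that either model captures
a particular real membrane.

## Findings the workflows make explicit

- **Flowrate invariance**: the exact-moment route gives a dispersivity that
  is identical across flowrates to 10⁻¹⁰ relative (pure self-similarity in
  `t·⟨v⟩`), for every σ. The fitted pipeline reproduces this only when its
  time grid scales with 1/⟨v⟩; freezing an absolute grid makes the fitted α
  drift with flowrate — an artifact the sweep report quantifies side by
  side with the invariant oracle column.
- **Bundle vs continuum**: feeding the bundle-derived `D_L` into the
  non-binding continuum equation yields curves agreeing in first moment to
  <2% at all σ, but the L∞ discrepancy *grows* with σ (0.016 → 0.066 for
  σ = 0.10 → 0.35 µm, raw or fitted curve, either closure): at matched
  variance the bundle's curve is increasingly right-skewed while the
  continuum response stays near-symmetric. The comparison report exposes
  both norms rather than asserting a preferred ordering.

## Problem sizes

Default runs used throughout the tests and the reproduction script:
600 radius bins × 4000 time intervals for the bundle pipeline, 400 PDE
cells with 300–600 output times for transport runs; each individual
pipeline completes in well under a second, the full binding simulation in
about one second.

## Known limitations

The sigmoid family cannot represent heavy residence-time tails, so
fitted-pipeline `D_L` for broad PSDs is window-dependent (use
`regularize=False` for the exact route). The continuum solver assumes a
single solute and local equilibrium; no film or pore-diffusion resistance.
Extra-column units are placed upstream of the bed — immaterial for linear
(non-binding) runs, a modelling choice for binding runs.
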