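# memchrom

Simulation and dispersion analysis for frontal membrane chromatography —
the loading mode in which a protein feed (e.g. polyclonal IgG) is pushed
through a thin stack of adsorptive membranes until the bed saturates.

The package is aimed at bioprocess modellers who need to (i) predict
breakthrough curves of laboratory membrane-adsorber units, including the
non-negligible extra-column hardware of bench FPLC systems, and (ii) audit
whether a hypothesized pore-size distribution (PSD) is a physically
consistent way to explain band broadening, or whether a single measurable
material property — the axial dispersion coefficient — does the job.

## Models

**Continuum transport.** The mobile-phase concentration `c(z, t)` in a bed of
thickness `L`, porosity `ε`, at interstitial velocity `⟨v⟩ = F/(εA)` obeys

```
φ(c) ∂c/∂t + ⟨v⟩ ∂c/∂z = D_L ∂²c/∂z²,     c(z, 0) = 0,
φ(c) = 1 + ((1−ε)/ε) Σ_sites q_m K_d / (c + K_d)²,
```

with local (bi-)Langmuir equilibrium lumped into the capacity factor `φ`
(`φ ≡ 1` for a non-binding tracer). `D_L` (cm²/s) is the axial dispersion
coefficient; `α = D_L/⟨v⟩` (cm) is the dispersivity, a velocity-independent
property of the porous medium. Extra-column hardware is a plug-flow delay
`V_PFR(F)/F` plus a stirred-tank mixer of time constant `V_CSTR/F` upstream
of the bed.

**Polydisperse pore bundle.** Alternatively the membrane is idealized as
parallel cylindrical pores whose radii follow a truncated Gaussian
`f(r_p)`. Hagen–Poiseuille flow makes the per-pore rate `∝ r_p⁴` and the
mean in-pore velocity `v_m(r_p) = ⟨v⟩ (M₂/M₄) r_p²` (`M_k` = k-th raw moment
of `f`), so a step input emerges as the flow-weighted superposition of
delayed steps, one delay `τ(r_p) = L/v_m(r_p)` per pore class. The staircase
breakthrough is regularized with an anchored logistic,
`a/(1+e^{−b[(t−t_lag)−c]}) − a/(1+e^{bc})` for `t > t_lag`, differentiated
analytically into a pulse peak, and fed to the method of moments:

```
µ1 = L/⟨v⟩,      µ̄2 = 2 L D_L / ⟨v⟩³   ⇒   D_L, α.
```

A grid-free oracle, `Var(τ) = (L/⟨v⟩)² (M₄M₀/M₂² − 1)`, cross-checks the
fitted pipeline — and proves that the bundle's dispersivity cannot depend on
flowrate, so any flowrate drift a fitted pipeline reports is a numerical
artifact of the regularization, not membrane physics.

## Worked example

```python
import memchrom as mc

column = mc.MembraneColumn.from_disc(thickness=275e-4, diameter=2.2, void_fraction=0.8)
conditions = mc.OperatingConditions.ml_per_min(1.0)
psd = mc.PoreSizeDistribution.from_microns(mu_um=1.5, sigma_um=0.10,
                                           r_min_um=0.5, r_max_um=6.5)
res = mc.PoreDispersionModel(column, conditions, psd).fit()
print(res.summary())
```

prints

```
Pore-bundle dispersion estimate
===============================================
mean pore radius mu                      1.5 um
std sigma                                0.1 um
retained support                [1.02, 1.98] um
flowrate                                   1 mL/min
interstitial velocity <v>           0.005481 cm/s
t_lag                                  2.946 s
-----------------------------------------------
sigmoid a                              1.001
sigmoid b                              2.608 1/s
sigmoid c                              2.027 s
fit SSR                                0.323
first moment mu1                       4.985 s
second central moment                 0.4554 s^2
D_L (epsilon-free)                1.3630e-06 cm^2/s
dispersivity alpha                2.4869e-04 cm
exact-moment D_L (no fit)         1.3308e-06 cm^2/s
```

Reading: no solute leaves before `t_lag ≈ 2.9` s (the fastest retained
pore); the mean residence time is the plug-flow time `L/⟨v⟩ ≈ 5.02` s; the
residence-time spread of this narrow PSD (σ/µ ≈ 7%) is worth
`D_L ≈ 1.4×10⁻⁶` cm²/s, i.e. a dispersivity of `2.5×10⁻⁴` cm — about 400×
smaller than the `0.104` cm actually measured for a real affinity membrane
stack, which is the quantitative core of the argument that an assumed PSD
alone cannot stand in for a measured dispersion coefficient.

The binding simulation runs the other way around, from a measured `α`:

```python
cfg = mc.SimulationConfig(
    column=mc.MembraneColumn(0.1, 3.8, 0.545, n_layers=5),
    conditions=mc.OperatingConditions.ml_per_min(1.0, 0.48),
    isotherm=mc.BiLangmuir(q_m_irr=4.75, k_d_irr=0.0, q_m_rev=7.00, k_d_rev=1.15),
    extra_column=mc.ExtraColumnConfig(0.69, 1.753, 0.025),
    dispersivity=0.104,
)
sol = mc.simulate_experiment(cfg)
print(sol.mass_balance()["residual_fraction"])   # ~1e-7
```

A `memchrom` console script exposes the same workflows
(`simulate`, `psd2dl`, `moments`, `compare`, `sweep`) on YAML configs; see
`memchrom --help`.

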