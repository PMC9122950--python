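# mnsox

Quantitative tools for **manganese-dependent sulfide oxidation in stratified
water columns** — the process by which sulfide diffusing up from euxinic deep
water is consumed at the upper boundary of euxinic water, in the absence of
oxygen and nitrate, by chemolithotrophic bacteria (*Sulfurimonas* spp. and
relatives) using MnO₂ as the terminal electron acceptor. The package is aimed
at microbial biogeochemists who want to (i) estimate first-order sulfide
removal kinetics from spiked-vessel microsensor traces, (ii) test whether
those kinetics, combined with observed cell abundances, can sustain the
observed water-column sulfide profile, and (iii) close diffusive-flux and
electron budgets across a redoxcline.

## What it computes

**Kinetics.** Each Na₂S spike into a stirred anoxic vessel decays as

    [S²⁻]_t / [S²⁻]₀ = e^(a + k t)

with rate coefficient *k* (s⁻¹, negative) fitted per spike by nonlinear least
squares. Pasteurization midway through the experiment isolates the abiotic
background, so

    k_bio = mean(k_pre) − mean(k_post),    k_cell = k_bio / abundance

gives the cell-specific coefficient *k*_cell (l cell⁻¹ s⁻¹). The H₂S
microsensor signal is first converted to total dissolved sulfide
(H₂S + HS⁻ + S²⁻) through the seawater first-dissociation equilibrium
(Millero 1988 pK₁, temperature- and salinity-dependent).

**Transport.** The steady-state sulfide profile across the redoxcline solves

    ∂C/∂t = D_x ∂²C/∂x² + κ(x)·C,    κ ≤ 0

by an explicit finite-difference scheme, with either a biological sink
κ = k_cell · CA(x) · F (abundance-weighted) or a chemical sink κ = k_chem,
active only at and above the upper boundary of euxinic water. Diagnostics
include the depth horizon containing 95% of the oxidation activity and the
linearity of the deep profile.

**Fluxes.** Fick's first law J = D·∂C/∂z from profile gradients, per-cell
flux normalization, and electron mass balance between the upward sulfide flux
(8 e⁻ per S²⁻ → SO₄²⁻) and the MnO₂ shuttle flux (2 e⁻ per Mn(IV) → Mn(II)),
including the share of sulfur electrons diverted to CO₂ fixation.

A synthetic-data module generates traces and depth profiles with known ground
truth so that every estimator can be checked for parameter recovery.

## Worked example

```python
import mnsox

# 8 biological + 3 post-pasteurization 30 uM spikes at 5e7 cells/ml
trace = mnsox.make_trace(mnsox.TraceTruth.default_experiment(seed=1))
print(mnsox.SpikeDecayModel(trace, abundance=5e10).fit().summary())
```

```
Spike-decay kinetics summary
==============================================
spikes fitted                      11 (8 pre, 3 post)
k pre-past. mean (s^-1)   -6.4956e-03 +/- 1.2e-05
k post-past. mean (s^-1)  -1.2514e-03 +/- 1.6e-06
k_bio (s^-1)              -5.2442e-03
cell abundance (l^-1)       5.000e+10
k_cell (l cell^-1 s^-1)   -1.0488e-13
```

A pre-pasteurization 30 µM spike is removed (falls below 1 µM) within ~9
minutes, a post-pasteurization spike in ~45 minutes; the recovered *k*_cell
matches the generator truth of −1.05 × 10⁻¹³ l cell⁻¹ s⁻¹ to 0.1%.

```python
profile = mnsox.make_profiles(mnsox.ProfileTruth())  # peaked abundance, 0.67 uM/m gradient
cfg = mnsox.ModelConfig(sink_mode="biological", tolerance=1e-12)
print(mnsox.SulfideTransportModel(cfg, profile).solve().summary())
```

```
Sulfide reaction-diffusion steady state
==============================================
sink mode                  biological
diffusivity (m^2 s^-1)       1.00e-06
grid                     80-120 m @ 0.2 m
dt used (s)                    8000.0
iterations                      33123
converged                        True
95% oxidation horizon      104.3 - 106.2 m
deep-profile linearity       1.000000 (R^2 below sink zone)
```

The biological model confines 95% of the oxidation to a ~2 m horizon at the
euxinic boundary and leaves the deep profile linear; the same run with
`sink_mode="chemical"` spreads it over ~12 m (94.2–106.0 m) and bends the
profile — the signature that distinguishes cell-catalysed from abiotic
MnO₂-mediated oxidation.

Flux bookkeeping:

```python
mnsox.fick_flux(0.67, 1e-6)            # 6.7e-07 mmol S2- m-2 s-1
mnsox.per_cell_flux(6.7e-7, 4e10)      # 1.675e-17 mmol cell-1 m-2 s-1
100 * mnsox.chemosynthesis_fraction_from_ratio(mnsox.StoichiometryParams())  # 7.5 (%)
```

The same stages are available from a shell:

```bash
mnsox simulate-trace --seed 7 --out trace.csv
mnsox fit-kinetics --trace trace.csv --abundance 5e10 --out summary.json
mnsox simulate-profiles --seed 7 --out profiles.tsv
mnsox run-model --mode biological --profiles profiles.tsv --out result.tsv
mnsox fluxes --profiles profiles.tsv --window 107:120 --out fluxes.json
```

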