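# Methods

## Scientific setting

In a stratified basin the redoxcline separates oxygenated surface water from
euxinic (sulfidic, anoxic) deep water. Where oxygen and nitrate are depleted
above the sulfide onset, an anoxic, non-sulfidic zone persists, and the
oxidant reaching the sulfide interface is particulate MnO₂ settling from
above (the Mn shuttle: Mn²⁺/Mn³⁺ diffuses upward, is oxidized, and the
particles sink back). Sulfide arriving by turbulent diapycnal diffusion from
below is consumed there either abiotically by MnO₂ or by chemolithotrophic
sulfur oxidizers that couple sulfide oxidation to MnO₂ reduction. This
package quantifies that balance in three linked steps: laboratory kinetics,
a water-column reaction–diffusion model, and flux/electron budgets.

## Speciation correction

Amperometric microsensors respond to H₂S gas only. Total dissolved sulfide
(written S²⁻: H₂S + HS⁻ + S²⁻) is recovered from the first dissociation
equilibrium, α = [H₂S]/ΣS = 1/(1 + 10^(pH − pK₁(T,S))). The default pK₁ is
the Millero (1988) seawater expression

    ln K₁ = 225.838 − 13275.3/T − 34.6435 ln T + 0.3449 √S − 0.0274 S

(T in kelvin, S in PSU; pK₁ ≈ 6.79 at 10 °C, S = 22). The coefficients live
in a `SpeciationConstants` record so another published formulation can be
substituted through configuration; defensible alternatives shift α by a few
percent at pH 7, which propagates only weakly into the fitted rate
coefficients because fitting is performed on normalized concentrations. The
second dissociation is neglected (pK₂ far above seawater pH). Validity is
enforced softly: T or S outside the stated range warns rather than fails,
while an evaluated pK₁ outside (5, 9) is treated as an error.

## Spike-decay kinetics

Each spike decay is modelled as C_t/C₀ = exp(a + k t). The intercept
correction *a* absorbs the mismatch between the nominal spike start and the
first retained sample (the segmenter discards a 10 s settling window after
each spike for sensor equilibration). The fit is unweighted nonlinear least
squares on the normalized concentrations with a deterministic
initialization: a = 0 and k from a log-linear pre-fit on the positive
samples. k is not sign-constrained; the negative values arise from the data.

Segmentation uses recorded spike events when present; otherwise an upward
jump ≥ 5 µM between consecutive samples (or an initial concentration already
above that threshold) marks a spike. Segments end at the next event or when
the concentration falls below 1 µM, the working detection floor; segments
shorter than 5 samples, failed fits, and fits with R² < 0.9 are excluded
from aggregation — the source experiment states no quality rule, so this is
the package's own conservative cut, exposed as a parameter.

Aggregation is the arithmetic mean of per-spike k per phase. The biological
coefficient is the phase difference k_bio = mean(k_pre) − mean(k_post), and
k_cell = k_bio / abundance with abundance in cells l⁻¹. Pasteurization is
treated as an instantaneous switch of the biological term to zero; no
thermal transient is modelled.

## Synthetic data

The generator reproduces the study conditions of the laboratory experiment
and the field profiles, with ground truth embedded for parameter-recovery
tests.

Traces: default truth k_cell = −1.05 × 10⁻¹³ l cell⁻¹ s⁻¹ at 5 × 10¹⁰
cells l⁻¹ (5 × 10⁷ ml⁻¹) and a sterile background of −1.25 × 10⁻³ s⁻¹, so a
30 µM spike falls below 1 µM in ~8.7 min with live cells and ~45 min after
pasteurization. Eight 30 µM spikes precede pasteurization and three follow.
Sampling is 1 s (microsensor-like; acquisition frequency is otherwise
unconstrained) and noise is additive Gaussian with sd 0.3 µM on the
total-sulfide channel — about 1% of spike amplitude, a realistic sensor
noise floor; no published noise model exists for these traces. The
as-measured H₂S channel is produced by the inverse speciation correction at
the configured pH 7.0, 10 °C, salinity 22, so reading a written trace
exercises the full correction path. Concentrations are clipped at zero after
noise addition.

Profiles: sulfide is zero above the euxinic boundary (106 m) and increases
linearly below at 0.67 mmol m⁻³ m⁻¹; Campylobacterota abundance is a
Gaussian peak (6.5 × 10⁷ cells l⁻¹ at 100 m, width 6 m — chosen so the
abundance at the euxinic boundary is ~4 × 10⁷ cells l⁻¹ — on a 2 × 10⁶
background), with a *Sulfurimonas* fraction of 0.96. A Gaussian is the
package's choice of smooth unimodal shape; only the peak height, location
and background are observationally constrained. The profile also carries a
static O₂ column vanishing at 90 m and a strictly increasing σθ coordinate
for alignment exercises.

What the generator does **not** emulate: sensor drift and calibration error,
pH excursions during spikes, Mn particle dynamics, lateral intrusions, and
real CTD density fine-structure. Passing recovery tests therefore
demonstrates estimator correctness under the assumed error model, not
robustness to instrument pathologies.

## Reaction–diffusion model

Explicit FTCS scheme on a uniform grid, 80–120 m at Δx = 0.2 m (201 cells),
concentrations in µM ≡ mmol m⁻³. Boundary conditions are Dirichlet: 10 µM at
120 m (the observed value at the base of the modelled domain, held fixed —
the steady state then reproduces it as a permanent boundary value) and 0 µM
at 80 m, where sulfide is undetectable above the redoxcline. A no-flux
(mirrored ghost cell, exactly mass-conserving) option exists for
conservation testing. The sink is active only at depths ≤ 106 m, the upper
boundary of euxinic water; below it the profile is purely diffusive, which
is what produces the linear deep limb.

Stability: Δt = 0.4 · min(Δx²/(2·max D_x), 1/max|κ|). A configured Δt above
the limit is rejected before the first step. Default initial condition is
zero except the bottom boundary cell; the steady state is independent of
initialization (property-tested from two different starts). Convergence is
declared when max|ΔC|/Δt < tolerance; the default tolerance of 10⁻⁹ µM s⁻¹
suits exploratory runs, while the analytic-comparison tests tighten it to
10⁻¹³–10⁻¹⁵ to expose the solver's true accuracy (the no-sink steady state
matches the exact line to ~10⁻⁷ µM; the uniform-sink case matches the sinh
closed form to ~10⁻⁵ relative).

Abundance is interpolated onto the grid log-linearly (abundances span orders
of magnitude; geometric interpolation avoids overshooting between sparse
casts), with constant extrapolation beyond the sampled range; linear
interpolation is available by option. The oxidation horizon is the depth
interval between the 2.5th and 97.5th percentiles of the cumulative
depth-integrated oxidation rate (trapezoidal). Depth is positive downward
throughout.

With the default synthetic profile, the biological model confines 95% of
oxidation to ~104.3–106.2 m while the chemical model spreads it over
~94–106 m, and the biological sink coefficient at boundary abundance exceeds
|k_chem| = 9.53 × 10⁻⁸ s⁻¹ roughly fortyfold — the qualitative contrast that
identifies the oxidation as biologically catalysed.

## Fluxes and electron balance

Fick's first law J = |∂C/∂z| · D with the gradient taken as the OLS slope of
concentration against depth over a stated window (107–120 m by default, the
linear limb below the sink zone). Fluxes are reported as magnitudes with
direction documented by the caller: S²⁻ and dissolved Mn diffuse upward; the
MnO₂ particle flux downward is taken equal to the upward dissolved-Mn flux
under the steady-shuttle argument. Per-cell flux is the plain quotient
flux/density.

Electron bookkeeping uses 2 e⁻ per Mn(IV) → Mn(II) and 8 e⁻ per
S²⁻ → SO₄²⁻ (and per thiosulfate → 2 sulfate per mole of S₂O₃²⁻ sulfur
pair in the growth-substrate couple). From a measured Mn-to-substrate molar
ratio r the chemosynthetic electron share is 1 − r·e_Mn/e_substrate; r = 3.7
gives 7.5%. The Mn-supported fraction of sulfide oxidation,
(J_Mn·e_Mn)/(J_S·e_S), is deliberately fully parameterized: under the
default constants and equal diffusivities the Mn and S gradient pair yields
~12%, and no single published bookkeeping convention is privileged — users
can recompute the balance under their own stoichiometric assumptions
(e.g. incomplete Mn reduction, partial S oxidation) by editing
`StoichiometryParams`.

## Density alignment

Casts are aligned by monotone piecewise-linear interpolation of a reference
cast's σθ → depth relation, preserving every non-depth field and the number
of observations. σθ outside the reference range maps to the end depths
(constant extrapolation) with a warning, with infinitesimal nudges keeping
the depth axis strictly increasing.

## Problem sizes and determinism

Default runs are desk-scale: a full 8+3-spike trace is ~16,000 samples and
fits in well under a second; a steady-state model run is 3–5 × 10⁴ explicit
steps (fractions of a second); the parameter-recovery suite uses 20 seeded
replicates of the full kinetics chain. All randomness flows through
`numpy.random.default_rng` seeded from explicit integers; every CLI run
writes a JSON log with the seed, a configuration hash, the derived stable Δt
and the package version.

## Known limitations

- First-order kinetics assume MnO₂ in excess; no second-order dependence on
  MnO₂ is modelled, and the sterile vessel decay is a single lumped
  coefficient (MnO₂ concentration and vessel geometry are not resolved).
- The transport model is single-species and time-invariant: no coupled
  Mn/O₂/N chemistry, no lateral intrusions, no time-dependent boundary
  forcing, no cryptic sulfur cycling below the sink zone.
- The 95% horizon of the chemical model depends on the assumed k_chem, which
  is itself conditional on an MnO₂ standing stock (10 nM) and on pH and
  temperature.
- Whether spike fits should use the raw H₂S or the total-sulfide channel is
  underdetermined for historical data; both channels are carried and, for a
  well-mixed vessel at constant pH, give identical k because the fit is
  scale-invariant.
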