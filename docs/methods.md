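# Methods

## Model structure

The liver is represented as `n_lu` well-mixed **liver units** (LUs) on the
centimetre scale — far above lobular zonation, which is deliberately not
resolved — coupled through a single plasma FFA pool. Each LU consists of a
sinusoidal (vascular) compartment and a hepatocyte compartment. Three
processes are modelled per unit:

1. **Perfusion.** Arterial inflow and venous outflow per sinusoid volume
   follow Poiseuille's law, v = π r_s⁴/(8 μ l_s Ω_s)·Δp, with sinusoid
   radius r_s = 3.15 µm, length l_s = 375 µm and volume
   Ω_s = 1.169·10⁻¹¹ L. The effective viscosity μ carries no independent
   meaning here; it is fixed so that the default geometry with Δp = 0.2
   perfuses one LU volume of blood per minute at a vascular volume fraction
   φ_sin = 0.1 (i.e. v_ap = v_vp = 10 min⁻¹ per sinusoid volume).

2. **FFA/TAG turnover** (state in mM; TAG counted in FFA equivalents).
   Gradient-driven uptake k_u(FFA_s − F) — reversible, so overloaded cells
   can release FFA back into the blood — β-oxidation k_β F, super-linear
   esterification k_+TAG·F·(F/FFA_crit)², TAG hydrolysis k_−TAG·TAG, VLDL
   export k_VLDL·TAG and a constant de novo synthesis flux. The cubic
   esterification law models the up-regulation of lipogenic enzymes once
   cellular FFA exceeds FFA_crit and acts as a strong buffer on F. All
   cellular fluxes are expressed per LU volume, so 1 mM/min corresponds to
   100 µmol/100 mL/min, directly comparable to whole-organ transport rates.

3. **Damage and repair** of the intact-cell fraction η (per day):
   regeneration k_r η²(1−η) — zero at both η = 0 (no regenerating cells
   left) and η = 1 (no stimulus), maximal at η = 2/3 — against first-order
   damage whose rate constant is basal (k_d) below the cytotoxicity
   threshold FFA_critical and grows linearly with slope γ above it.
   Transient damaging events ("hits") add Gaussian bumps
   k_damage·exp(−(t−T)²/2δ) to the damage rate constant. The two laws
   intersect twice or never: each unit is bistable, and once the effective
   damage rate exceeds k_r/4 (equivalently F exceeds
   FFA_critical·[1 + (k_r/4k_d − 1)/γ] ≈ 0.169 mM at default constants) the
   unit inevitably collapses to η = 0. η multiplies every cellular flux, so
   a collapsed unit neither metabolizes nor stores lipid; VLDL export is
   not η-scaled (a configurable choice, `eta_on_vldl`), which lets TAG
   drain out of failed units instead of freezing in them.

### Plasma closure

The plasma balance is
dFFA_p/dt = v_at − k_et·FFA_p − Λ·⟨v_ap FFA_p − v_vp FFA_s⟩, where ⟨·⟩
averages the arterio-venous extraction over all LUs and Λ is a single
dimensionless closure constant lumping the ratio of hepatic to total blood
volume. Λ is not independently known; it is **calibrated once** so that the
reference liver (all units at the standard constants, η at its basal
stationary value 0.9883) rests at plasma FFA = 0.26 mM under the reference
release rate v_at = 1.17 mM/min, giving Λ ≈ 0.712. Averaging (rather than
summing) over units makes the calibration independent of `n_lu`. Λ is then
reused unchanged in every scenario.

## Default parameters

| symbol | value | units | meaning |
|---|---|---|---|
| k_u | 0.78 | min⁻¹ | FFA uptake |
| k_β | 0.6 | min⁻¹ | β-oxidation |
| k_+TAG | 3.6 | min⁻¹ | esterification |
| k_−TAG | 0.018 | min⁻¹ | TAG hydrolysis |
| k_VLDL | 0.006 | min⁻¹ | VLDL export |
| v_denovo | 0.012 | mM/min | de novo synthesis |
| FFA_crit (synthesis) | 0.1 | mM | esterification threshold |
| k_at / k_et | 1.17 / 2.34 | mM/min, min⁻¹ | adipose release / extra-hepatic clearance |
| Δp_a = Δp_v | 0.2 | – | pressure gradients |
| k_d | 3.456·10⁻⁴ | d⁻¹ | basal damage |
| k_r | 3·10⁻² | d⁻¹ | regeneration |
| γ | 30 | – | damage amplification |
| FFA_critical | 0.1 | mM | cytotoxicity threshold |
| k_damage, δ | 2.1·10⁻³ d⁻¹, 2.4·10⁴ d² | | hit strength (≈ 6 k_d), width (FWHM ≈ 1 y) |

Two conventions deserve note. The hydrolysis/export pair is assigned
0.018/0.006: at the healthy steady state this reproduces the whole-organ
flux pattern (esterification ≈ 14 ≈ hydrolysis 11 + export 3.5
µmol/100 mL/min), whereas the opposite assignment cannot;
`LUMetabolicParams.printed_table_constants()` selects the swap. The
diurnal forcing runs three cycles per day (period 480 min) between
v_at = 0.35 and 2.45 mM/min.

## Heterogeneity generator

Functional heterogeneity — the package's central object of study — is
emulated by drawing selected rate constants per unit from
Normal(reference, cv·reference) with cv = 0.2, matching the reported
regional variability of hepatic blood flow and protein abundance. Draws
below 5% of the reference are redrawn, which perturbs the distribution
negligibly at cv = 0.2 but excludes non-physical non-positive rates.
Progression experiments randomize {Δp, k_u, k_β, k_+TAG, k_−TAG, k_d, k_r}
(perfusion applied as one factor on both pressure gradients); the diurnal
noise experiment randomizes the kinetic table {Δp, k_u, k_β, k_+TAG,
k_−TAG, k_VLDL, v_denovo}. Both lists are configurable. A *homogeneous*
liver shares one draw across all of its units, so livers differ from each
other but are internally uniform. Cohort streams derive from
(master seed, liver index), so results are independent of any
parallelization and bit-reproducible.

What the generator does **not** emulate: spatial correlation between
neighbouring units (draws are i.i.d.), intra-unit zonation, adaptive
up-regulation of metabolic capacity, and any coupling between perfusion
and metabolic draws. Passing tests therefore show that the *mechanism*
behaves as specified under idealized i.i.d. heterogeneity, not that real
livers carry such parameter fields.

## Numerical scheme

*Two-timescale progression.* Lipid turnover relaxes in minutes
(plasma ≈ 0.2 min, sinusoid ≈ 0.06 min, cellular FFA ≈ 1 min,
TAG ≈ 40 min) while η moves on a 30–3000 day scale, so at every outer step
(default 1 day) the coupled plasma/LU lipid system is placed at its exact
quasi-steady state and η is advanced by one classical Runge–Kutta step at
frozen cellular FFA. The quasi-steady state is found by Newton iteration
on the scalar plasma balance (strictly monotone in FFA_p), with the per-unit
cellular FFA balance — also strictly monotone — solved by an inner damped
Newton, vectorized over (livers × units) and warm-started from the previous
day; residual tolerances 10⁻¹³ (cellular) and 10⁻¹¹ (plasma). Halving the
outer step changes TFH at 30 years by < 10⁻³ (asserted in the suite). η is
clipped to [0, 1] and values below 10⁻⁶ are set to exactly 0, an absorbing
state that prevents numerical resurrection through the η² repair term.

*Diurnal runs* integrate the full minute-scale ODE system (1 + 3·n_lu
states) with the stiff BDF method (rtol 10⁻⁸, sparsity pattern supplied),
starting from the quasi-steady state at the mean release rate; statistics
are taken over the final forcing period of a 10-day run, ~100 times the
slowest (TAG) relaxation time. Steady-state solvers are bracketing
(Brent) on analytically reduced scalar balances; their independent oracle
is long-time BDF integration, agreement < 10⁻⁶ mM.

*Degenerate inputs.* η = 0 decouples a unit (sinusoid equilibrates with
plasma, TAG drains, cellular FFA reported as 0); a fully dead liver gives
the closed form FFA_p = v_at/k_et; zero esterification, zero de novo flux
and zero extra-hepatic clearance are all admitted (the mass-conservation
test disables every export pathway and checks that total FFA equivalents
grow exactly by the release rate).

## Scenario problem sizes

The shipped experiments use cohorts of 100 livers of 100 units (10 and
1000 units for the granularity sweep), 35 simulated years with challenge
onset at year 5, trajectories stored every 30 days; diurnal experiments
use 100 randomized units for 10 days. These sizes resolve the cohort
statistics of interest (outcome fractions, rank correlations, variance
ordering) while keeping any single preset within about a minute on one
CPU core.

## Model regime and known limitations

With the default constants the model sits in a **sub-cascade regime**, and
several literature-scale anchors are unreachable in principle; the
end-to-end suite asserts them anyway and the corresponding tests fail by
design, documenting the gap:

- *Plasma band.* Extra-hepatic clearance k_et = 2.34 min⁻¹ removes
  0.94 mM/min from plasma at 0.4 mM — more than the minimum release rate
  0.35 mM/min — and plasma relaxes within a minute, so under diurnal
  forcing plasma FFA quasi-statically tracks v_at down to ≈ 0.10 mM; a
  floor of 0.4 mM is arithmetically incompatible with these constants.
  The resulting ~5-fold plasma swing propagates into a TAG limit-cycle
  max/min ratio of ≈ 3.1 (an often-cited fed/fasted ratio is ≈ 1.8), and
  the relative oscillation amplitude of TAG (1.04) exceeds that of
  cellular FFA (0.43) instead of continuing the plasma → sinusoid → cell
  attenuation chain.
- *No cascade ignition.* Collapse of an average unit requires cellular
  FFA ≥ 0.169 mM, but the cubic esterification clamp caps it at ≈ 0.135 mM
  even at the theoretical plasma ceiling v_at/k_et = 0.75 mM (liver fully
  failed). Consequently the standard challenge (1.17 → 1.76 mM/min) moves
  cellular FFA of a median unit to ≈ 0.096 mM, only slightly past the
  threshold in unlucky units, and TFH drifts from 0.988 to ≈ 0.98 over
  30 years. Complete unit failure, the all-or-none behaviour of
  homogeneous livers, TAG stores above the 30 mM steatosis threshold, and
  hence a meaningful steatosis-pattern score, do not occur; cessation
  variants recover fully and tie exactly. Igniting the cascade would
  require a basal damage rate roughly an order of magnitude larger (a
  hepatocyte turnover of ≈ 1/365 d⁻¹ implies k_d ≈ 2.7·10⁻³ d⁻¹, ~8× the
  default) or a weaker esterification clamp; both are deliberate
  *non-defaults* here because the shipped constants are kept exactly as
  specified.
- *TAG variability.* Across 100 units with 20% kinetic noise the
  coefficient of variation of mean TAG is ≈ 27% (mean over independent
  batches 27.2 ± 1.8), below the ≈ 35% sometimes quoted for outbred
  animals; the esterification buffer narrows the cellular FFA spread that
  would otherwise propagate into TAG.

Qualitative structure is unaffected and verified: bistability and the
collapse bifurcation at k_r/4, mass conservation, monotone TAG/FFA shifts
with esterification capacity, damped oscillation transfer into the cell,
outcome variance shrinking with finer granularity, attenuation of
successive hit-induced dips, and full recovery from year-long hits spaced
three years apart (minimum TFH ≈ 0.90).

Further limitations: no inter-unit flow redistribution after failure
(coupling is purely through the shared plasma pool), no portal/arterial
split, no molecular lipotoxicity mechanisms, lipid droplets, cytokines,
immune or stellate cells — repair is the lumped η-law — and no mapping to
histological scores.
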