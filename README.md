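# nafldsim

Multi-scale simulation of free-fatty-acid (FFA)–driven non-alcoholic fatty
liver disease (NAFLD) progression in a liver composed of many functionally
heterogeneous **liver units** (LUs), written for systems-biology and
computational-hepatology work on how macro-scale (cm) heterogeneity of
perfusion, lipid metabolism and tissue repair shapes long-term disease
outcome.

## The model

Each LU is a two-compartment kinetic system. The sinusoidal blood space
(volume fraction φ_sin = 0.1) is perfused at Poiseuille flows
v_ap = π r_s⁴/(8 μ l_s Ω_s)·Δp_a and exchanges FFA with the hepatocyte
compartment; the cellular FFA pool F and the TAG storage pool (in FFA
equivalents) obey, per LU volume and with η the fraction of intact
hepatocytes,

    dFFA_s/dt = FFA_p·v_ap − FFA_s·v_vp − η·v_u·(Ω_cell/Ω_s)
    dF/dt     = η·(v_u − v_+TAG + v_−TAG − v_β + v_denovo)
    dTAG/dt   = η·(v_+TAG − v_−TAG) − v_VLDL

with v_u = k_u(FFA_s − F), v_β = k_β F, v_+TAG = k_+TAG·F·(F/FFA_crit)²
(super-linear TAG synthesis above FFA_crit = 0.1 mM), v_−TAG = k_−TAG·TAG
and v_VLDL = k_VLDL·TAG. All LUs share one plasma FFA pool fed by adipose
release v_at and drained by extra-hepatic clearance k_et·FFA_p plus the
summed hepatic arterio-venous extraction.

Hepatocyte loss and repair act on years:

    dη/dt = k_r·η²(1−η) − k_d·η·[1 + γ·max(0, F/FFA_critical − 1)] − DF(t)·η

The repair law peaks at η = 2/3; damage is basal below the cytotoxic
threshold FFA_critical = 0.1 mM and amplified (γ = 30) above it; DF(t) adds
Gaussian "hit" events (toxins, infections). Because the damage line can
intersect the repair curve twice or not at all, each unit is bistable: for
effective damage rates above k_r/4 its only attractor is η = 0. A failed
unit stops extracting FFA, which raises plasma FFA for all surviving units
— the cascading-failure loop this package exists to study.

Progression is integrated with a two-timescale scheme (lipids at their
quasi-steady state each day, η advanced by Runge–Kutta), diurnal dynamics
with a stiff minute-scale ODE solver. Functional heterogeneity is sampled
per unit as truncated-normal rate constants (default relative SD 20%).

## Worked example

```python
import nafldsim as ns

liver = ns.sample_virtual_liver(ns.EnsembleSpec(n_lu=100, cv=0.2, seed=7))
res = ns.simulate_progression(liver)          # 35 y; FFA challenge at year 5

print(f"plasma: {res.value_at('plasma_ffa', 4.9):.4f} -> {res.value_at('plasma_ffa', 6.0):.4f}")
print(f"TFH:    {res.value_at('tfh', 4.9):.4f} -> {res.tfh[-1]:.4f}")
print(f"TAG:    {res.per_lu_at('tag', 4.9).mean():.2f} -> {res.per_lu_at('tag', 35.0).mean():.2f} mM")
```

prints

```
plasma: 0.2625 -> 0.3825
TFH:    0.9882 -> 0.9827
TAG:    7.35 -> 13.00 mM
```

Before the challenge the liver rests at 0.26 mM plasma FFA with 98.8% of
hepatocytes intact (the stationary balance of basal damage and repair).
Raising the adipose release rate from 1.17 to 1.76 mM/min lifts plasma FFA
to 0.38 mM and nearly doubles the mean TAG store (7.4 → 13 mM). Under the
default constants the cellular FFA of a median unit stays just below the
0.1 mM cytotoxicity threshold, so the intact fraction only drifts from
0.988 to 0.983 over 30 years — the cascading regime needs units to be
pushed well past threshold (see the methods note for the regime analysis).

The same experiments are available from the shell, e.g.

```bash
nafldsim diurnal --seed 1 --out out/          # limit cycle + 20%-noise cohort
nafldsim hits --seed 2 --n-lu 100 --out out/  # three year-long damaging hits
```

Every run writes tidy CSV trajectories plus `run.json` with the full
configuration, seed, package version and git commit; re-running from that
record reproduces the summaries bit-identically.

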