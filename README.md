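# sedgrid

Custom-grid analysis of sedimentation-velocity analytical-ultracentrifugation
(AUC) experiments for nanoparticle analytes — lipid nanoparticles (LNPs) in
particular — whose densities may lie *above or below* the solvent density in
the same sample, so that some particles sediment while others float.
Combined with D₂O density matching, the package derives distributions of
partial specific volume (v̄, the reciprocal of particle density), molar mass
(M) and hydrodynamic radius (R_h), which together discriminate cargo-loaded
from empty particles where size metrics alone cannot.

## Who this is for

Biophysicists and formulation scientists analysing sedimentation-velocity
AUC data of heterogeneous nanoparticles (LNPs, polymer or metal particles,
loaded vesicles) where the classic constant-v̄ assumption breaks down, and
anyone needing a scriptable, fully text-based AUC simulation + fitting
pipeline with ground-truth synthetic data for validation.

## The model

Radial transport of each species in a spinning sector cell obeys the Lamm
equation

    ∂C/∂t = −(1/r) ∂/∂r [ s ω² r² C − D r ∂C/∂r ],   m < r < b,

with zero total flux at the meniscus *m* and cell bottom *b*.  A scan set is
fitted as a non-negative linear combination of simulated single-solute
solutions (2-D spectrum analysis),

    C_T(r, t) = Σᵢ cᵢ L(sᵢ, Dᵢ),   cᵢ ≥ 0,

over a **custom grid** of basis solutes parameterized by sedimentation
coefficient and partial specific volume at a fixed frictional ratio
α = f/f₀.  The Svedberg and Stokes–Einstein relations close the system:

    s = M(1 − v̄ρ)/(N f),   D = RT/(N f),   R_h = f/(6πη),
    D(s, α, v̄) = RT / [ N · 18π (αη)^{3/2} · √( s v̄ / (2(1 − v̄ρ)) ) ].

The sign of the buoyancy term 1 − v̄ρ decides sedimentation (+) versus
flotation (−); the grid assigns each v̄ column its sign automatically, so a
single grid specification fits purely sedimenting, purely floating and mixed
samples at every solvent density.

**Density matching**: the same sample is measured at several D₂O fractions.
Fitted s-distributions are cut into cumulative-signal boundary fractions,
each fraction's viscosity-corrected mean s is regressed on solvent density,
and the zero crossing gives the density that matches that fraction —
ρ_m = 1/v̄.  M and R_h then follow from the Svedberg and Stokes–Einstein
relations at the reference (lightest) condition.

## Worked example

Simulate an mRNA-LNP-like population (median R_h 21 nm, v̄ ≈ 0.9805 mL/g) at
0/10/15/20% D₂O, fit every condition with the same combined grid, and run
density matching:

```python
import numpy as np
from sedgrid import (BufferSpec, CustomGridModel, DensityMatching, NoiseSpec,
                     PopulationSpec, ComponentSpec, make_density_series,
                     mixed_buoyancy_grid, sample_population)

spec = PopulationSpec(components=(
    ComponentSpec(median_Rh_nm=21.0, Rh_log_sd=0.15, mean_vbar=0.9805,
                  vbar_sd=0.0015, vbar_bounds=(0.977, 0.984), signal=0.83),),
    n_draws=50, seed=42)
pop = sample_population(spec)
sets, truth = make_density_series(pop, [0.0, 0.10, 0.15, 0.20],
                                  noise=NoiseSpec(sigma=0.003), seed=7,
                                  n_radial=200)
ensembles = {}
for phi, data in sets.items():
    grid = mixed_buoyancy_grid(data.buffer.state(), n_s=48, n_vbar=32,
                               s_min_sv=0.3, s_max_sv=40.0,
                               spacing="logarithmic")
    res = CustomGridModel(data, grid).fit(method="iterative", n_partitions=8)
    print(f"{100*phi:>4.0f}% D2O: rmsd = {res.rmsd:.5f}, "
          f"{(res.fitted_amplitudes > 0).sum()} solutes carry signal")
    ensembles[phi] = res.monte_carlo(20, seed=11)

result = DensityMatching(ensembles).fit(n_fractions=12)
print(result.summary())
```

which prints

```
   0% D2O: rmsd = 0.00298, 21 solutes carry signal
  10% D2O: rmsd = 0.00298, 22 solutes carry signal
  15% D2O: rmsd = 0.00725, 13 solutes carry signal
  20% D2O: rmsd = 0.00315, 17 solutes carry signal

Density-matching analysis
================================================================
conditions: 4 solvent densities (reference: 0.0)
fractions: 12 (tails excluded: 2% each side; matched: 12, skipped near match point: 0)
vbar  : 0.9802 +/- 0.0002 mL/g [0.9800, 0.9807]
M     : 1.953e+07 +/- 5.78e+06 Da [1.11e+07, 3.09e+07]
Rh    : 21.40 +/- 2.16 nm [17.88, 25.18]
```

The per-condition rmsd values sit at the injected noise level
(σ = 0.003 OD; the 15% condition is the mixed sediment/float regime where
species at the isopycnic point barely move and are hardest to resolve), and
the recovered signal-weighted v̄ of 0.9802 mL/g reproduces the generating
population's 0.9802 mL/g.  The M and R_h columns summarise the derived
distributions (the population spans ≈15–30 nm R_h by construction).

The same pipeline is available from the shell:

```sh
sedgrid simulate -c run.yaml     # scan sets + ground truth
sedgrid fit -c run.yaml          # custom-grid fits + Monte Carlo
sedgrid densmatch -c run.yaml    # v̄/M/Rh tables
sedgrid report -c run.yaml       # overlay figures
```

(see `tests/test_cli.py` for a complete minimal `run.yaml`).

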