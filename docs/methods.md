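# Methods

This note documents the models, numerical methods, default parameters and
design choices behind sedgrid, and states what the synthetic-data validation
does and does not demonstrate.

## Units and conventions

All internal computation is CGS (cm, g, s, poise, erg, K).  Sedimentation
coefficients are stored in seconds and reported in Svedberg
(1 S = 10⁻¹³ s); radii are reported in nm.  The partial specific volume v̄
is the *apparent particle* value — volume per gram of the whole sedimenting
particle including hydration and bound ions — so the minimal-sphere radius
R₀ refers to a sphere of equal hydrated volume, α = f/f₀ ≥ 1 with equality
for a sphere, and R_h = αR₀ exactly.  No anhydrous correction is applied
anywhere.  This convention introduces a small, deliberate hydration bias in
M that is negligible against the order-of-magnitude heterogeneity of
nanoparticle mass distributions.

Conversions that divide by the buoyancy term are refused inside the band
|1 − v̄ρ| < 10⁻⁴ (configurable): there the implied molar masses diverge and
the (s, α, v̄) parameterization of D is numerically meaningless.

## Buffer model

Densities and viscosities of H₂O/D₂O mixtures come from bundled reference
tables for the pure solvents at 0–40 °C (handbook values; H₂O density
0.99821 g/mL and viscosity 1.0016 mPa·s at 20 °C; D₂O density maximum near
11 °C, viscosity ratio ≈1.245 at 20 °C), interpolated linearly in
temperature and in D₂O volume fraction (density directly, viscosity through
the D₂O/H₂O ratio).  Salts are a constant density increment (default
0.0046 g/mL for 1× PBS, applied at every D₂O fraction because the salt mix
is reconstituted in D₂O) and a viscosity multiplier (default 1.0).  Any
table inaccuracy can be bypassed with explicit (ρ, η) overrides.  Full
solute-composition density models are out of scope.

## Lamm solver

Finite volumes on a fixed uniform radial grid with exponentially fitted
(Scharfetter–Gummel) face fluxes.  Consequences:

- conservation of sector-weighted mass Σ Cᵢ rᵢ h to machine precision, by
  flux telescoping, at any Péclet number;
- the discrete zero-flux steady state is the sedimentation-equilibrium
  exponential exp(sω²r²/2D) *exactly* at the cell centres (the midpoint
  face radius telescopes exactly because r is linear in the index);
- positivity preservation (the implicit operator is an M-matrix);
- stable sharp fronts in the near-zero-D limit, where the flux degrades
  gracefully to upwinding.

Time integration is a θ-scheme: Crank–Nicolson (θ = ½) with an 8-step
backward-Euler start-up to damp the initial-condition discontinuity, and
pure backward Euler when the maximum cell Péclet number exceeds 20 (there
the front is a numerical discontinuity; CN would ring, and only the front
*position* carries information).  Steps follow a deterministic
advection-limited schedule — dt ≤ `cells_per_step`·h/v_max (default 2
cells per step), at least `min_steps` = 150 steps over the run, ramping
geometrically from dt_max/64 — rather than error-controlled adaptivity:
determinism matters more than optimal step counts here, because fitted data
and basis solutions must be *bit-reproducible* and mutually consistent.
Self-convergence is first order or better; on diffusion-resolved profiles
doubling the radial resolution moves the solution by < 10⁻³ RMS (verified
in the test suite).  Rotor acceleration is ignored: ω is constant from
t = 0.

A practical resolution limit, exploited knowingly in the tests: species
whose boundaries are sharper than the radial grid (large |s|, tiny D) have
numerically indistinguishable basis solutions for neighbouring D values, so
their amplitudes are identifiable only as local sums.

## Custom grid

The default basis spans (s, v̄) at fixed α (default 1.1, the near-spherical
value appropriate for LNPs); (s, f/f₀)-at-fixed-v̄ blocks are available for
generality.  Axes are linear or logarithmic; a logarithmic axis on a
negative (flotation) range is logarithmic in magnitude, mirrored.  The
two-block builder pairs a nominally sedimenting v̄ range (default
0.94–0.999 mL/g) and a nominally floating one (1.003–1.05 mL/g), each
carrying the full |s| axis (default 1–100 S, 200 points per block, 60 v̄
points per block — 24 000 solutes).

Each v̄ column's sedimentation sign is assigned from its own buoyancy term,
sign(s) = sign(1 − v̄ρ).  This is the key to using *one grid specification
at every solvent density*: as D₂O moves the match point 1/ρ through the v̄
range, affected columns flip from sedimenting to floating instead of
becoming invalid.  Columns inside the buoyancy-exclusion band are dropped.

For iterative refinement the grid is partitioned into coarse interleaved
subgrids (2-D strides over both axes), every partition spanning the full
parameter range.  Partitions are fitted in sequence, carrying the
accumulated non-zero solute set forward; sweeps repeat until the support is
stable.  This sequential-accumulation schedule makes the final rmsd
monotone and bounded by any single-partition rmsd.  Partition fits and
Monte Carlo iterations are independent units; results do not depend on
execution order.

## Spectrum fitting

Amplitudes are obtained by non-negative least squares
(scipy's Lawson–Hanson active-set solver).  A final polish refits the
support pruned at 10⁻⁵ of the total signal, removing sub-ppm amplitude
leakage between nearly collinear columns; exactly representable data are
then recovered to machine precision.

Time-invariant (per-radius) and radially invariant (per-scan) noise vectors
are estimated by alternation: NNLS on noise-corrected data, TI = scan-mean
of residuals, RI = radius-mean of TI-removed residuals, iterated to an rmsd
change < 10⁻⁶ (max 20 rounds).  A constant offset is not identifiable
between TI and RI, so RI is constrained to zero mean with the offset
absorbed into TI — this changes the noise vectors, never the modeled
signal.

Meniscus/bottom refinement is an rmsd grid search (full fit per candidate)
with parabolic interpolation through the bracketing triple; an edge minimum
is flagged as not bracketed.  During the search, basis solutions are
simulated on an internal grid spanning each candidate column and
interpolated to the data radii.

Monte Carlo error analysis refits the converged model's basis against
synthetic data = model prediction + homoscedastic Gaussian noise with
σ = fit rmsd (residual resampling available as an option), seeded and
bit-reproducible.  Restricting refits to the converged basis (rather than
the full grid) is a desk-scale economy; it slightly understates the
variance contributed by support changes.

## PCSA

The straight-line family v̄(s) = a + b·s: a K×K grid of endpoint pairs,
L solutes per line, NNLS per line, deterministic argmin with ties broken by
smaller |slope| then smaller intercept, followed by one half-spacing
refinement pass around the winner.  Only straight lines are implemented;
curved (e.g. sigmoidal) families are future work, and no Tikhonov
regularization is applied.  Any line's solutes are a subset of a
sufficiently fine 2-D grid, so the unconstrained custom grid can never fit
worse — PCSA is the orthogonal, more constrained validator.

## Density matching

Per condition, the fitted (Monte-Carlo-averaged) s-distribution is cut into
`n_fractions` equal cumulative-signal slices after excluding
`tail_exclusion` (default 2%) at each end; point masses straddling a cut
are split exactly.  Defaults are 100 fractions, but the number of fractions
should be matched to the s-resolution of the fitting grid — each slice
should average several grid points, or the grid quantization leaks into the
per-fraction means (the validation pipeline uses 12 fractions against
48-point log s-axes).

Fractions pair across conditions by quantile rank, which assumes the
species order in s is preserved across densities.  Two refinements to that
classic assumption:

- **Orientation.**  Flotation inverts the signed-s order of species (the
  largest particles are the most negative), so conditions whose
  signal-weighted mean s is negative are reversed before pairing.  Without
  this, an all-floating 20% D₂O condition would pair its largest particles
  with the reference's smallest.
- **Mixed conditions.**  Where the match point lies inside the v̄
  distribution, rank pairing is genuinely approximate — but those
  conditions contribute points near s′ = 0, where mis-pairing has little
  leverage on the extrapolation.

Each fraction's viscosity-corrected mean s′ = s·η/η_ref is regressed on
solvent density (unweighted OLS — no weighting scheme is imposed); s′ of an
ideal species is exactly linear in ρ, the slope must be negative, and the
zero crossing must fall in (0.9, 1.3) g/mL, else the fraction is flagged
unmatchable.  v̄ = 1/ρ_m.

M and R_h derive from the reference condition (default: lowest density,
largest |s| signal).  The diffusion coefficient entering them is, by
default, *re-constrained* from the reference mean s, the extrapolated v̄
and the fixed frictional ratio through the (s, α, v̄) parameterization —
the same constraint the fitting grid imposes — rather than the
signal-weighted mean of fitted grid D values, which is quantized at the
grid's v̄ resolution and noticeably coarser.  The fitted-D route is
available via `d_source="fit"`.

## Synthetic data

The generator emulates LNP density-matching experiments: lognormal R_h
(sizes are unimodal and right-skewed in micrographs of such particles),
truncated-normal v̄ drawn independently of size, fixed α = 1.1, intrinsic
(M, v̄, α) held fixed across conditions while (s, D) are recomputed per
buffer.  Four presets cover the cargo-loading states — empty
(v̄ 0.990–0.992 mL/g, strongly size-heterogeneous, 20–110 nm diameter),
protein-conjugated (0.980–0.990), mRNA-loaded (0.977–0.984) and
protein+mRNA (0.9725–0.9845) — with v̄ windows inside the ranges reported
for such formulations.  The mRNA-like preset is arranged so the standard
0/10/15/20% D₂O series traverses all three regimes: fully sedimenting at
0–10%, mixed at 15%, fully floating at 20%.  Noise defaults to σ = 0.003
signal units (≈ the SNR of a good absorbance experiment at 0.8 OD loading),
plus optional Gaussian-bump TI and zero-mean per-scan RI artifacts.

What passing the synthetic validation shows: the full pipeline — solver,
grids, NNLS, noise decomposition, Monte Carlo, extrapolation — recovers
known ground truth at realistic noise, sizes and densities, including the
mixed regime.  What it does not show: robustness to real-instrument
systematics beyond TI/RI (window artifacts, λ calibration, rotor
acceleration, concentration-dependent non-ideality, solvent compression),
to H/D exchange effects on v̄, or to size–density correlations within a
formulation (draws are independent; real cargo loading may couple them).

## Validation problem sizes

The automated checks run at desk scale, chosen to finish in minutes on one
CPU: 10⁴ random draws for the hydrodynamic identity (agreement to 10⁻¹⁰
relative); solver physics on 600-cell grids; spectrum recovery on a
40 × 24 reduced grid; the mixed-regime fit on a 40 × 24 combined grid; the
density-matching pipeline on the mRNA-like preset (100 draws, 4 densities,
25 scans × 200 radii, 48 × 32 grids, 20 Monte Carlo iterations, 12
fractions), recovering per-fraction v̄ within ±0.005 mL/g, M within ±15%
and R_h within ±10%; and PCSA line recovery within one endpoint-grid
spacing.  The full-scale 24 000-solute grid is constructed and partitioned
in the tests but not fitted end-to-end there.

## Known limitations

- Single-speed, constant-ω experiments only; no pressure/compressibility
  effects; no concentration dependence s(C), D(C).
- Boundary-fraction pairing across densities is rank-based; strongly
  size–density-correlated samples could violate it in the mixed regime.
- Amplitudes of basis solutes sharing near-identical (s, D) are only
  identifiable as sums (an intrinsic property of spectrum methods, not a
  defect of the solver).
- Raw vendor/archive scan formats are not parsed; an adapter stub documents
  the required mapping onto the package's text format.
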