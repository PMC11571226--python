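# Methods

## Model

`mixent` estimates the configurational entropy of mixing of one coordinate
frame.  Each site *i* (an atom, or one site per molecule) is broadened into
a unit-normalised Gaussian of width σ_i; summing the kernels of one species
gives its partial density ρ^(λ)(r), and the molar-fraction field is the
ratio x^(λ)(r) = ρ^(λ)/Σ_μ ρ^(μ).  The entropy-of-mixing density is the
local ideal-mixing (Shannon) term −(1/V) Σ_λ x^(λ) ln x^(λ), in units of
R per volume, and its box integral is the scalar ΔS in units of R.

The estimator's defining properties, each covered by tests:

- **Range.** 0 ≤ ΔS ≤ −Σ x̄ ln x̄ (the equilibrium value at the global
  fractions).  Separated phases give ≈ 0 because the Shannon term vanishes
  wherever one species dominates; only interface regions contribute.
- **Mixed limit.** A perfectly alternating arrangement approaches R ln 2
  from below; the deficit is controlled by σ, since finite broadening keeps
  the local fractions oscillating around the global ones.  Increasing σ
  moves ΔS toward the bound.  No correction toward the equilibrium value is
  attempted: ΔS is reported as defined, and the σ-dependence is regarded as
  part of the estimator.
- **Intensivity.** ΔS is a per-mole quantity: tiling a frame leaves it
  unchanged.
- **Multicomponent.** Any number of species is supported; the bound becomes
  ln S for an equimolar S-component mixture.

Only configurational mixing enters: no vibrational, pressure or thermal
contributions are modelled.

## Parameters

- **σ (Angstrom).** Physical scale of a site, near its van der Waals
  radius.  Defaults: the Bondi radius per element when element symbols are
  available, otherwise 1.5 Å (a typical heavy-atom radius).  Accepts a
  scalar, per-species mapping, or per-site array.
- **cutoff_multiple (default 4).** Kernels are truncated at this many σ;
  the neglected mass is below `exp(−c²/2)` relative.  When the truncation
  radius exceeds half a box length, explicit periodic images are summed, so
  arbitrarily broad kernels remain exact rather than being restricted to
  minimum-image evaluation.
- **Vacuum floor.** The fraction field is 0/0 far from all sites.  Points
  whose total density falls below 1e−12 × the tallest single-site kernel
  amplitude are defined to contribute zero entropy density.  `x ln x` is
  evaluated as 0 at x = 0 (continuous limit).
- **Resolution.** Grid integration defaults to a spacing of σ_min/4, which
  resolves the kernels; a coarser grid triggers a warning.

## Integration

The default integrator is a Riemann sum on a regular grid commensurate with
the periodic box, with densities rasterised by per-site stencil
accumulation (wrapping stencils deposit all contributing periodic images).
Its error estimate is the difference against the stride-2 subgrid.  An
adaptive multidimensional cubature over the whole box is available as an
alternative (`method="adaptive"`) and agrees with the grid within combined
tolerances; non-convergence raises an error carrying the best estimate.
The whole-box adaptive scheme was chosen over a pair-localised subdivision
because the regular grid already serves as the fast default and the
unrestricted cubature is the simpler, unambiguous formulation; the two
routes cross-validate each other in the tests.

Spatial weighting is uniform (units R/V), matching the definition of the
entropy density; an alternative local-density weighting
(−Σ x ln x · ρ_tot/N) is available behind a flag for systems with vacuum,
where it preserves molarity.

## Cell estimator

The coarse-grained ancestor of the field estimator partitions the box into
elementary volumes, applies the equilibrium formula to each cell's local
fractions and sums with mole weights N_α/N.  Mole weighting is used (rather
than volume weighting) so that a configuration whose cells all sit at the
global fractions reduces *exactly* to the equilibrium formula regardless of
occupancy fluctuations.  Pure and empty cells contribute zero.  As a
plug-in entropy estimate it carries the usual finite-occupancy
(Miller–Madow) bias of about (S−1)·n_cells/(2N), which the tests account
for explicitly when comparing against ln 2.

## Synthetic data

The generators provide configurations whose mixing state is known by
construction: 1-D chains at integer multiples of a spacing (separated
`AAAAABBBBB` or alternating `ABAB…` patterns; 1-D frames are first-class),
checkerboard lattices, uniformly random slab phases (fully separated) and
uniform random mixtures.  Default conditions are 250 sites per species in a
30 Å cubic box — number density 0.019 Å⁻³, representative of one site per
small solvent molecule — with σ = 1.5 Å.

The Brownian pseudo-trajectory is plumbing, not physics: an overdamped
random walk (defaults D = 0.05 Å²/ps, dt = 0.5 ps) with an optional
exponential interspecies repulsion bias that drives demixing.  It exists so
that mixing and demixing traces with a known direction can be produced
without any simulation engine.  Passing tests on it demonstrate the
estimator and the fitting pipeline, *not* agreement with molecular-dynamics
kinetics: real trajectories have momentum conservation, molecular
structure, and interaction-dependent time constants that the walker does
not emulate.  The demo conditions (96+96 sites, 20 Å box, σ = 2 Å, 300
steps sampled every 3) were sized so a full mixing transient fits in a
desk-scale run.  All generators draw from `numpy.random.default_rng`
(PCG64) and are bit-reproducible from the seed.

## File handling

XYZ (plain and extended, with `Lattice` comments honoured), GRO and PDB
are read through MDAnalysis and mdtraj; GRO topology names are taken
verbatim from the file while coordinates/times come from the multi-frame
reader.  GRO nanometres are converted to Å on read; all internal lengths
are Å and times ps.  Boxes must be orthorhombic — triclinic cells are
rejected with a clear error.  Species are per residue/molecule: ordered
selector rules (`resname:`, `name:`, `index:`, first match wins) map
residues to components, with an optional default.  Frames of dimensionality
below three written to XYZ carry a `mixent_dim` comment tag so they
round-trip.  Entropy traces serialise to CSV with a JSON-valued metadata
preamble and round-trip losslessly (floats written via shortest
round-trip repr).

## Kinetics

Traces are fitted to ΔS(t) = ΔS₀ + ΔS∞(1 − exp(−t/τ)) by bounded nonlinear
least squares with τ log-parameterised (strictly positive) and ΔS₀ ≥ 0;
demixing corresponds to ΔS∞ < 0.  Initial guesses: ΔS₀ from the first
value, ΔS∞ from the span, τ from the half-rise time.  The covariance is the
linearised least-squares covariance, delta-method-transformed from log τ to
τ.  Flat traces (variance < 1e−12) are rejected as non-identifiable;
optimizer failure is reported via `converged=False` rather than an
exception.  Times are fitted relative to the first sample, so τ is exactly
equivariant under time rescaling.

## Numerical choices and degenerate inputs

- Grid spacings divide the box exactly (nearest integer voxel count), so
  periodic wrapping is commensurate.
- A species with zero sites yields an identically zero density, not an
  error; a single-species frame has ΔS = 0.
- Points outside the box on a non-periodic axis are a domain error;
  periodic axes wrap.
- Sites exactly on the truncation sphere are included (the cutoff test is
  strict inequality for exclusion).
- Tiny negative totals from floating-point cancellation are clipped to 0.

## Known limitations

- ΔS depends on σ; values are comparable only at fixed broadening
  settings, and no σ-calibration toward the equilibrium limit is provided.
- Orthorhombic boxes only.
- The adaptive integrator evaluates the full box and is slower than the
  grid for large frames; the grid is the intended default.
- The synthetic generators place independent uniform sites (no excluded
  volume or liquid structure), so absolute ΔS levels on real liquids will
  differ from the synthetic figures at the same density and σ.
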