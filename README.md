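# mixent

Instantaneous configurational entropy of mixing of a multicomponent
particle system, computed directly from a single frame of coordinates.

## The problem

For a fully mixed equilibrium system the molar entropy of mixing is the
textbook expression

    ΔS / R = − Σ_λ x^(λ) ln x^(λ),

with global molar fractions `x^(λ) = N^(λ)/N` (so `ln 2 ≈ 0.69` for an
equimolar binary mixture).  That formula says nothing about *transient*
states: halfway through a mixing or demixing process there has been no way
to read "how mixed is this configuration?" off the coordinates of one
snapshot.  `mixent` implements a spatial estimator that does exactly that,
which makes the degree of mixing an on-the-fly observable along a molecular
dynamics (or any other) trajectory.

## The estimator

1. Every site *i* is replaced by a unit-normalised Gaussian of width σ_i
   (chosen near the van der Waals radius), giving broadened partial
   densities per species under periodic boundary conditions:
   `ρ^(λ)(r) = Σ_{i∈λ} (2πσ_i²)^(−d/2) exp(−|r−R_i|²/2σ_i²)`.
2. Molar-fraction fields are density ratios:
   `x^(λ)(r) = ρ^(λ)(r) / Σ_μ ρ^(μ)(r)`.
3. The entropy-of-mixing density is the local Shannon term,
   `ΔS(r) = −(1/V) Σ_λ x^(λ)(r) ln x^(λ)(r)` (units R/V), concentrated at
   interspecies interfaces.
4. Integrating over the box yields the scalar `ΔS` in units of the gas
   constant R, bounded by `[0, −Σ x ln x]`: separated phases give ≈ 0,
   well-mixed frames approach the equilibrium value from below.

A coarse-grained estimator (partition the box into cells, apply the
equilibrium formula cell-wise with mole weights) is included as an
independent cross-check, along with exponential kinetics fitting
`ΔS(t) = ΔS₀ + ΔS∞(1 − exp(−t/τ))` for traces, synthetic configuration
generators, and readers for XYZ/GRO/PDB files.

## Worked example

```python
import numpy as np
from mixent import make_slabs, make_random, entropy_of_mixing

box = (30.0, 30.0, 30.0)
separated = make_slabs((250, 250), box, seed=1)
mixed = make_random((250, 250), box, seed=1)

for name, frame in [("separated", separated), ("mixed", mixed)]:
    r = entropy_of_mixing(frame, sigma=1.5)
    print(f"{name}: dS = {r.delta_S:.3f} R (max {r.theoretical_max:.3f} R)")
```

prints

```
separated: dS = 0.153 R (max 0.693 R)
mixed: dS = 0.530 R (max 0.693 R)
```

The separated two-slab frame retains a small positive value because its two
periodic interfaces still mix locally on the scale of σ = 1.5 Å; the random
frame sits well below the `ln 2` bound because finite broadening keeps the
local fractions oscillating around 0.5.

The same pipeline from the shell, with an exponential fit of a Brownian
pseudo-trajectory (a deliberately minimal stand-in dynamics used only to
exercise the workflow):

```sh
mixent demo --seed 7 -o demo-out
mixent compute -g chain --pattern ABABABABAB --sigma 1.5 -o chain.csv
mixent fit demo-out/mixing_trace.csv
```

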