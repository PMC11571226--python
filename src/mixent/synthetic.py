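"""Synthetic configurations and pseudo-trajectories with known mixing state.

These generators provide every geometry the estimator must handle —
one-dimensional model chains, fully separated slabs, uniform random
mixtures, ordered alternating lattices — plus a seeded overdamped
random-walk ("Brownian") pseudo-trajectory for exercising the kinetics
pipeline end to end.  The Brownian walker is deliberately minimal plumbing:
it has no forces beyond an optional interspecies repulsion bias and makes
no claim to reproduce molecular-dynamics behaviour; it merely produces
trajectories whose mixing state evolves monotonically in a known direction.

Default study conditions: 250 sites per species in a 30 Angstrom cubic box
(number density ~0.019 per cubic Angstrom, typical of one site per small
solvent molecule).  All randomness comes from ``numpy.random.default_rng``
(PCG64) and is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .frames import ParticleFrame

__all__ = [
    "GeneratorConfig",
    "Repulsion",
    "make_chain_1d",
    "make_lattice_alternating",
    "make_slabs",
    "make_random",
    "brownian_trajectory",
    "generate",
]

DEFAULT_BOX = (30.0, 30.0, 30.0)
DEFAULT_N_PER_SPECIES = (250, 250)


@dataclass
class Repulsion:
    """Interspecies repulsive bias for the Brownian walker.

    ``strength`` is the displacement scale in Angstrom^2/ps applied along
    the pair axis, decaying as ``exp(-r / range_)``; pairs beyond
    ``4 * range_`` are ignored.
    """

    strength: float = 1.0
    range_: float = 2.5


@dataclass
class GeneratorConfig:
    """Fully explicit generator settings; the seed determines the output."""

    seed: int = 0
    n_per_species: tuple[int, ...] = DEFAULT_N_PER_SPECIES
    box: tuple[float, ...] = DEFAULT_BOX
    geometry: str = "random"  # chain_1d | slabs | random | lattice_alternating
    species: tuple[str, ...] = ("A", "B")
    pattern: str = "AAAAABBBBB"  # chain_1d only
    spacing: float = 1.0  # chain_1d / lattice only
    dynamics: dict = dc_field(default_factory=dict)


def make_chain_1d(pattern: str, spacing: float = 1.0) -> ParticleFrame:
    """One-dimensional chain of sites at 0, spacing, 2*spacing, ...

    The species of site ``k`` is ``pattern[k]``; the periodic box length is
    ``len(pattern) * spacing`` so the chain tiles seamlessly.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    coords = (np.arange(len(pattern)) * spacing)[:, None]
    species = np.array(list(pattern), dtype=object)
    return ParticleFrame(coords, species, [len(pattern) * spacing])


def make_lattice_alternating(n_cells: int = 4, spacing: float = 2.5,
                             species: Sequence[str] = ("A", "B")
                             ) -> ParticleFrame:
    """Simple-cubic lattice with strictly alternating (checkerboard) species."""
    if len(species) != 2:
        raise ValueError("alternating lattice requires exactly two species")
    idx = np.stack(
        np.meshgrid(*[np.arange(n_cells)] * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    coords = (idx + 0.5) * spacing
    parity = idx.sum(axis=1) % 2
    labels = np.where(parity == 0, species[0], species[1]).astype(object)
    box = np.full(3, n_cells * spacing)
    return ParticleFrame(coords, labels, box)


def _uniform(rng, n, box):
    return rng.random((n, len(box))) * np.asarray(box)


def make_slabs(n_per_species: Sequence[int] = DEFAULT_N_PER_SPECIES,
               box: Sequence[float] = DEFAULT_BOX, seed: int = 0,
               species: Sequence[str] = ("A", "B"),
               axis: int = -1) -> ParticleFrame:
    """Fully separated phases: one uniform slab per species along ``axis``."""
    if len(n_per_species) != len(species):
        raise ValueError("one site count per species is required")
    if any(n < 1 for n in n_per_species):
        raise ValueError("site counts must be >= 1")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    axis = axis % len(box)
    n_species = len(species)
    slab = box[axis] / n_species
    coords, labels = [], []
    for k, (n, s) in enumerate(zip(n_per_species, species)):
        pts = _uniform(rng, n, box)
        pts[:, axis] = k * slab + rng.random(n) * slab
        coords.append(pts)
        labels.extend([s] * n)
    return ParticleFrame(np.concatenate(coords), np.array(labels, dtype=object),
                         box, time=0.0)


def make_random(n_per_species: Sequence[int] = DEFAULT_N_PER_SPECIES,
                box: Sequence[float] = DEFAULT_BOX, seed: int = 0,
                species: Sequence[str] = ("A", "B")) -> ParticleFrame:
    """Ideal-gas random mixture: every species uniform over the whole box."""
    if len(n_per_species) != len(species):
        raise ValueError("one site count per species is required")
    if any(n < 1 for n in n_per_species):
        raise ValueError("site counts must be >= 1")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    coords = _uniform(rng, int(np.sum(n_per_species)), box)
    labels = np.concatenate(
        [np.full(n, s, dtype=object) for n, s in zip(n_per_species, species)]
    )
    return ParticleFrame(coords, labels, box, time=0.0)


def brownian_trajectory(start: ParticleFrame, n_steps: int,
                        dt: float = 0.5, diffusion: float = 0.05,
                        seed: int = 0, repulsion: Repulsion | None = None,
                        stride: int = 1) -> list[ParticleFrame]:
    """Overdamped random walk under periodic wrapping (pseudo-trajectory).

    Displacements per step are ``sqrt(2 D dt)`` Gaussian per axis
    (``diffusion`` in Angstrom^2/ps, ``dt`` in ps).  With a
    :class:`Repulsion` bias, unlike-species pairs push each other apart and
    the system demixes; without it the walk mixes toward uniformity.
    Returns the frames at step 0, stride, 2*stride, ...; bit-reproducible
    for a given seed.
    """
    if dt <= 0 or diffusion < 0:
        raise ValueError("dt must be positive and diffusion non-negative")
    step_scale = np.sqrt(2.0 * diffusion * dt)
    if step_scale > min(start.box) / 4.0:
        raise ValueError(
            f"rms step {step_scale:.3g} exceeds a quarter box; reduce dt or "
            "the diffusion coefficient"
        )
    rng = np.random.default_rng(seed)
    box = start.box.astype(float)
    coords = start.coordinates.copy()
    species = start.species
    t0 = start.time or 0.0
    if repulsion is not None:
        labels = np.asarray([str(s) for s in species])
    frames = [ParticleFrame(coords.copy(), species.copy(), box.copy(),
                            start.periodic.copy(), t0,
                            None if start.elements is None
                            else start.elements.copy())]
    for step in range(1, n_steps + 1):
        disp = rng.normal(scale=step_scale, size=coords.shape) \
            if diffusion > 0 else np.zeros_like(coords)
        if repulsion is not None and repulsion.strength > 0:
            disp += _repulsion_bias(coords, labels, box, repulsion, dt)
        coords = np.mod(coords + disp, box)
        if step % stride == 0:
            frames.append(
                ParticleFrame(coords.copy(), species.copy(), box.copy(),
                              start.periodic.copy(), t0 + step * dt,
                              None if start.elements is None
                              else start.elements.copy())
            )
    return frames


def _repulsion_bias(coords, labels, box, repulsion: Repulsion,
                    dt: float) -> np.ndarray:
    cutoff = 4.0 * repulsion.range_
    tree = cKDTree(coords, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    bias = np.zeros_like(coords)
    if len(pairs) == 0:
        return bias
    i, j = pairs[:, 0], pairs[:, 1]
    unlike = labels[i] != labels[j]
    i, j = i[unlike], j[unlike]
    if len(i) == 0:
        return bias
    delta = coords[i] - coords[j]
    delta -= box * np.round(delta / box)
    r = np.linalg.norm(delta, axis=1)
    r = np.maximum(r, 1e-6)
    mag = repulsion.strength * dt * np.exp(-r / repulsion.range_)
    push = delta / r[:, None] * mag[:, None]
    np.add.at(bias, i, push)
    np.add.at(bias, j, -push)
    return bias


def generate(config: GeneratorConfig) -> ParticleFrame:
    """Dispatch on ``config.geometry``; dynamics are applied by the caller."""
    if config.geometry == "chain_1d":
        return make_chain_1d(config.pattern, config.spacing)
    if config.geometry == "lattice_alternating":
        return make_lattice_alternating(spacing=config.spacing,
                                        species=config.species[:2])
    if config.geometry == "slabs":
        return make_slabs(config.n_per_species, config.box, config.seed,
                          config.species)
    if config.geometry == "random":
        return make_random(config.n_per_species, config.box, config.seed,
                           config.species)
    raise ValueError(f"unknown geometry {config.geometry!r}")
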