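"""Particle frames and Gaussian broadening settings.

A :class:`ParticleFrame` is one snapshot of a particle system: site
coordinates in an orthorhombic (or lower-dimensional) periodic box, with a
mixture-component label per site.  All internal lengths are Angstrom and all
times picoseconds.  A :class:`BroadeningSpec` carries the Gaussian width
``sigma`` assigned to each site (physically, close to the van der Waals
radius of the underlying atom) together with the kernel truncation policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ParticleFrame",
    "BroadeningSpec",
    "BONDI_RADII",
    "DEFAULT_SIGMA",
]

#: Bondi van der Waals radii in Angstrom, used as per-element default widths.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Ne": 1.54, "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88,
    "Br": 1.85, "Kr": 2.02, "I": 1.98, "Xe": 2.16,
}

#: Fallback Gaussian width (Angstrom) for sites without element information:
#: a typical heavy-atom van der Waals radius.
DEFAULT_SIGMA: float = 1.5


def _as_array(x, dtype=float) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(x, dtype=dtype))


@dataclass
class ParticleFrame:
    """One snapshot of site coordinates, box vectors and species labels.

    Parameters
    ----------
    coordinates
        ``(n_sites, ndim)`` array of positions in Angstrom.  ``ndim`` may be
        1, 2 or 3; one-dimensional model chains are first-class citizens.
    species
        ``(n_sites,)`` array of component labels (e.g. ``"A"``, ``"B"``).
    box
        ``(ndim,)`` strictly positive orthorhombic box lengths in Angstrom.
    periodic
        Per-axis periodicity flags; defaults to fully periodic.
    time
        Optional frame time in picoseconds.
    elements
        Optional per-site element symbols; used to look up default Gaussian
        widths from the Bondi table.
    """

    coordinates: np.ndarray
    species: np.ndarray
    box: np.ndarray
    periodic: np.ndarray | None = None
    time: float | None = None
    elements: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(_as_array(self.coordinates))
        self.species = np.asarray(self.species, dtype=object)
        self.box = np.atleast_1d(_as_array(self.box))
        if self.coordinates.ndim != 2:
            raise ValueError("coordinates must be an (n_sites, ndim) array")
        n, d = self.coordinates.shape
        if d not in (1, 2, 3):
            raise ValueError(f"ndim must be 1, 2 or 3, got {d}")
        if self.box.shape != (d,):
            raise ValueError(f"box must have {d} lengths, got {self.box.shape}")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be strictly positive")
        if self.species.shape != (n,):
            raise ValueError("species must have one label per site")
        if self.periodic is None:
            self.periodic = np.ones(d, dtype=bool)
        else:
            self.periodic = np.atleast_1d(np.asarray(self.periodic, dtype=bool))
            if self.periodic.shape != (d,):
                raise ValueError("periodic flags must match ndim")
        if self.elements is not None:
            self.elements = np.asarray(self.elements, dtype=object)
            if self.elements.shape != (n,):
                raise ValueError("elements must have one symbol per site")
        # wrap into [0, box) on periodic axes
        coords = self.coordinates
        per = self.periodic
        coords[:, per] = np.mod(coords[:, per], self.box[per])
        on_fixed = coords[:, ~per]
        if on_fixed.size and (
            np.any(on_fixed < 0) or np.any(on_fixed >= self.box[~per])
        ):
            raise ValueError("coordinates outside box on a non-periodic axis")

    # -- basic geometry -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.coordinates.shape[0]

    @property
    def ndim(self) -> int:
        return self.coordinates.shape[1]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def species_names(self) -> tuple[str, ...]:
        """Distinct species labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.species:
            seen.setdefault(str(s), None)
        return tuple(seen)

    def counts(self) -> dict[str, int]:
        return {s: int(np.sum(self.species == s)) for s in self.species_names}

    def global_fractions(self) -> dict[str, float]:
        n = self.n_sites
        return {s: c / n for s, c in self.counts().items()}

    def sites_of(self, species: str) -> np.ndarray:
        """Coordinates of all sites belonging to one species."""
        return self.coordinates[self.species == species]

    # -- derived frames -------------------------------------------------

    def shifted(self, vector) -> "ParticleFrame":
        """Translate all sites by ``vector`` and rewrap (periodic axes)."""
        vector = _as_array(vector)
        return ParticleFrame(
            self.coordinates + vector,
            self.species.copy(),
            self.box.copy(),
            self.periodic.copy(),
            self.time,
            None if self.elements is None else self.elements.copy(),
        )

    def tiled(self, reps: int = 2) -> "ParticleFrame":
        """Replicate the frame ``reps`` times along every axis."""
        d = self.ndim
        shifts = np.stack(
            np.meshgrid(*[np.arange(reps)] * d, indexing="ij"), axis=-1
        ).reshape(-1, d)
        coords = np.concatenate(
            [self.coordinates + s * self.box for s in shifts]
        )
        species = np.concatenate([self.species] * len(shifts))
        elements = (
            None
            if self.elements is None
            else np.concatenate([self.elements] * len(shifts))
        )
        return ParticleFrame(
            coords, species, self.box * reps, self.periodic.copy(),
            self.time, elements,
        )


@dataclass
class BroadeningSpec:
    """Per-site Gaussian widths and kernel truncation policy.

    ``sigma`` may be a scalar (same width for every site), a mapping from
    species label to width, a per-site array, or ``None``.  With ``None``,
    widths are looked up per element from the Bondi van der Waals table when
    the frame carries element symbols, falling back to :data:`DEFAULT_SIGMA`.

    Kernel contributions beyond ``cutoff_multiple * sigma`` from a site are
    dropped; the neglected Gaussian mass is below ``exp(-cutoff_multiple^2/2)``
    relative in any dimension.
    """

    sigma: float | Mapping[str, float] | Sequence[float] | None = None
    cutoff_multiple: float = 4.0
    kernel: str = "gaussian"

    def __post_init__(self) -> None:
        if self.cutoff_multiple < 3:
            raise ValueError("cutoff_multiple must be >= 3")
        if self.kernel != "gaussian":
            raise NotImplementedError(
                f"kernel {self.kernel!r} is not implemented (only 'gaussian')"
            )
        if np.isscalar(self.sigma) and self.sigma is not None:
            if float(self.sigma) <= 0:
                raise ValueError("sigma must be strictly positive")

    def site_sigmas(self, frame: ParticleFrame) -> np.ndarray:
        """Resolve the per-site width array for ``frame``."""
        n = frame.n_sites
        if self.sigma is None:
            if frame.elements is not None:
                out = np.array(
                    [
                        BONDI_RADII.get(str(e).capitalize(), DEFAULT_SIGMA)
                        for e in frame.elements
                    ]
                )
            else:
                out = np.full(n, DEFAULT_SIGMA)
        elif isinstance(self.sigma, Mapping):
            try:
                out = np.array([float(self.sigma[str(s)]) for s in frame.species])
            except KeyError as exc:
                raise KeyError(f"no sigma given for species {exc.args[0]!r}") from exc
        elif np.isscalar(self.sigma):
            out = np.full(n, float(self.sigma))
        else:
            out = _as_array(self.sigma)
            if out.shape != (n,):
                raise ValueError("per-site sigma array must match n_sites")
        if not np.all(out > 0):
            raise ValueError("sigma must be strictly positive")
        return out
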