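"""Gaussian-broadened partial densities under periodic boundary conditions.

Each site of a species is replaced by a unit-normalised Gaussian of width
``sigma``; the partial density of species ``lambda`` is the sum of these
kernels over all its sites,

    rho_lambda(r) = sum_{i in lambda} (2 pi sigma_i^2)^(-d/2)
                    exp(-|r - R_i|^2 / (2 sigma_i^2)),

with distances taken to the nearest periodic image.  Unit normalisation makes
the box integral of each partial density equal to the number of sites of
that species, so molar fractions are ratios of particle densities.  Kernels
are truncated at ``cutoff_multiple * sigma``; when the truncation radius
exceeds half a box length, explicit periodic images are summed so the result
stays exact for arbitrarily broad kernels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .frames import BroadeningSpec, ParticleFrame

__all__ = [
    "DensityField",
    "Grid",
    "evaluate_density",
    "density_on_grid",
    "write_cube",
]

_CHUNK = 4096  # points per evaluation block, bounds peak memory


@dataclass
class Grid:
    """Scalar values at voxel centers of a regular grid spanning the box."""

    values: np.ndarray
    spacing: np.ndarray
    box: np.ndarray
    origin: np.ndarray  # coordinate of the first voxel center

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axes(self) -> list[np.ndarray]:
        """Voxel-center coordinates along each axis."""
        return [
            self.origin[a] + self.spacing[a] * np.arange(self.values.shape[a])
            for a in range(self.values.ndim)
        ]

    def integral(self) -> float:
        """Riemann-sum integral of the field over the box."""
        return float(self.values.sum() * self.voxel_volume)

    def points(self) -> np.ndarray:
        """All voxel centers as an ``(n_voxels, ndim)`` array."""
        mesh = np.meshgrid(*self.axes(), indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)


class DensityField:
    """Broadened partial density of one species in a frame.

    Parameters
    ----------
    frame
        The particle snapshot.
    spec
        Gaussian widths and truncation policy.
    species
        Label of the component this field represents.  The species may have
        zero sites (the field is then identically zero); an unknown label is
        only an error when the caller requires a declared species.
    """

    def __init__(self, frame: ParticleFrame, spec: BroadeningSpec, species: str):
        self.frame = frame
        self.spec = spec
        self.species = str(species)
        mask = frame.species == self.species
        self.sites = frame.coordinates[mask]
        self.sigmas = spec.site_sigmas(frame)[mask]

    @property
    def n_sites(self) -> int:
        return self.sites.shape[0]

    def peak_site_density(self) -> float:
        """Largest possible single-kernel amplitude, ``(2 pi s^2)^(-d/2)``."""
        if self.n_sites == 0:
            return 0.0
        d = self.frame.ndim
        s = float(self.sigmas.min())
        return float((2.0 * np.pi * s * s) ** (-d / 2.0))

    # -- point evaluation ----------------------------------------------

    def _wrap_points(self, points: np.ndarray) -> np.ndarray:
        frame = self.frame
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != frame.ndim:
            raise ValueError(f"points must be {frame.ndim}-vectors")
        pts = pts.copy()
        per = frame.periodic
        pts[:, per] = np.mod(pts[:, per], frame.box[per])
        fixed = pts[:, ~per]
        if fixed.size and (np.any(fixed < 0) or np.any(fixed >= frame.box[~per])):
            raise ValueError("point outside box on a non-periodic axis")
        return pts

    def _image_shifts(self) -> np.ndarray:
        """Lattice shifts around the minimum image needed for broad kernels."""
        frame = self.frame
        if self.n_sites == 0:
            return np.zeros((1, frame.ndim))
        cut_max = self.spec.cutoff_multiple * float(self.sigmas.max())
        offsets = []
        for a in range(frame.ndim):
            L = frame.box[a]
            if frame.periodic[a] and cut_max > L / 2.0:
                k = int(np.ceil(cut_max / L + 0.5))
                offsets.append(np.arange(-k, k + 1) * L)
            else:
                offsets.append(np.zeros(1))
        return np.array(list(itertools.product(*offsets)))

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Density at arbitrary points (minimum image plus extra images)."""
        pts = self._wrap_points(points)
        out = np.zeros(pts.shape[0])
        if self.n_sites == 0:
            return out
        frame = self.frame
        d = frame.ndim
        sig2 = self.sigmas**2
        cut2 = (self.spec.cutoff_multiple * self.sigmas) ** 2
        norm = (2.0 * np.pi * sig2) ** (-d / 2.0)
        box = frame.box
        per = frame.periodic
        shifts = self._image_shifts()
        for lo in range(0, pts.shape[0], _CHUNK):
            block = pts[lo : lo + _CHUNK]
            delta = block[:, None, :] - self.sites[None, :, :]
            delta[..., per] -= box[per] * np.round(delta[..., per] / box[per])
            acc = np.zeros((block.shape[0], self.n_sites))
            for shift in shifts:
                r2 = ((delta + shift) ** 2).sum(axis=-1)
                w = np.exp(-0.5 * r2 / sig2) * norm
                w[r2 > cut2] = 0.0
                acc += w
            out[lo : lo + _CHUNK] = acc.sum(axis=1)
        return out

    # -- grid rasterisation --------------------------------------------

    def on_grid(self, resolution: float) -> Grid:
        """Rasterise the density at voxel centers of a regular grid.

        The grid spacing is the box length divided by the nearest integer
        voxel count, so periodic wrapping is commensurate.  Accumulation is
        per-site over a local stencil; stencils wider than the box wrap and
        legitimately deposit several periodic images into the same voxel.
        """
        if resolution is None or resolution <= 0:
            raise ValueError("resolution must be a positive grid spacing")
        frame = self.frame
        d = frame.ndim
        n = np.maximum(1, np.round(frame.box / resolution).astype(int))
        spacing = frame.box / n
        if self.n_sites and spacing.max() > float(self.sigmas.min()):
            warnings.warn(
                "grid spacing exceeds the smallest sigma; the kernel is "
                "under-resolved",
                RuntimeWarning,
                stacklevel=2,
            )
        values = np.zeros(n)
        cuts = self.spec.cutoff_multiple * self.sigmas
        norms = (2.0 * np.pi * self.sigmas**2) ** (-d / 2.0)
        for site, sig, cut, amp in zip(self.sites, self.sigmas, cuts, norms):
            idx_axes = []
            d2_axes = []
            safe_fancy = True
            for a in range(d):
                h = spacing[a]
                j0 = int(np.ceil((site[a] - cut) / h - 0.5))
                j1 = int(np.floor((site[a] + cut) / h - 0.5))
                idx = np.arange(j0, j1 + 1)
                dx = (idx + 0.5) * h - site[a]
                if frame.periodic[a]:
                    if idx.size > n[a]:
                        safe_fancy = False
                    idx = np.mod(idx, n[a])
                else:
                    keep = (idx >= 0) & (idx < n[a])
                    idx, dx = idx[keep], dx[keep]
                idx_axes.append(idx)
                d2_axes.append(dx * dx)
            if any(ix.size == 0 for ix in idx_axes):
                continue
            r2 = sum(
                d2.reshape([-1 if k == a else 1 for k in range(d)])
                for a, d2 in enumerate(d2_axes)
            )
            block = amp * np.exp(-0.5 * r2 / (sig * sig))
            block[r2 > cut * cut] = 0.0
            if safe_fancy:
                values[np.ix_(*idx_axes)] += block
            else:
                np.add.at(values, np.ix_(*idx_axes), block)
        return Grid(values, spacing, frame.box.copy(), spacing / 2.0)


def evaluate_density(field: DensityField, points) -> np.ndarray:
    """Partial density of ``field`` at the given points (length^-d units)."""
    return field.evaluate(points)


def density_on_grid(field: DensityField, resolution: float) -> Grid:
    """Rasterise ``field`` on a regular grid of the requested spacing."""
    return field.on_grid(resolution)


_BOHR_PER_ANGSTROM = 1.8897261254578281
_ELEMENT_NUMBERS = {
    "H": 1, "He": 2, "C": 6, "N": 7, "O": 8, "F": 9, "Ne": 10, "Si": 14,
    "P": 15, "S": 16, "Cl": 17, "Ar": 18, "Br": 35, "Kr": 36, "I": 53,
    "Xe": 54,
}


def write_cube(path, grid: Grid, frame: ParticleFrame | None = None,
               comment: str = "mixent scalar field") -> None:
    """Write a 3-D grid as a Gaussian cube file (lengths in Bohr, C order).

    When a frame is supplied, its sites are written as the atom records
    (element numbers looked up when available, otherwise helium as a neutral
    placeholder) so the field can be visualised on top of the structure.
    """
    if grid.values.ndim != 3:
        raise ValueError("cube export requires a 3-D grid")
    b = _BOHR_PER_ANGSTROM
    nx, ny, nz = grid.values.shape
    natoms = 0 if frame is None else frame.n_sites
    lines = [comment, "generated by mixent"]
    ox, oy, oz = grid.origin * b
    lines.append(f"{natoms:5d} {ox:11.6f} {oy:11.6f} {oz:11.6f}")
    for a, count in zip(range(3), (nx, ny, nz)):
        vec = [0.0, 0.0, 0.0]
        vec[a] = grid.spacing[a] * b
        lines.append(
            f"{count:5d} {vec[0]:11.6f} {vec[1]:11.6f} {vec[2]:11.6f}"
        )
    if frame is not None:
        for i in range(frame.n_sites):
            el = None if frame.elements is None else str(frame.elements[i])
            z = _ELEMENT_NUMBERS.get((el or "").capitalize(), 2)
            x, y, zc = frame.coordinates[i] * b
            lines.append(f"{z:5d} {0.0:11.6f} {x:11.6f} {y:11.6f} {zc:11.6f}")
    flat = grid.values.reshape(nx * ny, nz)
    for row in range(nx * ny):
        vals = flat[row]
        for lo in range(0, nz, 6):
            lines.append(
                " ".join(f"{v: .5E}" for v in vals[lo : lo + 6])
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
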