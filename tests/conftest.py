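import numpy as np
import pytest

from mixent import BroadeningSpec, ParticleFrame


@pytest.fixture
def single_site_frame():
    """One site at the origin of a 10 Angstrom cubic periodic box."""
    return ParticleFrame(np.array([[0.0, 0.0, 0.0]]), ["A"], [10.0, 10.0, 10.0])


@pytest.fixture
def two_species_frame():
    """One A and one B site 2 Angstrom apart along x."""
    return ParticleFrame(
        np.array([[4.0, 5.0, 5.0], [6.0, 5.0, 5.0]]), ["A", "B"],
        [10.0, 10.0, 10.0],
    )


@pytest.fixture
def unit_spec():
    return BroadeningSpec(sigma=1.0)


def gro_lines(time_ps, rows, box_nm):
    """Format one GRO frame; rows are (resid, resname, name, x, y, z) in nm."""
    lines = [f"synthetic mixture t= {time_ps:.3f}", f"{len(rows):>5d}"]
    for i, (resid, resname, name, x, y, z) in enumerate(rows, start=1):
        lines.append(
            f"{resid:>5d}{resname:<5s}{name:>5s}{i:>5d}{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    lines.append(f"{box_nm[0]:10.5f}{box_nm[1]:10.5f}{box_nm[2]:10.5f}")
    return "\n".join(lines) + "\n"


def brute_force_density(points, sites, sigma, box, cutoff_multiple=6.0,
                        n_images=1):
    """Independent all-images Gaussian sum (reference oracle for tests)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    box = np.asarray(box, dtype=float)
    d = points.shape[1]
    norm = (2.0 * np.pi * sigma**2) ** (-d / 2.0)
    cut2 = (cutoff_multiple * sigma) ** 2
    out = np.zeros(len(points))
    images = np.stack(
        np.meshgrid(*[np.arange(-n_images, n_images + 1)] * d, indexing="ij"),
        axis=-1,
    ).reshape(-1, d)
    for site in sites:
        for img in images:
            delta = points - (site + img * box)
            r2 = (delta**2).sum(axis=1)
            w = norm * np.exp(-0.5 * r2 / sigma**2)
            w[r2 > cut2] = 0.0
            out += w
    return out
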