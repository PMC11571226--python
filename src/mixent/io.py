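"""Reading coordinate frames, assigning species, and trace serialization.

Supported inputs are plain/extended XYZ, GRO and PDB, read through
MDAnalysis (XYZ, PDB, GRO topology) and mdtraj (multi-frame GRO
coordinates).  All coordinates are converted to Angstrom internally (GRO
nanometres are scaled on read) and boxes must be orthorhombic.  Species are
assigned per residue/molecule through an ordered rule list, so every atom
inherits the component of its residue.

Entropy traces — time series of the instantaneous entropy of mixing — are
written as CSV with a commented metadata preamble and round-trip losslessly.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field as dc_field
from fnmatch import fnmatchcase
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .frames import BONDI_RADII, ParticleFrame

__all__ = [
    "SpeciesAssignment",
    "EntropyTrace",
    "read_frames",
    "write_xyz",
    "write_trace",
    "read_trace",
]


# -- species assignment --------------------------------------------------


@dataclass
class SpeciesAssignment:
    """Ordered rules mapping residues/atoms to mixture components.

    Each rule is a ``(selector, species)`` pair.  Selectors take the forms
    ``"resname:PATTERN"``, ``"name:PATTERN"`` (shell-style wildcards) or
    ``"index:LO-HI"`` (inclusive atom-index range); a bare pattern matches
    against the residue name first and the atom name second.  The first
    matching rule wins; sites matching no rule fall back to
    ``default_species`` or raise an error naming the offending atom.
    """

    rules: Sequence[tuple[str, str]] = dc_field(default_factory=list)
    default_species: str | None = None

    @classmethod
    def from_mapping(cls, mapping: dict[str, str],
                     default_species: str | None = None) -> "SpeciesAssignment":
        """Convenience constructor from ``{selector: species}``."""
        return cls(list(mapping.items()), default_species)

    @staticmethod
    def _matches(selector: str, resname: str, name: str, index: int) -> bool:
        if ":" in selector:
            kind, _, pattern = selector.partition(":")
            kind = kind.strip().lower()
            pattern = pattern.strip()
            if kind == "resname":
                return fnmatchcase(resname, pattern)
            if kind == "name":
                return fnmatchcase(name, pattern)
            if kind == "index":
                lo, _, hi = pattern.partition("-")
                lo_i = int(lo)
                hi_i = int(hi) if hi else lo_i
                return lo_i <= index <= hi_i
            raise ValueError(f"unknown selector kind {kind!r}")
        return fnmatchcase(resname, selector) or fnmatchcase(name, selector)

    def assign(self, resnames: Sequence[str], names: Sequence[str]
               ) -> np.ndarray:
        """Species label per site; raises on any unassignable site."""
        labels = np.empty(len(names), dtype=object)
        for i, (rn, nm) in enumerate(zip(resnames, names)):
            for selector, species in self.rules:
                if self._matches(selector, str(rn), str(nm), i):
                    labels[i] = species
                    break
            else:
                if self.default_species is not None:
                    labels[i] = self.default_species
                else:
                    raise ValueError(
                        f"atom {i} (residue {rn!r}, name {nm!r}) matches no "
                        "species rule and no default species is set"
                    )
        return labels


def _element_from_name(name: str) -> str | None:
    """Best-effort element symbol from an atom name (e.g. ``'C1' -> 'C'``)."""
    stripped = re.sub(r"[^A-Za-z]", "", str(name))
    if not stripped:
        return None
    two = stripped[:2].capitalize()
    if two in BONDI_RADII:
        return two
    one = stripped[:1].upper()
    return one if one in BONDI_RADII else None


# -- frame reading -------------------------------------------------------


_LATTICE_RE = re.compile(r'Lattice\s*=\s*"([^"]+)"')
_DIM_RE = re.compile(r"mixent_dim\s*=\s*(\d)")


def _orthorhombic_box(lengths, angles=None) -> np.ndarray:
    lengths = np.asarray(lengths, dtype=float)
    if angles is not None and not np.allclose(angles, 90.0, atol=1e-3):
        raise ValueError(
            f"triclinic boxes are not supported (angles {angles})"
        )
    if not np.all(lengths > 0):
        raise ValueError("box information missing or degenerate; "
                         "supply an explicit box")
    return lengths


def _xyz_comment_info(path) -> tuple[np.ndarray | None, int]:
    """Box (from an extended-XYZ Lattice entry) and dimensionality hint."""
    with open(path) as fh:
        fh.readline()
        comment = fh.readline()
    box = None
    m = _LATTICE_RE.search(comment)
    if m:
        cell = np.array([float(v) for v in m.group(1).split()]).reshape(3, 3)
        if not np.allclose(cell - np.diag(np.diag(cell)), 0.0, atol=1e-8):
            raise ValueError("non-orthorhombic Lattice in XYZ comment")
        box = np.diag(cell).copy()
    dm = _DIM_RE.search(comment)
    return box, int(dm.group(1)) if dm else 3


def _infer_format(path, format: str | None) -> str:
    if format:
        return format.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("xyz", "gro", "pdb"):
        return suffix
    raise ValueError(f"cannot infer format from {path!r}; pass format=")


def read_frames(path, format: str | None = None,
                assignment: SpeciesAssignment | None = None,
                box=None) -> Iterator[ParticleFrame]:
    """Lazily read frames from an XYZ, GRO or PDB file.

    ``box`` (Angstrom lengths) overrides or supplies missing box
    information; XYZ files may instead carry an extended-XYZ ``Lattice``
    comment.  Without an ``assignment`` every residue name (atom name for
    XYZ) becomes its own species.
    """
    fmt = _infer_format(path, format)
    if fmt == "gro":
        yield from _read_gro(path, assignment, box)
    elif fmt in ("xyz", "pdb"):
        yield from _read_mda(path, fmt, assignment, box)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def _labels_and_elements(resnames, names, assignment):
    if assignment is None:
        labels = np.asarray([str(r) for r in resnames], dtype=object)
    else:
        labels = assignment.assign(resnames, names)
    elements = np.asarray([_element_from_name(n) for n in names], dtype=object)
    if any(e is None for e in elements):
        elements = None
    return labels, elements


def _read_mda(path, fmt, assignment, box) -> Iterator[ParticleFrame]:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), topology_format=fmt.upper(),
                         format=fmt.upper())
    names = [str(n) for n in u.atoms.names]
    resnames = (
        [str(r) for r in u.atoms.resnames]
        if hasattr(u.atoms, "resnames") else list(names)
    )
    labels, elements = _labels_and_elements(resnames, names, assignment)
    ndim = 3
    file_box = None
    if fmt == "xyz":
        file_box, ndim = _xyz_comment_info(path)
    warnings.filterwarnings(
        "ignore", message="Reader has no dt information",
        category=UserWarning,
    )
    for ts in u.trajectory:
        if box is not None:
            frame_box = _orthorhombic_box(np.broadcast_to(box, (3,)))
        elif fmt == "xyz":
            if file_box is None:
                raise ValueError(
                    "XYZ file has no Lattice comment; supply box= explicitly"
                )
            frame_box = file_box
        else:
            if ts.dimensions is None:
                raise ValueError(
                    f"{path}: no box information (missing CRYST1?); "
                    "supply box= explicitly"
                )
            frame_box = _orthorhombic_box(ts.dimensions[:3], ts.dimensions[3:])
        coords = np.asarray(ts.positions, dtype=float)[:, :ndim]
        yield ParticleFrame(
            coords, labels.copy(), np.asarray(frame_box)[:ndim],
            time=float(ts.time), elements=elements,
        )


def _read_gro(path, assignment, box) -> Iterator[ParticleFrame]:
    import MDAnalysis as mda
    import mdtraj

    # topology (verbatim residue/atom names) from the first frame
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    names = [str(n) for n in u.atoms.names]
    resnames = [str(r) for r in u.atoms.resnames]
    labels, elements = _labels_and_elements(resnames, names, assignment)
    traj = mdtraj.load(str(path))
    for i in range(traj.n_frames):
        if box is not None:
            frame_box = _orthorhombic_box(np.broadcast_to(box, (3,)))
        else:
            if traj.unitcell_lengths is None:
                raise ValueError(f"{path}: GRO box line missing")
            frame_box = _orthorhombic_box(
                traj.unitcell_lengths[i] * 10.0,
                traj.unitcell_angles[i] if traj.unitcell_angles is not None
                else None,
            )
        yield ParticleFrame(
            np.asarray(traj.xyz[i], dtype=float) * 10.0, labels.copy(),
            frame_box, time=float(traj.time[i]), elements=elements,
        )


# -- frame writing -------------------------------------------------------


def write_xyz(path, frames: ParticleFrame | Iterable[ParticleFrame]) -> None:
    """Write frames as extended XYZ with a ``Lattice`` comment.

    Species labels are written in the atom-name column.  Frames of
    dimensionality below three are padded with zero transverse coordinates
    and unit transverse box lengths; a ``mixent_dim`` tag in the comment
    lets :func:`read_frames` restore the original dimensionality.
    """
    if isinstance(frames, ParticleFrame):
        frames = [frames]
    lines: list[str] = []
    for frame in frames:
        d = frame.ndim
        box3 = np.ones(3)
        box3[:d] = frame.box
        cell = np.diag(box3).ravel()
        lattice = " ".join(f"{v:.8g}" for v in cell)
        tags = [f'Lattice="{lattice}"',
                'Properties=species:S:1:pos:R:3']
        if d != 3:
            tags.append(f"mixent_dim={d}")
        if frame.time is not None:
            tags.append(f"Time={frame.time:.6g}")
        lines.append(str(frame.n_sites))
        lines.append(" ".join(tags))
        coords3 = np.zeros((frame.n_sites, 3))
        coords3[:, :d] = frame.coordinates
        for s, xyz in zip(frame.species, coords3):
            lines.append(
                f"{s} {xyz[0]:.10g} {xyz[1]:.10g} {xyz[2]:.10g}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# -- entropy traces ------------------------------------------------------


@dataclass
class EntropyTrace:
    """Time series of the entropy of mixing along a trajectory.

    ``times`` are picoseconds and must be strictly increasing; ``values``
    are in units of R.  ``metadata`` records the settings (sigma, method,
    box, seed, ...) that produced the trace.
    """

    times: np.ndarray
    values: np.ndarray
    frame_indices: np.ndarray
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if not (len(self.times) == len(self.values) == len(self.frame_indices)):
            raise ValueError("times, values and frame_indices must align")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EntropyTrace):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.frame_indices, other.frame_indices)
            and self.metadata == other.metadata
        )

    def rescaled_times(self, factor: float) -> "EntropyTrace":
        return EntropyTrace(self.times * factor, self.values.copy(),
                            self.frame_indices.copy(), dict(self.metadata))


_TRACE_HEADER = "time_ps,delta_S_R,frame_index"


def write_trace(trace: EntropyTrace, path) -> None:
    """Write a trace as CSV with a ``# meta`` preamble; lossless round-trip."""
    lines = ["# mixent-trace-v1"]
    for key in trace.metadata:
        lines.append(f"# meta {key} = {json.dumps(trace.metadata[key])}")
    lines.append(_TRACE_HEADER)
    for t, v, i in zip(trace.times, trace.values, trace.frame_indices):
        lines.append(f"{float(t)!r},{float(v)!r},{int(i)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_trace(path) -> EntropyTrace:
    """Read a trace written by :func:`write_trace`."""
    metadata: dict = {}
    times: list[float] = []
    values: list[float] = []
    indices: list[int] = []
    seen_header = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("meta "):
                    key, _, value = body[5:].partition("=")
                    metadata[key.strip()] = json.loads(value.strip())
                continue
            if not seen_header:
                if line != _TRACE_HEADER:
                    raise ValueError(f"unexpected trace header: {line!r}")
                seen_header = True
                continue
            t, v, i = line.split(",")
            times.append(float(t))
            values.append(float(v))
            indices.append(int(i))
    if not seen_header:
        raise ValueError(f"{path} is not a mixent trace file")
    return EntropyTrace(np.array(times), np.array(values),
                        np.array(indices, dtype=int), metadata)
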