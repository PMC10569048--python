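"""Core in-memory containers shared by every analysis stage.

All coordinates are Å, times ps, charges e, masses amu.  Boxes are
orthorhombic, given as the three edge lengths (Lx, Ly, Lz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric inputs."""


class EmptySelectionError(ValueError):
    """Raised when a named atom group resolves to no atoms."""


@dataclass
class LabeledStructure:
    """Atom coordinates with names, residue labels, charges and masses.

    ``groups`` maps semantic group names (``phosphate_backbone``,
    ``major_groove``, ``minor_groove``, ``water``, ``ion:MG`` ...,
    ``helix1``, ``helix2``) to integer index arrays into the atom table.
    """

    positions: np.ndarray          # (N, 3) Å
    names: np.ndarray              # (N,) str
    resnames: np.ndarray           # (N,) str
    resids: np.ndarray             # (N,) int
    charges: np.ndarray            # (N,) e
    masses: np.ndarray             # (N,) amu
    box: np.ndarray                # (3,) Å
    groups: Dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return int(self.positions.shape[0])

    def group(self, name: str) -> np.ndarray:
        """Return the index array for a named group; error if empty/absent."""
        idx = self.groups.get(name)
        if idx is None or len(idx) == 0:
            raise EmptySelectionError(f"group {name!r} is empty or undefined")
        return np.asarray(idx, dtype=int)

    def subset(self, idx: np.ndarray) -> "LabeledStructure":
        idx = np.asarray(idx, dtype=int)
        remap = {v: i for i, v in enumerate(idx)}
        groups = {}
        for k, g in self.groups.items():
            kept = [remap[a] for a in g if a in remap]
            if kept:
                groups[k] = np.array(kept, dtype=int)
        return replace(
            self,
            positions=self.positions[idx],
            names=self.names[idx],
            resnames=self.resnames[idx],
            resids=self.resids[idx],
            charges=self.charges[idx],
            masses=self.masses[idx],
            groups=groups,
        )

    def concat(self, other: "LabeledStructure") -> "LabeledStructure":
        off = self.n_atoms
        groups = dict(self.groups)
        for k, g in other.groups.items():
            g = np.asarray(g, dtype=int) + off
            groups[k] = np.concatenate([groups[k], g]) if k in groups else g
        return LabeledStructure(
            positions=np.vstack([self.positions, other.positions]),
            names=np.concatenate([self.names, other.names]),
            resnames=np.concatenate([self.resnames, other.resnames]),
            resids=np.concatenate([self.resids, other.resids]),
            charges=np.concatenate([self.charges, other.charges]),
            masses=np.concatenate([self.masses, other.masses]),
            box=self.box.copy(),
            groups=groups,
            meta={**self.meta, **other.meta},
        )


@dataclass
class TrajectoryWindow:
    """A frame sequence over a fixed topology — the substrate of all
    ensemble averages.

    ``positions`` has shape (n_frames, n_atoms, 3); ``velocities`` is
    optional with the same shape (Å/ps); ``dt`` is the frame spacing in ps.
    """

    structure: LabeledStructure
    positions: np.ndarray
    velocities: Optional[np.ndarray] = None
    dt: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.positions.shape[1])

    @property
    def box(self) -> np.ndarray:
        return self.structure.box

    def frame(self, i: int) -> LabeledStructure:
        return replace(self.structure, positions=self.positions[i])

    @classmethod
    def single_frame(cls, structure: LabeledStructure,
                     velocities: Optional[np.ndarray] = None,
                     dt: float = 1.0) -> "TrajectoryWindow":
        vel = None if velocities is None else velocities[None, :, :]
        return cls(structure=structure,
                   positions=structure.positions[None, :, :],
                   velocities=vel, dt=dt)


@dataclass
class ScalarField3D:
    """Gridded scalar density (number or charge) on a regular lattice.

    ``values[i, j, k]`` is the density in the voxel whose lower corner is
    ``origin + spacing * (i, j, k)``; units count/Å^3 or e/Å^3.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    species: str = ""
    units: str = "count/A^3"

    @property
    def voxel_volume(self) -> float:
        return float(self.spacing ** 3)

    def integral(self) -> float:
        """Total content: sum(values) * voxel volume (mean particle count
        for a number density)."""
        return float(self.values.sum() * self.voxel_volume)


@dataclass
class RadialProfile:
    """A binned function of a radial coordinate (cylindrical λ, spherical
    r, or surface distance)."""

    edges: np.ndarray              # (n_bins+1,) Å, strictly increasing
    values: np.ndarray             # (n_bins,)
    kind: str = "cylindrical_concentration"
    units: str = ""
    counts: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.values) != len(self.edges) - 1:
            raise ValueError("values/edges length mismatch")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"bin_lo": self.edges[:-1],
                             "bin_hi": self.edges[1:],
                             "value": self.values})


def minimum_image(vectors: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors to the nearest periodic image
    (orthorhombic box)."""
    vectors = np.asarray(vectors, dtype=float)
    box = np.asarray(box, dtype=float)
    return vectors - box * np.round(vectors / box)


def fit_helix_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares straight-line fit through a point cloud.

    Returns (centroid, unit direction).  The direction is the principal
    component of the cloud, oriented toward +z.  Used to define the
    'center of the helix' for cylindrical profiles and interhelical
    distances.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise GeometryError("need at least 2 points to fit an axis")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if direction[2] < 0:
        direction = -direction
    return centroid, direction


def axis_distance_xy(c1: np.ndarray, c2: np.ndarray,
                     box: Optional[np.ndarray] = None) -> float:
    """Distance between two (assumed z-parallel) helix axes in the xy
    plane, minimum-image if a box is given."""
    d = np.asarray(c2[:2], float) - np.asarray(c1[:2], float)
    if box is not None:
        d = d - box[:2] * np.round(d / box[:2])
    return float(np.hypot(*d))
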