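"""Structure/trajectory/hills I/O and atom-group resolution.

Readers normalise everything to the internal unit system (Å, ps, e,
amu).  Structures round-trip through PDB/GRO, trajectories through
multi-frame XYZ, metadynamics hills through a plain-text dialect with
``#!`` header lines.  Partial charges and group assignments — which
PDB/GRO cannot carry — travel in a JSON sidecar written next to each
structure file.
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import LabeledStructure, TrajectoryWindow

logger = logging.getLogger("helixatmos")


class CorruptFileError(ValueError):
    """Raised when a file is truncated, shuffled or internally
    inconsistent."""


class FormatError(ValueError):
    """Raised on frame/topology mismatches or unsupported formats."""


# ---------------------------------------------------------------------------
# Hills
# ---------------------------------------------------------------------------

@dataclass
class HillSeries:
    """Deposited Gaussian bias records from a well-tempered run.

    One record per hill: deposit time (ps), center in (d, θ), widths
    (σ_d, σ_θ), height (kJ/mol).  A single bias factor γ applies to the
    whole series; ``np.inf`` means non-tempered (constant-height)
    metadynamics.
    """

    times: np.ndarray
    centers_d: np.ndarray          # nm
    centers_theta: np.ndarray      # rad
    sigma_d: np.ndarray            # nm
    sigma_theta: np.ndarray        # rad
    heights: np.ndarray            # kJ/mol
    bias_factor: float = 10.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("times", "centers_d", "centers_theta",
                     "sigma_d", "sigma_theta", "heights"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.times)
        for name in ("centers_d", "centers_theta", "sigma_d",
                     "sigma_theta", "heights"):
            if len(getattr(self, name)) != n:
                raise ValueError("hill record arrays have unequal lengths")
        if n and np.any(np.diff(self.times) <= 0):
            raise CorruptFileError("hill times are not strictly increasing")
        if n and (np.any(self.sigma_d <= 0) or np.any(self.sigma_theta <= 0)):
            raise ValueError("hill widths must be positive")
        if n and np.any(self.heights < 0):
            raise ValueError("hill heights must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def empty(cls, bias_factor: float = 10.0) -> "HillSeries":
        z = np.empty(0)
        return cls(z, z, z, z, z, z, bias_factor=bias_factor)


HILLS_FIELDS = ["time", "cv1", "cv2", "sigma1", "sigma2", "height", "biasf"]


def write_hills(series: HillSeries, path: str) -> None:
    """Write a HillSeries in the whitespace/'#!'-header hills dialect."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(HILLS_FIELDS) + "\n")
        fh.write("#! SET periodic_cv2 2pi\n")
        for i in range(len(series)):
            fh.write(
                f"{series.times[i]:.6f} {series.centers_d[i]:.9f} "
                f"{series.centers_theta[i]:.9f} {series.sigma_d[i]:.9f} "
                f"{series.sigma_theta[i]:.9f} {series.heights[i]:.9f} "
                f"{series.bias_factor:.6f}\n")


def read_hills(path: str) -> HillSeries:
    """Read a hills file; validates monotone time and positive widths.

    A missing ``biasf`` column falls back to the non-tempered
    interpretation (γ = ∞) with a logged warning.
    """
    fields = None
    rows: List[List[float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#!"):
                toks = line[2:].split()
                if toks and toks[0] == "FIELDS":
                    fields = toks[1:]
                continue
            if line.startswith("#"):
                continue
            try:
                vals = [float(t) for t in line.split()]
            except ValueError as exc:
                raise CorruptFileError(
                    f"{path}: unparsable hills line {ln}") from exc
            rows.append(vals)
    if fields is None:
        fields = HILLS_FIELDS
    ncv = sum(1 for f in fields if f.startswith(("cv", "d", "theta"))
              and not f.startswith("sigma"))
    if rows and len(set(len(r) for r in rows)) != 1:
        raise CorruptFileError(f"{path}: ragged hills rows")
    if rows and len(rows[0]) != len(fields):
        raise CorruptFileError(
            f"{path}: {len(rows[0])} columns but header names {len(fields)}")
    data = np.array(rows, dtype=float).reshape(len(rows), len(fields))
    col = {name: data[:, i] for i, name in enumerate(fields)}

    def pick(*names):
        for n in names:
            if n in col:
                return col[n]
        return None

    time = pick("time")
    cv1 = pick("cv1", "d")
    cv2 = pick("cv2", "theta")
    s1 = pick("sigma1", "sigma_d", "sigma_cv1")
    s2 = pick("sigma2", "sigma_theta", "sigma_cv2")
    h = pick("height")
    if any(v is None for v in (time, cv1, cv2, s1, s2, h)):
        raise CorruptFileError(f"{path}: missing required hills columns "
                               f"(have {fields})")
    bf = pick("biasf")
    if bf is None:
        logger.warning("%s: no bias-factor column; assuming non-tempered "
                       "metadynamics (gamma = inf)", path)
        bias_factor = np.inf
    else:
        u = np.unique(bf)
        if len(u) > 1:
            raise CorruptFileError(f"{path}: multiple bias factors {u}")
        bias_factor = float(u[0]) if len(u) else 10.0
    if len(time) == 0:
        return HillSeries.empty(bias_factor=bias_factor)
    _ = ncv  # two-CV dialect is the only one supported
    return HillSeries(time, cv1, cv2, s1, s2, h, bias_factor=bias_factor)


# ---------------------------------------------------------------------------
# Atom groups
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """A named atom group defined by (residue-name, atom-name) pairs.

    An atom-name of ``"*"`` matches any atom in the residue.
    """

    name: str
    selection: List[Tuple[str, str]]


#: Groove-atom dictionary for real nucleic-acid PDB input: ring/edge
#: atoms facing the major vs minor groove.  Overridable via GroupSpec.
MAJOR_GROOVE_ATOMS = {"N7", "O6", "N6", "O4", "C5M", "C7"}
MINOR_GROOVE_ATOMS = {"N3", "O2", "N2"}

#: Atom-name table for generated fixtures: name -> (charge e, mass amu,
#: group tags).  Phosphate pseudo-atoms carry the full -1e backbone
#: charge.
FIXTURE_ATOM_TABLE: Dict[str, Tuple[float, float, Tuple[str, ...]]] = {
    "P":   (-1.0, 94.97, ("phosphate_backbone",)),
    "MAJ": (0.0, 1.0, ("major_groove",)),
    "MIN": (0.0, 1.0, ("minor_groove",)),
    "OW":  (-0.834, 15.999, ("water", "water_oxygen")),
    "HW1": (0.417, 1.008, ("water", "water_hydrogen")),
    "HW2": (0.417, 1.008, ("water", "water_hydrogen")),
    "MG":  (2.0, 24.305, ("ion:MG",)),
    "NA":  (1.0, 22.990, ("ion:NA",)),
    "K":   (1.0, 39.098, ("ion:K",)),
    "CL":  (-1.0, 35.453, ("ion:CL",)),
    "SP":  (4.0, 202.34, ("ion:SP",)),
}

DNA_GROUPS = ("phosphate_backbone", "major_groove", "minor_groove")


def resolve_group(structure: LabeledStructure, spec: GroupSpec) -> np.ndarray:
    """Resolve a GroupSpec to a sorted atom-index array (pure: same
    topology + spec -> same set)."""
    mask = np.zeros(structure.n_atoms, dtype=bool)
    for resname, atname in spec.selection:
        m = structure.resnames == resname
        if atname != "*":
            m &= structure.names == atname
        mask |= m
    return np.nonzero(mask)[0]


def assign_fixture_groups(structure: LabeledStructure) -> None:
    """Populate ``structure.groups`` from the fixture atom-name table,
    keeping any helix1/helix2 assignments already present."""
    tags: Dict[str, list] = {}
    for i, nm in enumerate(structure.names):
        entry = FIXTURE_ATOM_TABLE.get(str(nm))
        if entry is None:
            continue
        for tag in entry[2]:
            tags.setdefault(tag, []).append(i)
    for tag, idx in tags.items():
        structure.groups[tag] = np.array(idx, dtype=int)
    dna = sorted(set(np.concatenate(
        [structure.groups.get(g, np.empty(0, int)) for g in DNA_GROUPS]
    ).astype(int)))
    if dna:
        structure.groups["dna"] = np.array(dna, dtype=int)


# ---------------------------------------------------------------------------
# Structures and trajectories (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _sidecar_path(path: str) -> str:
    return os.path.splitext(path)[0] + ".meta.json"


def _to_universe(structure: LabeledStructure,
                 positions: Optional[np.ndarray] = None,
                 velocities: Optional[np.ndarray] = None):
    import MDAnalysis as mda
    n = structure.n_atoms
    resids = np.asarray(structure.resids, dtype=int)
    # compress residues preserving order of first appearance
    uniq, inverse = np.unique(resids, return_inverse=True)
    u = mda.Universe.empty(
        n_atoms=n, n_residues=len(uniq), atom_resindex=inverse,
        residue_segindex=np.zeros(len(uniq), dtype=int),
        trajectory=True, velocities=velocities is not None)
    u.add_TopologyAttr("names", np.asarray(structure.names, dtype=object))
    resnames = np.empty(len(uniq), dtype=object)
    for i in range(len(uniq)):
        resnames[i] = str(structure.resnames[np.nonzero(inverse == i)[0][0]])
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", uniq)
    u.add_TopologyAttr("masses", np.asarray(structure.masses, dtype=float))
    u.add_TopologyAttr("charges", np.asarray(structure.charges, dtype=float))
    u.add_TopologyAttr("elements", np.asarray(
        [str(nm)[:1] for nm in structure.names], dtype=object))
    u.dimensions = [*np.asarray(structure.box, float), 90.0, 90.0, 90.0]
    u.atoms.positions = (structure.positions if positions is None
                         else positions)
    if velocities is not None:
        u.atoms.velocities = velocities
    return u


def write_structure(structure: LabeledStructure, path: str,
                    velocities: Optional[np.ndarray] = None,
                    sidecar: bool = True) -> None:
    """Write a structure as PDB or GRO (by extension), plus a JSON
    sidecar carrying charges, masses and groups."""
    u = _to_universe(structure, velocities=velocities)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(path)
    if sidecar:
        meta = {
            "charges": np.asarray(structure.charges, float).tolist(),
            "masses": np.asarray(structure.masses, float).tolist(),
            "groups": {k: np.asarray(v, int).tolist()
                       for k, v in structure.groups.items()},
            "box": np.asarray(structure.box, float).tolist(),
            "meta": _jsonable(structure.meta),
        }
        with open(_sidecar_path(path), "w") as fh:
            json.dump(meta, fh)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_trajectory(window: TrajectoryWindow, path: str) -> None:
    """Write a multi-frame XYZ trajectory."""
    import MDAnalysis as mda
    u = _to_universe(window.structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=window.n_atoms) as w:
            for i in range(window.n_frames):
                u.atoms.positions = window.positions[i]
                w.write(u.atoms)


def load_trajectory(paths: Sequence[str] | str,
                    topology: Optional[str] = None,
                    dt: float = 1.0,
                    box: Optional[np.ndarray] = None) -> TrajectoryWindow:
    """Load PDB/GRO/XYZ frames into a TrajectoryWindow.

    Units are normalised to Å and Å/ps (GRO velocities arrive in nm/ps
    and are converted by MDAnalysis).  Charges, masses and groups are
    restored from the JSON sidecar when present, else from the fixture
    atom-name table.
    """
    import MDAnalysis as mda
    if isinstance(paths, (str, os.PathLike)):
        paths = [str(paths)]
    paths = [str(p) for p in paths]
    for p in paths:
        if p.lower().endswith(".xyz"):
            _validate_xyz_blocks(p)
    top = topology if topology is not None else paths[0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(top, *paths, dt=dt)
    except (ValueError, EOFError, OSError) as exc:
        raise FormatError(f"cannot load {paths}: {exc}") from exc

    n = len(u.atoms)
    names = np.array([a.name for a in u.atoms], dtype=object)
    try:
        resnames = np.array([a.resname for a in u.atoms], dtype=object)
    except AttributeError:
        resnames = np.array(["UNK"] * n, dtype=object)
    try:
        resids = np.array([a.resid for a in u.atoms], dtype=int)
    except AttributeError:
        resids = np.arange(n) + 1

    charges = np.zeros(n)
    masses = np.ones(n)
    groups: Dict[str, np.ndarray] = {}
    side = _sidecar_path(top)
    have_sidecar = os.path.exists(side)
    if have_sidecar:
        with open(side) as fh:
            meta = json.load(fh)
        charges = np.asarray(meta["charges"], float)
        masses = np.asarray(meta["masses"], float)
        groups = {k: np.asarray(v, int) for k, v in meta["groups"].items()}
        if len(charges) != n:
            raise FormatError(f"sidecar {side} describes {len(charges)} "
                              f"atoms but topology has {n}")
    else:
        for i, nm in enumerate(names):
            entry = FIXTURE_ATOM_TABLE.get(str(nm))
            if entry is not None:
                charges[i], masses[i] = entry[0], entry[1]

    dims = u.dimensions
    if dims is not None and dims[:3].any():
        box_arr = np.asarray(dims[:3], float)
    elif box is not None:
        box_arr = np.asarray(box, float)
    elif have_sidecar and meta.get("box"):
        box_arr = np.asarray(meta["box"], float)
    else:
        box_arr = np.zeros(3)

    frames = []
    vels = []
    has_vel = hasattr(u.trajectory.ts, "velocities") and \
        u.trajectory.ts.has_velocities
    try:
        for ts in u.trajectory:
            if len(ts) != n:
                raise FormatError(
                    f"frame {ts.frame}: {len(ts)} atoms, topology has {n}")
            frames.append(ts.positions.astype(float).copy())
            if has_vel:
                vels.append(ts.velocities.astype(float).copy())
    except (ValueError, EOFError) as exc:
        raise FormatError(
            f"truncated/corrupt frame {len(frames)} in {paths}") from exc

    structure = LabeledStructure(
        positions=frames[0], names=names, resnames=resnames, resids=resids,
        charges=charges, masses=masses, box=box_arr, groups=groups)
    if not groups:
        assign_fixture_groups(structure)
    return TrajectoryWindow(
        structure=structure, positions=np.array(frames),
        velocities=np.array(vels) if vels else None, dt=dt)


# ---------------------------------------------------------------------------
# Periodicity
# ---------------------------------------------------------------------------

def _validate_xyz_blocks(path: str) -> None:
    """Reject silently-truncated multi-frame XYZ files: every frame
    must be a complete (natoms + 2)-line block."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].split()[0])
        except (ValueError, IndexError) as exc:
            raise FormatError(
                f"{path}: malformed frame header at frame {frame}") from exc
        block = lines[i + 2:i + 2 + nat]
        if len(block) < nat or any(len(l.split()) < 4 for l in block):
            raise FormatError(f"{path}: truncated frame {frame} "
                              f"({len(block)}/{nat} atom lines)")
        i += nat + 2
        frame += 1


def unwrap_z(window: TrajectoryWindow,
             warn_threshold: float = 0.5) -> TrajectoryWindow:
    """Make per-atom z continuous across frames by minimum-image
    increments; x and y are untouched.

    A single-step z displacement beyond ``warn_threshold``·Lz/2 after
    unwrapping is ambiguous under periodic wrapping; offending atoms
    are reported in a warning.
    """
    lz = float(window.box[2])
    if lz <= 0:
        raise ValueError("box z-vector undefined; cannot unwrap")
    pos = window.positions.copy()
    z = pos[:, :, 2]
    dz = np.diff(z, axis=0)
    dz -= lz * np.round(dz / lz)
    big = np.abs(dz) > warn_threshold * lz
    if big.any():
        atoms = sorted(set(np.nonzero(big)[1].tolist()))
        warnings.warn(f"unwrap_z: ambiguous jumps (> {warn_threshold:.2f}"
                      f"·Lz) for atoms {atoms[:20]}", stacklevel=2)
    z[1:] = z[0][None, :] + np.cumsum(dz, axis=0)
    return TrajectoryWindow(structure=window.structure, positions=pos,
                            velocities=window.velocities, dt=window.dt,
                            meta=dict(window.meta))
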