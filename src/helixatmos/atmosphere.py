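"""Ion-atmosphere analyses: time-averaged 3D densities, cylindrical
concentration profiles, excess-cation integrals, per-shell excess
charge, and RDF/SDF pair correlations.

The cylindrical coordinate λ is the distance from the helix axis,
which is fit per frame as the least-squares line through the reference
helix's phosphates (the helix drifts in real trajectories, so a static
axis would smear the profile).  Concentrations are molar; conversions
use N_A and 1 Å³ = 1e−27 L.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import A3_TO_L, N_AVOGADRO
from .core import (EmptySelectionError, GeometryError, LabeledStructure,
                   RadialProfile, ScalarField3D, TrajectoryWindow,
                   fit_helix_axis, minimum_image)


class ResolutionError(RuntimeError):
    """Raised when a Monte-Carlo volume estimate is too noisy."""


def _group_positions(window: TrajectoryWindow, group: str) -> np.ndarray:
    idx = window.structure.group(group)
    return window.positions[:, idx, :]


# ---------------------------------------------------------------------------
# 3D number density
# ---------------------------------------------------------------------------

def number_density(window: TrajectoryWindow, species: str,
                   spacing: float = 1.0,
                   weights: Optional[np.ndarray] = None) -> ScalarField3D:
    """Time-averaged number density of a species on a regular grid.

    The grid tiles the whole box (edges at multiples of ``spacing``,
    last voxel padded past the box edge so no particle is lost); the
    field integrates back to the mean particle count exactly.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    box = np.asarray(window.box, float)
    pos = _group_positions(window, species)
    nf, na = pos.shape[0], pos.shape[1]
    shape = np.maximum(np.ceil(box / spacing - 1e-9).astype(int), 1)
    edges = [np.arange(s + 1) * spacing for s in shape]
    flat = np.mod(pos.reshape(-1, 3), box)
    w = None
    if weights is not None:
        w = np.tile(np.asarray(weights, float), nf)
    hist, _ = np.histogramdd(flat, bins=edges, weights=w)
    values = hist / (nf * spacing ** 3)
    return ScalarField3D(origin=np.zeros(3), spacing=float(spacing),
                         values=values, species=species)


def charge_density(window: TrajectoryWindow, species: str,
                   spacing: float = 1.0) -> ScalarField3D:
    """Time-averaged charge density (e/Å³) of a species group."""
    idx = window.structure.group(species)
    field = number_density(window, species, spacing=spacing,
                           weights=window.structure.charges[idx])
    field.units = "e/A^3"
    return field


def export_opendx(field: ScalarField3D, path: str) -> None:
    """Write a ScalarField3D as an OpenDX grid (the lingua franca of
    molecular-visualisation density maps)."""
    nx, ny, nz = field.values.shape
    o = field.origin
    s = field.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}\n")
        fh.write(f"delta {s:.6f} 0 0\ndelta 0 {s:.6f} 0\ndelta 0 0 {s:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items "
                 f"{nx * ny * nz} data follows\n")
        flat = field.values.ravel(order="C")
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n'
                 'object "density" class field\n')


def export_hdf5(field: ScalarField3D, path: str) -> None:
    """Write a ScalarField3D as a flat HDF5 file (values + grid
    metadata)."""
    import h5py
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("density", data=field.values)
        ds.attrs["origin"] = np.asarray(field.origin, float)
        ds.attrs["spacing"] = field.spacing
        ds.attrs["units"] = field.units
        ds.attrs["species"] = field.species


def profile_to_tsv(profile: RadialProfile, path: str) -> None:
    """Write a RadialProfile as TSV with header metadata lines."""
    with open(path, "w") as fh:
        fh.write(f"# kind: {profile.kind}\n# units: {profile.units}\n")
        for k, v in profile.meta.items():
            if np.isscalar(v) or isinstance(v, str):
                fh.write(f"# {k}: {v}\n")
        fh.write("bin_lo\tbin_hi\tvalue\n")
        for lo, hi, v in zip(profile.edges[:-1], profile.edges[1:],
                             profile.values):
            fh.write(f"{lo:.6g}\t{hi:.6g}\t{v:.8g}\n")


# ---------------------------------------------------------------------------
# Cylindrical concentration about the helix axis
# ---------------------------------------------------------------------------

def _frame_axes(window: TrajectoryWindow,
                axis_group: str = "helix1") -> np.ndarray:
    """Per-frame helix axis xy-position (least-squares line fit through
    the reference helix, restricted to phosphates when present)."""
    s = window.structure
    idx = s.group(axis_group)
    if "phosphate_backbone" in s.groups:
        ph = np.intersect1d(idx, s.groups["phosphate_backbone"])
        if len(ph) >= 2:
            idx = ph
    centers = np.empty((window.n_frames, 3))
    for f in range(window.n_frames):
        c, _ = fit_helix_axis(window.positions[f, idx, :])
        centers[f] = c
    return centers


def _lambda_distances(window: TrajectoryWindow, species: str,
                      axis_group: str) -> np.ndarray:
    """Per-frame xy distances of species atoms to the fitted axis,
    minimum-image in xy."""
    box = np.asarray(window.box, float)
    pos = _group_positions(window, species)
    centers = _frame_axes(window, axis_group)
    d = pos[:, :, :2] - centers[:, None, :2]
    d -= box[:2] * np.round(d / box[:2])
    return np.linalg.norm(d, axis=2)


def cylindrical_concentration(window: TrajectoryWindow, species: str,
                              axis_group: str = "helix1",
                              bin_width: float = 0.5,
                              lambda_max: Optional[float] = None,
                              valence: float = 1.0) -> RadialProfile:
    """Molar concentration c(λ) in cylindrical shells about the helix
    axis (default shell width 0.5 Å).

    ``valence`` scales counts into charge concentration when building
    total-charge profiles.  Shell volume is π(λ_out²−λ_in²)·Lz.
    """
    box = np.asarray(window.box, float)
    limit = 0.5 * min(box[0], box[1])
    if lambda_max is None:
        lambda_max = limit
    if lambda_max > limit + 1e-9:
        raise ValueError(f"lambda_max {lambda_max} exceeds half the "
                         f"smallest xy box edge {limit}")
    lam = _lambda_distances(window, species, axis_group)
    edges = np.arange(0.0, lambda_max + bin_width * 0.5, bin_width)
    counts, _ = np.histogram(lam.ravel(), bins=edges)
    mean_counts = counts / window.n_frames
    shell_vol = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * box[2]   # Å³
    conc = valence * mean_counts / (N_AVOGADRO * shell_vol * A3_TO_L)
    return RadialProfile(edges=edges, values=conc,
                         kind="cylindrical_concentration", units="mol/L",
                         counts=mean_counts,
                         meta={"species": species, "L": float(box[2]),
                               "valence": valence,
                               "n_frames": window.n_frames})


def cylindrical_from_field(field: ScalarField3D, axis_xy: np.ndarray,
                           L: float, bin_width: float = 0.5,
                           lambda_max: Optional[float] = None
                           ) -> RadialProfile:
    """Cylindrical concentration computed from a 3D density field
    (voxel centers binned by λ) — the field-route cross-check for the
    direct position-based profile."""
    nx, ny, nz = field.values.shape
    s = field.spacing
    x = field.origin[0] + (np.arange(nx) + 0.5) * s
    y = field.origin[1] + (np.arange(ny) + 0.5) * s
    lam = np.hypot(x[:, None] - axis_xy[0], y[None, :] - axis_xy[1])
    if lambda_max is None:
        lambda_max = lam.max()
    edges = np.arange(0.0, lambda_max + bin_width * 0.5, bin_width)
    col_counts = field.values.sum(axis=2) * field.voxel_volume  # per column
    counts, _ = np.histogram(lam.ravel(), bins=edges,
                             weights=col_counts.ravel())
    shell_vol = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * L
    conc = counts / (N_AVOGADRO * shell_vol * A3_TO_L)
    return RadialProfile(edges=edges, values=conc,
                         kind="cylindrical_concentration", units="mol/L",
                         counts=counts, meta={"L": L})


def estimate_bulk_concentration(profile: RadialProfile,
                                outer_fraction: float = 0.2) -> float:
    """Bulk concentration from the outermost ``outer_fraction`` of
    λ-bins (count-weighted so empty far shells don't bias it)."""
    n = len(profile.values)
    k = max(1, int(round(outer_fraction * n)))
    tail = profile.values[n - k:]
    vol = (profile.edges[n - k + 1:] ** 2
           - profile.edges[n - k:-1] ** 2)
    return float(np.average(tail, weights=vol))


def excess_ions(profile: RadialProfile, c_bulk: Optional[float] = None,
                L: Optional[float] = None,
                R: float | Sequence[float] = 10.0):
    """Cumulative excess ion count Γ(R): the radial integral of
    c(λ) − c_bulk over cylindrical shells up to R, times N_A·L.

    ``c_bulk`` defaults to the outer-bin estimate; ``L`` defaults to
    the profile's recorded axial length.
    """
    if L is None:
        L = profile.meta.get("L")
        if L is None:
            raise ValueError("axial length L required")
    if c_bulk is None:
        c_bulk = estimate_bulk_concentration(profile)
    if c_bulk < 0:
        raise ValueError("c_bulk must be >= 0")
    Rs = np.atleast_1d(np.asarray(R, dtype=float))
    if np.any(Rs > profile.edges[-1] + 1e-9):
        raise ValueError(f"R beyond profile range {profile.edges[-1]} Å")
    shell_vol_L = (np.pi * (profile.edges[1:] ** 2 - profile.edges[:-1] ** 2)
                   * L * A3_TO_L)
    dn = (profile.values - c_bulk) * N_AVOGADRO * shell_vol_L
    cum = np.concatenate([[0.0], np.cumsum(dn)])
    # interpolate the cumulative integral to arbitrary R
    out = np.interp(Rs, profile.edges, cum)
    return float(out[0]) if np.isscalar(R) else out


# ---------------------------------------------------------------------------
# Surface shells and excess charge
# ---------------------------------------------------------------------------

DEFAULT_SHELLS = {"R1": 3.5, "R2": 6.0, "R3": 10.0}


def surface_distances(positions: np.ndarray, reference: np.ndarray,
                      box: np.ndarray) -> np.ndarray:
    """Distance of each position to the nearest reference atom,
    minimum-image in all three dimensions."""
    if len(reference) == 0:
        raise EmptySelectionError("empty reference group")
    box = np.asarray(box, float)
    tree = cKDTree(np.mod(reference, box), boxsize=box)
    d, _ = tree.query(np.mod(positions, box))
    return d


def excess_charge_by_shell(window: TrajectoryWindow,
                           shells: Optional[Dict[str, float]] = None,
                           species: Optional[Iterable[str]] = None,
                           reference: str = "dna") -> Dict[str, Dict]:
    """Time-averaged charge (e) of each species within surface shells
    of the DNA (distance to the nearest DNA atom ≤ shell radius).

    Returns ``{shell: {species: charge, ..., 'total': charge}}`` plus a
    ``'reference_charge'`` entry (the DNA's own total charge) for
    electroneutrality accounting.
    """
    if shells is None:
        shells = dict(DEFAULT_SHELLS)
    radii = np.array(list(shells.values()), float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("shell radii must be strictly increasing")
    s = window.structure
    ref_idx = s.group(reference)
    if species is None:
        species = sorted(k for k in s.groups
                         if k.startswith("ion:") or k == "water")
    report: Dict[str, Dict] = {name: {} for name in shells}
    box = np.asarray(window.box, float)
    charges = s.charges
    acc = {name: {sp: 0.0 for sp in species} for name in shells}
    for f in range(window.n_frames):
        ref_pos = window.positions[f, ref_idx, :]
        for sp in species:
            idx = s.group(sp)
            d = surface_distances(window.positions[f, idx, :], ref_pos, box)
            q = charges[idx]
            for name, r in shells.items():
                acc[name][sp] += float(q[d <= r].sum())
    for name in shells:
        for sp in species:
            report[name][sp] = acc[name][sp] / window.n_frames
        report[name]["total"] = sum(acc[name][sp] for sp in species) \
            / window.n_frames
    report["reference_charge"] = float(charges[ref_idx].sum())
    return report


# ---------------------------------------------------------------------------
# RDF and SDF
# ---------------------------------------------------------------------------

def _pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray,
                    exclude_self: bool) -> np.ndarray:
    diff = b[None, :, :] - a[:, None, :]
    diff = minimum_image(diff, box)
    d = np.linalg.norm(diff, axis=2)
    if exclude_self:
        d = d[d > 1e-12]
    return d.ravel()


def rdf(window: TrajectoryWindow, reference: str, target: str,
        bin_width: float = 0.2, r_max: Optional[float] = None
        ) -> RadialProfile:
    """Radial distribution function g(r) of target atoms about
    reference atoms, normalised by ideal-gas shell counts at the
    target's box density."""
    s = window.structure
    ref_idx, tgt_idx = s.group(reference), s.group(target)
    box = np.asarray(window.box, float)
    vol = box.prod()
    if vol <= 0:
        raise GeometryError("zero box volume")
    if r_max is None:
        r_max = 0.5 * box.min()
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    counts = np.zeros(len(edges) - 1)
    same = reference == target
    for f in range(window.n_frames):
        d = _pair_distances(window.positions[f, ref_idx, :],
                            window.positions[f, tgt_idx, :], box,
                            exclude_self=same)
        h, _ = np.histogram(d, bins=edges)
        counts += h
    counts /= window.n_frames
    rho = len(tgt_idx) / vol
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = len(ref_idx) * rho * shell_vol
    g = np.divide(counts, ideal, out=np.zeros_like(counts),
                  where=ideal > 0)
    return RadialProfile(edges=edges, values=g, kind="rdf", units="",
                         counts=counts,
                         meta={"rho_target": rho, "n_ref": len(ref_idx)})


def coordination_number(profile: RadialProfile, r: float) -> float:
    """Integrate 4πr²ρ g(r) dr up to r — the running coordination
    number of an RDF."""
    rho = profile.meta["rho_target"]
    edges = profile.edges
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    inc = profile.values * rho * shell_vol
    cum = np.concatenate([[0.0], np.cumsum(inc)])
    return float(np.interp(r, edges, cum))


def sdf(window: TrajectoryWindow, reference: str, target: str,
        bin_width: float = 0.5, r_max: Optional[float] = None,
        mc_samples: int = 1_000_000, seed: int = 0,
        mc_rel_tol: float = 0.1) -> RadialProfile:
    """Surface distribution function: pair correlation versus distance
    to the *nearest* reference atom, so an irregular molecular surface
    is probed at constant thickness instead of through spherical
    shells.

    Accessible shell volumes have no closed form around an arbitrary
    surface and are estimated by seeded Monte-Carlo integration of the
    box; a uniform gas therefore normalises to 1.  Bins whose volume
    estimate carries a relative error above ``mc_rel_tol`` raise
    ResolutionError (more samples needed).
    """
    s = window.structure
    ref_idx, tgt_idx = s.group(reference), s.group(target)
    box = np.asarray(window.box, float)
    if r_max is None:
        r_max = 0.5 * box.min()
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    counts = np.zeros(len(edges) - 1)
    rng = np.random.default_rng(seed)
    mc_hits = np.zeros(len(edges) - 1)
    mc_total = 0
    per_frame = max(1, mc_samples // window.n_frames)
    for f in range(window.n_frames):
        ref_pos = window.positions[f, ref_idx, :]
        d = surface_distances(window.positions[f, tgt_idx, :], ref_pos, box)
        h, _ = np.histogram(d, bins=edges)
        counts += h
        probe = rng.uniform(0, 1, size=(per_frame, 3)) * box
        dm = surface_distances(probe, ref_pos, box)
        hm, _ = np.histogram(dm, bins=edges)
        mc_hits += hm
        mc_total += per_frame
    counts /= window.n_frames
    vol = box.prod()
    shell_vol = mc_hits / mc_total * vol          # frame-averaged
    rho = len(tgt_idx) / vol
    occupied = counts > 0
    too_noisy = occupied & (mc_hits > 0) & (1.0 / np.sqrt(
        np.maximum(mc_hits, 1)) > mc_rel_tol)
    if np.any(occupied & (mc_hits == 0)) or too_noisy.any():
        raise ResolutionError(
            "Monte-Carlo shell-volume estimate too noisy for occupied "
            f"bins {np.nonzero(occupied & ((mc_hits == 0) | too_noisy))[0]};"
            " increase mc_samples")
    g = np.divide(counts, rho * shell_vol, out=np.zeros_like(counts),
                  where=shell_vol > 0)
    return RadialProfile(edges=edges, values=g, kind="sdf", units="",
                         counts=counts,
                         meta={"rho_target": rho, "mc_samples": mc_total,
                               "shell_volumes": shell_vol.tolist()})
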