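"""Hydration-structure metrics: the tetrahedral order parameter of
water, bound-water counts in the first (R1 = 3.5 Å) surface shell, and
geometric hydrogen-bond counts.

S_g is the standard four-neighbour tetrahedral order parameter,

    S_g = (3/32) Σ_{j<k} (cos Ψ_jk + 1/3)²,

with Ψ_jk the angle at the central oxygen between its j-th and k-th
nearest oxygen neighbours; the 3/32 factor bounds it to [0, 1], with 0
a perfect tetrahedron.  An isotropic random neighbour shell averages
to 1/4 (E[(cos Ψ + 1/3)²] = 4/9 per pair).
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import RadialProfile, TrajectoryWindow, minimum_image
from .atmosphere import _frame_axes, surface_distances


class MissingHydrogensError(RuntimeError):
    """Raised when donor hydrogens are required but absent; callers may
    fall back to the oxygen-distance-only criterion."""


def tetrahedral_order_frame(oxygens: np.ndarray, box: np.ndarray,
                            neighbor_cutoff: float = 5.0
                            ) -> Tuple[np.ndarray, int]:
    """Per-oxygen S_g for one frame.

    Neighbours are the 4 nearest oxygens by minimum-image distance,
    regardless of distance; oxygens whose 4th neighbour lies beyond
    ``neighbor_cutoff`` are skipped (value NaN) and counted.
    """
    oxygens = np.asarray(oxygens, float)
    n = oxygens.shape[0]
    if n < 5:
        raise ValueError("need at least 5 waters (4 neighbours each)")
    box = np.asarray(box, float)
    wrapped = np.mod(oxygens, box) if box.all() else oxygens
    tree = cKDTree(wrapped, boxsize=box if box.all() else None)
    d, idx = tree.query(wrapped, k=5)
    d, idx = d[:, 1:], idx[:, 1:]          # drop self
    sg = np.full(n, np.nan)
    skipped = 0
    pairs = [(j, k) for j in range(4) for k in range(j + 1, 4)]
    for i in range(n):
        if d[i, 3] > neighbor_cutoff:
            skipped += 1
            continue
        vec = wrapped[idx[i]] - wrapped[i]
        vec = minimum_image(vec, box) if box.all() else vec
        unit = vec / np.linalg.norm(vec, axis=1)[:, None]
        acc = 0.0
        for j, k in pairs:
            c = float(np.dot(unit[j], unit[k]))
            acc += (c + 1.0 / 3.0) ** 2
        sg[i] = 3.0 / 32.0 * acc
    return sg, skipped


def tetrahedral_order(window: TrajectoryWindow,
                      water_group: str = "water_oxygen",
                      axis_group: Optional[str] = "helix1",
                      bin_width: float = 0.5,
                      neighbor_cutoff: float = 5.0
                      ) -> Tuple[np.ndarray, Optional[RadialProfile]]:
    """S_g for every water over all frames, plus the mean ⟨S_g⟩ binned
    into 0.5 Å cylindrical shells from the helix axis (None when no
    axis group is available)."""
    s = window.structure
    o_idx = s.group(water_group)
    box = np.asarray(window.box, float)
    all_sg = np.empty((window.n_frames, len(o_idx)))
    skipped_total = 0
    for f in range(window.n_frames):
        sg, skipped = tetrahedral_order_frame(
            window.positions[f, o_idx, :], box, neighbor_cutoff)
        all_sg[f] = sg
        skipped_total += skipped
    profile = None
    if axis_group is not None and axis_group in s.groups:
        centers = _frame_axes(window, axis_group)
        d = window.positions[:, o_idx, :2] - centers[:, None, :2]
        d -= box[:2] * np.round(d / box[:2])
        lam = np.linalg.norm(d, axis=2).ravel()
        vals = all_sg.ravel()
        ok = np.isfinite(vals)
        lam, vals = lam[ok], vals[ok]
        lmax = 0.5 * min(box[0], box[1])
        edges = np.arange(0.0, lmax + bin_width * 0.5, bin_width)
        counts, _ = np.histogram(lam, bins=edges)
        sums, _ = np.histogram(lam, bins=edges, weights=vals)
        mean = np.divide(sums, counts, out=np.full(len(counts), np.nan),
                         where=counts > 0)
        profile = RadialProfile(edges=edges, values=np.nan_to_num(mean),
                                kind="tetrahedral", units="",
                                counts=counts.astype(float),
                                meta={"skipped": skipped_total})
    return all_sg, profile


def bound_water_count(frame_positions: np.ndarray, o_idx: np.ndarray,
                      ref_pos: np.ndarray, box: np.ndarray,
                      r1: float = 3.5) -> int:
    """Number of water oxygens within surface distance r1 of the
    reference atoms in one frame."""
    if len(o_idx) == 0:
        return 0
    d = surface_distances(frame_positions[o_idx], ref_pos, box)
    return int((d <= r1).sum())


def bound_waters(window: TrajectoryWindow, r1: float = 3.5,
                 reference: str = "dna",
                 water_group: str = "water_oxygen") -> np.ndarray:
    """Per-frame count of bound waters (oxygens with surface distance
    ≤ r1 to the nearest DNA atom)."""
    s = window.structure
    o_idx = s.groups.get(water_group, np.empty(0, int))
    if len(o_idx) == 0:
        return np.zeros(window.n_frames)
    ref_idx = s.group(reference)
    box = np.asarray(window.box, float)
    return np.array([
        bound_water_count(window.positions[f], o_idx,
                          window.positions[f, ref_idx, :], box, r1)
        for f in range(window.n_frames)], dtype=float)


def hydrogen_bonds_frame(frame_positions: np.ndarray,
                         donors_o: np.ndarray,
                         donor_h: Dict[int, np.ndarray],
                         acceptors: np.ndarray,
                         box: np.ndarray,
                         r_cut: float = 3.5,
                         angle_cut: float = 150.0) -> int:
    """Geometric hydrogen-bond count in one frame.

    A bond requires donor-oxygen···acceptor distance ≤ ``r_cut`` Å and
    a donor−H···acceptor angle ≥ ``angle_cut`` degrees for at least
    one hydrogen of the donor.
    """
    if len(donors_o) == 0 or len(acceptors) == 0:
        return 0
    box = np.asarray(box, float)
    apos = np.mod(frame_positions[acceptors], box)
    tree = cKDTree(apos, boxsize=box)
    cos_cut = np.cos(np.deg2rad(angle_cut))
    count = 0
    dpos = np.mod(frame_positions[donors_o], box)
    neighbor_lists = tree.query_ball_point(dpos, r_cut)
    for di, neigh in zip(donors_o, neighbor_lists):
        o = frame_positions[di]
        hs = frame_positions[donor_h[di]]
        for aj in neigh:
            ai = acceptors[aj]
            if ai == di:
                continue
            oa = minimum_image(frame_positions[ai] - o, box)
            for h in hs:
                oh = minimum_image(h - o, box)
                ha = oa - oh
                nh, na = np.linalg.norm(oh), np.linalg.norm(ha)
                if nh < 1e-9 or na < 1e-9:
                    continue
                # angle at H between H->O and H->A
                cang = float(np.dot(-oh, ha) / (nh * na))
                if cang <= cos_cut:
                    count += 1
                    break
    return count


def _water_topology(structure) -> Tuple[np.ndarray, Dict[int, np.ndarray]]:
    """Water oxygen indices and their hydrogen indices, matched by
    residue id."""
    o_idx = structure.groups.get("water_oxygen", np.empty(0, int))
    h_idx = structure.groups.get("water_hydrogen", np.empty(0, int))
    donor_h: Dict[int, np.ndarray] = {}
    if len(h_idx):
        by_res: Dict[int, list] = {}
        for h in h_idx:
            by_res.setdefault(int(structure.resids[h]), []).append(int(h))
        for o in o_idx:
            donor_h[int(o)] = np.array(
                by_res.get(int(structure.resids[o]), []), dtype=int)
    return np.asarray(o_idx, int), donor_h


def hydrogen_bonds(window: TrajectoryWindow,
                   reference: str = "dna", region_cut: float = 3.5,
                   r_cut: float = 3.5, angle_cut: float = 150.0,
                   fallback_distance_only: bool = False) -> np.ndarray:
    """Per-frame hydrogen-bond count among waters inside the R1 region
    (surface distance ≤ ``region_cut``; pass ``np.inf`` for the whole
    box).  Water–water bonds only in the reduced fixture
    representation.

    Without hydrogens the geometric criterion is impossible; with
    ``fallback_distance_only`` the O···O ≤ r_cut criterion is used and
    labelled in the result's metadata, otherwise
    MissingHydrogensError.
    """
    s = window.structure
    o_idx, donor_h = _water_topology(s)
    if len(o_idx) == 0:
        return np.zeros(window.n_frames)
    have_h = all(len(donor_h.get(int(o), ())) for o in o_idx)
    if not have_h and not fallback_distance_only:
        raise MissingHydrogensError(
            "water hydrogens missing; re-run with "
            "fallback_distance_only=True for the O···O distance criterion")
    box = np.asarray(window.box, float)
    ref_idx = s.groups.get(reference, np.empty(0, int))
    counts = np.zeros(window.n_frames)
    for f in range(window.n_frames):
        pos = window.positions[f]
        sel = o_idx
        if np.isfinite(region_cut) and len(ref_idx):
            d = surface_distances(pos[o_idx], pos[ref_idx], box)
            sel = o_idx[d <= region_cut]
        if len(sel) < 2:
            continue
        if have_h:
            counts[f] = hydrogen_bonds_frame(pos, sel, donor_h, sel, box,
                                             r_cut, angle_cut)
        else:
            wrapped = np.mod(pos[sel], box)
            tree = cKDTree(wrapped, boxsize=box)
            pairs = tree.query_pairs(r_cut)
            counts[f] = len(pairs)
    counts = np.asarray(counts)
    return counts
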