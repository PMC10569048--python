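"""Shell-restricted electrostatics: the Coulomb potential of a helix's
charge shell and the stored interhelical energy U_d along the
condensation path.

Each helix together with the charged particles inside a 10 Å surface
shell (the Debye layer at the study's salt condition) forms one charge
group; U_d is the shell-to-shell *cross* Coulomb energy — self-energy
within a group never enters, so U_d measures how well each atmosphere
screens the other helix.  Sums are plain vacuum Coulomb (relative
permittivity configurable); periodic images beyond the primary cell
are deliberately omitted, consistent with the screened, shell-limited
picture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np

from .constants import KE_COULOMB
from .core import (LabeledStructure, TrajectoryWindow, fit_helix_axis,
                   minimum_image)
from .atmosphere import surface_distances

logger = logging.getLogger("helixatmos")

#: Minimum probe-to-source distance before the Coulomb sum is declared
#: singular, Å.
EPSILON_R = 0.1


class SingularityError(ValueError):
    """Raised when an evaluation point (numerically) touches a source
    charge."""


@dataclass
class ShellChargeDistribution:
    """Charges assigned to one helix: the helix's own atoms plus every
    charged particle within ``thickness`` of its surface."""

    positions: np.ndarray          # (M, 3) Å
    charges: np.ndarray            # (M,) e
    helix: str = "helix1"
    thickness: float = 10.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.charges = np.atleast_1d(np.asarray(self.charges, float))
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("charges must be finite")
        if len(self.charges) != len(self.positions):
            raise ValueError("positions/charges length mismatch")


@dataclass
class EnergyProfile:
    """Stored electrostatic energy versus interhelical distance."""

    d: np.ndarray                  # nm, strictly increasing
    u: np.ndarray                  # kJ/mol (absolute)
    du: np.ndarray                 # kJ/mol, relative to largest-d bin
    n_frames: np.ndarray

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"d_nm": self.d, "U_kJmol": self.u,
                             "dU_kJmol": self.du,
                             "n_frames": self.n_frames})


def potential_at(points: np.ndarray, dist: ShellChargeDistribution,
                 rel_permittivity: float = 1.0,
                 box: Optional[np.ndarray] = None) -> np.ndarray:
    """Coulomb potential (kJ/mol/e) at each point from the shell's
    charges: k_e Σ q_i / |r − r_i|, minimum-image when a box is given.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    diff = pts[:, None, :] - dist.positions[None, :, :]
    if box is not None:
        diff = minimum_image(diff, np.asarray(box, float))
    r = np.linalg.norm(diff, axis=2)
    bad = np.nonzero(r < EPSILON_R)
    if len(bad[0]):
        offenders = sorted(set(bad[1].tolist()))
        raise SingularityError(
            f"evaluation point(s) within {EPSILON_R} Å of source "
            f"charge(s) {offenders[:10]}")
    phi = (KE_COULOMB / rel_permittivity) * (dist.charges[None, :] / r).sum(
        axis=1)
    return phi if np.asarray(points).ndim > 1 else float(phi[0])


def build_shells(frame: LabeledStructure, thickness: float = 10.0,
                 include_dna: bool = True,
                 mobile_groups: Optional[Iterable[str]] = None
                 ) -> Tuple[ShellChargeDistribution,
                            ShellChargeDistribution]:
    """Partition a frame's charges into the two helix shell groups.

    Each mobile charged particle joins the shell of its *nearest* helix
    (by surface distance) if within ``thickness`` of that surface;
    exact ties are excluded from both shells and logged.  With
    ``include_dna`` the helix's own charges belong to its group.
    """
    box = np.asarray(frame.box, float)
    h1 = frame.group("helix1")
    h2 = frame.group("helix2")
    if mobile_groups is None:
        mobile_groups = sorted(k for k in frame.groups
                               if k.startswith("ion:") or k == "water")
    mobile = sorted(set(np.concatenate(
        [frame.groups[g] for g in mobile_groups]).astype(int))) \
        if mobile_groups else []
    mobile = np.array(mobile, dtype=int)
    members1 = [h1] if include_dna else []
    members2 = [h2] if include_dna else []
    if len(mobile):
        pos = frame.positions[mobile]
        d1 = surface_distances(pos, frame.positions[h1], box)
        d2 = surface_distances(pos, frame.positions[h2], box)
        tie = np.isclose(d1, d2, rtol=0, atol=1e-12) & (d1 <= thickness)
        if tie.any():
            logger.warning("build_shells: %d particle(s) equidistant from "
                           "both helices excluded", int(tie.sum()))
        in1 = (d1 < d2) & (d1 <= thickness) & ~tie
        in2 = (d2 < d1) & (d2 <= thickness) & ~tie
        members1.append(mobile[in1])
        members2.append(mobile[in2])
    i1 = np.concatenate(members1) if members1 else np.empty(0, int)
    i2 = np.concatenate(members2) if members2 else np.empty(0, int)
    s1 = ShellChargeDistribution(frame.positions[i1], frame.charges[i1],
                                 helix="helix1", thickness=thickness)
    s2 = ShellChargeDistribution(frame.positions[i2], frame.charges[i2],
                                 helix="helix2", thickness=thickness)
    return s1, s2


def stored_energy(shell1: ShellChargeDistribution,
                  shell2: ShellChargeDistribution,
                  rel_permittivity: float = 1.0,
                  box: Optional[np.ndarray] = None) -> float:
    """Cross Coulomb energy (kJ/mol) between the two shell groups:
    Σ_{i∈2} q_i Φ_1(r_i).  No self-energy terms."""
    if len(shell1.charges) == 0 or len(shell2.charges) == 0:
        raise ValueError("both shells must be non-empty")
    phi = potential_at(shell2.positions, shell1,
                       rel_permittivity=rel_permittivity, box=box)
    return float((shell2.charges * phi).sum())


def interhelical_distance(frame: LabeledStructure,
                          use_phosphates: bool = True) -> float:
    """Axis-to-axis xy distance (nm) from least-squares axis fits of
    the two helices."""
    box = np.asarray(frame.box, float)
    cs = []
    for h in ("helix1", "helix2"):
        idx = frame.group(h)
        if use_phosphates and "phosphate_backbone" in frame.groups:
            ph = np.intersect1d(idx, frame.groups["phosphate_backbone"])
            if len(ph) >= 2:
                idx = ph
        c, _ = fit_helix_axis(frame.positions[idx])
        cs.append(c)
    d = cs[1][:2] - cs[0][:2]
    if box[:2].all():
        d = d - box[:2] * np.round(d / box[:2])
    return float(np.hypot(*d) / 10.0)


def energy_vs_distance(window: TrajectoryWindow,
                       d_edges: Optional[np.ndarray] = None,
                       thickness: float = 10.0,
                       include_dna: bool = True,
                       rel_permittivity: float = 1.0,
                       periodic: bool = False) -> EnergyProfile:
    """Bin frames by interhelical distance (default δd = 0.5 Å) and
    average the stored shell-to-shell energy per bin; ΔU_d is reported
    relative to the largest-d (free-state) bin."""
    ds = np.array([interhelical_distance(window.frame(f))
                   for f in range(window.n_frames)])
    if d_edges is None:
        d_edges = np.arange(ds.min() - 0.025, ds.max() + 0.05, 0.05)
    d_edges = np.asarray(d_edges, float)
    box = np.asarray(window.box, float) if periodic else None
    which = np.digitize(ds, d_edges) - 1
    nb = len(d_edges) - 1
    sums = np.zeros(nb)
    counts = np.zeros(nb, dtype=int)
    for f in range(window.n_frames):
        b = which[f]
        if not 0 <= b < nb:
            continue
        s1, s2 = build_shells(window.frame(f), thickness=thickness,
                              include_dna=include_dna)
        if len(s1.charges) == 0 or len(s2.charges) == 0:
            continue
        sums[b] += stored_energy(s1, s2, rel_permittivity=rel_permittivity,
                                 box=box)
        counts[b] += 1
    keep = counts > 0
    if (~keep).any():
        logger.warning("energy_vs_distance: dropping %d empty d-bin(s)",
                       int((~keep).sum()))
    centers = 0.5 * (d_edges[:-1] + d_edges[1:])[keep]
    u = sums[keep] / counts[keep]
    du = u - u[-1] if len(u) else u
    return EnergyProfile(d=centers, u=u, du=du, n_frames=counts[keep])
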