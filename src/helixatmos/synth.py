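"""Ground-truth synthetic fixtures: ideal duplex pairs, ion clouds,
thermal velocities and toy well-tempered metadynamics runs.

Every generator is deterministic under its seed and records its own
parameters in ``meta`` so downstream oracles can recover the known
truth.  Fixtures use a reduced representation — phosphate pseudo-atoms
carrying the backbone charge, groove marker pseudo-atoms, 3-site
waters, monatomic ions — which is all the analysis math ever touches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .constants import KB, N_AVOGADRO, A3_TO_L
from .core import GeometryError, LabeledStructure, TrajectoryWindow
from .io import FIXTURE_ATOM_TABLE, HillSeries, assign_fixture_groups


class PackingError(RuntimeError):
    """Raised when random placement cannot satisfy hard-core
    constraints."""


class DomainViolationError(RuntimeError):
    """Raised when a CV trajectory leaves the declared domain."""

    def __init__(self, msg: str, step: int):
        super().__init__(msg)
        self.step = step


# ---------------------------------------------------------------------------
# Duplex geometry
# ---------------------------------------------------------------------------

@dataclass
class HelixSpec:
    """Idealised B-form duplex: phosphates on two helical strands plus
    groove marker pseudo-atoms.

    ``groove_phase`` is the angular offset between the two strands'
    phosphates at equal z; with the B-form default of 154° the minor
    groove subtends 154° and the major groove the remaining 206°.
    """

    n_bp: int = 20
    rise: float = 3.4              # Å per bp
    twist: float = 36.0            # deg per bp
    backbone_radius: float = 8.9   # Å
    groove_phase: float = 154.0    # deg
    axis_origin: Optional[np.ndarray] = None   # Å; None = center in box
    azimuth0: float = 0.0          # rad

    def __post_init__(self):
        if self.n_bp < 1:
            raise ValueError("n_bp must be >= 1")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not 0 < self.twist <= 180:
            raise ValueError("twist must lie in (0, 180] degrees")

    @property
    def length(self) -> float:
        """Helix z-extent (Å): n_bp · rise, i.e. the periodic repeat
        when the duplex is continued across the z boundary."""
        return self.n_bp * self.rise


def _single_helix(spec: HelixSpec, origin: np.ndarray, azimuth: float,
                  tag: str) -> LabeledStructure:
    k = np.arange(spec.n_bp)
    z = origin[2] + k * spec.rise
    az1 = azimuth + np.deg2rad(spec.twist) * k
    az2 = az1 + np.deg2rad(spec.groove_phase)
    # groove bisectors: minor between the strands, major opposite
    az_min = az1 + 0.5 * np.deg2rad(spec.groove_phase)
    az_maj = az_min + np.pi
    r, rg = spec.backbone_radius, 0.6 * spec.backbone_radius

    def ring(azs, radius):
        return np.column_stack([origin[0] + radius * np.cos(azs),
                                origin[1] + radius * np.sin(azs), z])

    pos = np.vstack([ring(az1, r), ring(az2, r),
                     ring(az_maj, rg), ring(az_min, rg)])
    names = np.array(["P"] * (2 * spec.n_bp) + ["MAJ"] * spec.n_bp
                     + ["MIN"] * spec.n_bp, dtype=object)
    resnames = np.array(["DP"] * pos.shape[0], dtype=object)
    resids = np.concatenate([k + 1, k + 1, k + 1, k + 1])
    charges = np.array([FIXTURE_ATOM_TABLE[str(n)][0] for n in names])
    masses = np.array([FIXTURE_ATOM_TABLE[str(n)][1] for n in names])
    s = LabeledStructure(positions=pos, names=names, resnames=resnames,
                         resids=resids, charges=charges, masses=masses,
                         box=np.zeros(3),
                         groups={tag: np.arange(pos.shape[0])})
    return s


def build_duplex_pair(spec: HelixSpec, separation: float, theta: float,
                      box: np.ndarray,
                      periodic_z: bool = False) -> LabeledStructure:
    """Build two parallel duplexes along z at a given interhelical
    distance and azimuthal rotation.

    Parameters
    ----------
    separation : float
        Axis-to-axis distance d in nm, applied along +x in the xy plane.
    theta : float
        Rotation (rad) of helix 2 about its own axis relative to the
        restrained helix 1.
    box : array
        Orthorhombic box edge lengths, Å.
    periodic_z : bool
        Require the box z-extent to be an integer multiple of the helix
        repeat so the duplex continues seamlessly across the boundary.
    """
    box = np.asarray(box, dtype=float)
    sep_A = float(separation) * 10.0
    if sep_A < 2 * spec.backbone_radius:
        raise GeometryError(
            f"separation {sep_A:.1f} Å < helix diameter "
            f"{2 * spec.backbone_radius:.1f} Å: helices overlap")
    if spec.axis_origin is None:
        origin1 = np.array([box[0] / 2 - sep_A / 2, box[1] / 2, 0.0])
    else:
        origin1 = np.asarray(spec.axis_origin, dtype=float)
    origin2 = origin1 + np.array([sep_A, 0.0, 0.0])
    margin = spec.backbone_radius
    for o in (origin1, origin2):
        if not (margin <= o[0] <= box[0] - margin
                and margin <= o[1] <= box[1] - margin):
            raise GeometryError("box too small for the requested pair")
    if periodic_z:
        ratio = box[2] / spec.length
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise GeometryError(
                f"box z {box[2]} Å is not an integer multiple of the "
                f"helical repeat {spec.length} Å")
    h1 = _single_helix(spec, origin1, spec.azimuth0, "helix1")
    h2 = _single_helix(spec, origin2, spec.azimuth0 + float(theta), "helix2")
    pair = h1.concat(h2)
    pair.box = box
    assign_fixture_groups(pair)
    pair.meta.update({
        "helix_spec": {"n_bp": spec.n_bp, "rise": spec.rise,
                       "twist": spec.twist,
                       "backbone_radius": spec.backbone_radius,
                       "groove_phase": spec.groove_phase,
                       "azimuth0": spec.azimuth0},
        "separation_nm": float(separation), "theta": float(theta),
        "origin1": origin1.tolist(), "origin2": origin2.tolist(),
    })
    return pair


# ---------------------------------------------------------------------------
# Ions and waters
# ---------------------------------------------------------------------------

@dataclass
class IonPlacementSpec:
    """How to scatter one ion species into a structure's box.

    ``uniform_bulk`` draws a Poisson count at molar ``concentration``
    and places uniformly outside a hard core around existing atoms;
    ``helical_groove_chain`` puts exactly ``count`` ions at Gaussian
    radial scatter (σ = ``chain_sigma``) around a helical guide curve
    offset outward from the backbone — the idealisation of the
    groove-localised cation chains seen around condensed duplexes.
    """

    species: str = "MG"
    valence: int = 2
    mode: str = "uniform_bulk"
    concentration: float = 0.0     # mol/L (uniform_bulk)
    chain_sigma: float = 1.0       # Å (helical_groove_chain)
    count: int = 0                 # (helical_groove_chain)
    guide_offset: float = 2.0      # Å outward from backbone radius
    hard_core: float = 2.0         # Å exclusion around existing atoms
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("uniform_bulk", "helical_groove_chain"):
            raise ValueError(f"unknown placement mode {self.mode!r}")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.chain_sigma <= 0:
            raise ValueError("chain_sigma must be positive")


def _ion_structure(positions: np.ndarray, spec: IonPlacementSpec,
                   box: np.ndarray) -> LabeledStructure:
    n = positions.shape[0]
    name = spec.species.upper()
    entry = FIXTURE_ATOM_TABLE.get(name, (float(spec.valence), 23.0, ()))
    charges = np.full(n, float(spec.valence))
    masses = np.full(n, entry[1])
    return LabeledStructure(
        positions=positions,
        names=np.array([name] * n, dtype=object),
        resnames=np.array(["ION"] * n, dtype=object),
        resids=np.arange(n) + 1, charges=charges, masses=masses,
        box=np.asarray(box, float),
        groups={f"ion:{name}": np.arange(n)})


def place_ions(structure: LabeledStructure,
               spec: IonPlacementSpec) -> LabeledStructure:
    """Return a new structure with one ion species added per ``spec``.

    Placements and the generating parameters are recorded in
    ``meta['placements'][species]`` for oracle use.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(structure.box, float)
    if not box.all():
        raise GeometryError("structure has no box; cannot place ions")

    if spec.mode == "uniform_bulk":
        volume_L = box.prod() * A3_TO_L
        count = int(rng.poisson(spec.concentration * volume_L * N_AVOGADRO))
        positions = _place_uniform(rng, count, box, structure.positions,
                                   spec.hard_core)
    else:
        positions = _place_groove_chain(rng, structure, spec)

    ions = _ion_structure(positions, spec, box)
    out = structure.concat(ions)
    out.box = box
    placements = dict(out.meta.get("placements", {}))
    placements[spec.species.upper()] = {
        "mode": spec.mode, "count": int(positions.shape[0]),
        "valence": spec.valence, "seed": spec.seed,
        "chain_sigma": spec.chain_sigma if spec.mode != "uniform_bulk"
        else None,
        "concentration": spec.concentration,
    }
    out.meta["placements"] = placements
    return out


def _place_uniform(rng, count, box, existing, hard_core,
                   max_tries=200) -> np.ndarray:
    if count == 0:
        return np.empty((0, 3))
    from scipy.spatial import cKDTree
    tree = None
    if existing is not None and len(existing):
        tree = cKDTree(np.mod(existing, box), boxsize=box)
    placed = np.empty((0, 3))
    need = count
    for _ in range(max_tries):
        cand = rng.uniform(0, 1, size=(need, 3)) * box
        if tree is not None:
            d, _i = tree.query(cand)
            cand = cand[d > hard_core]
        placed = np.vstack([placed, cand])
        need = count - placed.shape[0]
        if need <= 0:
            return placed[:count]
    raise PackingError(f"could not place {count} ions after {max_tries} "
                       "rounds; box too crowded")


def _guide_curve(structure: LabeledStructure, spec: IonPlacementSpec,
                 helix: str, t: np.ndarray) -> np.ndarray:
    """Helical guide curve offset outward from the backbone, following
    the major-groove bisector of the named helix."""
    hs = structure.meta.get("helix_spec")
    if hs is None:
        raise GeometryError("groove placement needs a duplex fixture "
                            "with helix metadata")
    origin = np.asarray(structure.meta[
        "origin1" if helix == "helix1" else "origin2"], float)
    az0 = hs["azimuth0"] + (structure.meta.get("theta", 0.0)
                            if helix == "helix2" else 0.0)
    radius = hs["backbone_radius"] + spec.guide_offset
    turn = np.deg2rad(hs["twist"]) / hs["rise"]    # rad per Å of z
    phase = az0 + np.deg2rad(hs["groove_phase"]) / 2 + np.pi
    z = t * hs["rise"] * hs["n_bp"]
    az = phase + turn * z
    return np.column_stack([origin[0] + radius * np.cos(az),
                            origin[1] + radius * np.sin(az),
                            origin[2] + z])


def _place_groove_chain(rng, structure, spec) -> np.ndarray:
    helices = [h for h in ("helix1", "helix2") if h in structure.groups]
    if not helices:
        raise GeometryError("no helix groups for groove placement")
    counts = np.diff(np.round(np.linspace(0, spec.count, len(helices) + 1))
                     ).astype(int)
    pts = []
    for helix, c in zip(helices, counts):
        t = rng.uniform(0, 1, size=c)
        guide = _guide_curve(structure, spec, helix, t)
        disp = rng.normal(0.0, spec.chain_sigma, size=(c, 3))
        pts.append(guide + disp)
    return np.vstack(pts) if pts else np.empty((0, 3))


_WATER_OH = 0.9572      # Å, 3-site geometry
_WATER_HOH = np.deg2rad(104.52)


def place_waters(structure: LabeledStructure, count: int,
                 seed: int = 0, hard_core: float = 2.2,
                 region: Optional[Tuple[np.ndarray, float]] = None
                 ) -> LabeledStructure:
    """Add ``count`` rigid 3-site waters at random positions and
    orientations (uniform in the box, or in a cylindrical shell
    ``region=(axis_point, radius)``)."""
    rng = np.random.default_rng(seed)
    box = np.asarray(structure.box, float)
    if region is None:
        opos = _place_uniform(rng, count, box, structure.positions,
                              hard_core)
    else:
        center, radius = region
        ang = rng.uniform(0, 2 * np.pi, count)
        rad = radius * np.sqrt(rng.uniform(0, 1, count))
        z = rng.uniform(0, box[2], count)
        opos = np.column_stack([center[0] + rad * np.cos(ang),
                                center[1] + rad * np.sin(ang), z])
    pos, names = _water_sites(rng, opos)
    n_w = count
    water = LabeledStructure(
        positions=pos, names=names,
        resnames=np.array(["SOL"] * (3 * n_w), dtype=object),
        resids=np.repeat(np.arange(n_w) + 1, 3),
        charges=np.array([FIXTURE_ATOM_TABLE[str(n)][0] for n in names]),
        masses=np.array([FIXTURE_ATOM_TABLE[str(n)][1] for n in names]),
        box=box, groups={})
    out = structure.concat(water)
    out.box = box
    assign_fixture_groups(out)
    return out


def _water_sites(rng, opos: np.ndarray):
    """O + 2 H sites with random rigid orientation per molecule."""
    n = opos.shape[0]
    pos = np.empty((3 * n, 3))
    names = np.empty(3 * n, dtype=object)
    half = _WATER_HOH / 2
    local = np.array([
        [0.0, 0.0, 0.0],
        [_WATER_OH * math.sin(half), 0.0, _WATER_OH * math.cos(half)],
        [-_WATER_OH * math.sin(half), 0.0, _WATER_OH * math.cos(half)],
    ])
    from scipy.spatial.transform import Rotation
    rots = Rotation.random(n, random_state=np.random.RandomState(
        rng.integers(0, 2**31 - 1)))
    for i in range(n):
        pos[3 * i:3 * i + 3] = opos[i] + rots[i].apply(local)
        names[3 * i:3 * i + 3] = ["OW", "HW1", "HW2"]
    return pos, names


# ---------------------------------------------------------------------------
# Thermal velocities
# ---------------------------------------------------------------------------

def sample_velocities(structure: LabeledStructure, temperature: float,
                      seed: int = 0,
                      remove_com: bool = True) -> TrajectoryWindow:
    """Draw Maxwell–Boltzmann velocities at ``temperature`` (K).

    Each Cartesian component is Normal(0, kT/m); net linear momentum is
    projected out afterwards when ``remove_com``.
    """
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    rng = np.random.default_rng(seed)
    m = np.asarray(structure.masses, float)
    if np.any(m <= 0):
        raise ValueError("all masses must be positive")
    if temperature == 0:
        vel = np.zeros_like(structure.positions)
    else:
        sigma = np.sqrt(KB * temperature / (m * 0.01))    # Å/ps
        vel = rng.normal(size=(structure.n_atoms, 3)) * sigma[:, None]
        if remove_com:
            p = (m[:, None] * vel).sum(axis=0)
            vel -= p / m.sum()
    return TrajectoryWindow.single_frame(structure, velocities=vel)


def sample_ou_velocities(structure: LabeledStructure, temperature: float,
                         tau: float, n_frames: int, dt: float,
                         seed: int = 0) -> TrajectoryWindow:
    """Diffusive ideal-gas fixture: per-atom velocities follow an
    Ornstein–Uhlenbeck process with relaxation time ``tau`` (ps) at
    the Maxwell–Boltzmann stationary distribution.

    The exact self-diffusion constant is D = kT·τ/m (internal units),
    giving a Lorentzian velocity spectrum with known zero-frequency
    density — the analytic truth for density-of-states and fluidicity
    tests.  Positions are static (ignored by spectral analyses).
    """
    if temperature <= 0 or tau <= 0:
        raise ValueError("temperature and tau must be positive")
    rng = np.random.default_rng(seed)
    m = np.asarray(structure.masses, float)
    sigma = np.sqrt(KB * temperature / (m * 0.01))
    a = math.exp(-dt / tau)
    b = math.sqrt(1.0 - a * a)
    n = structure.n_atoms
    vel = np.empty((n_frames, n, 3))
    vel[0] = rng.normal(size=(n, 3)) * sigma[:, None]
    for t in range(1, n_frames):
        vel[t] = a * vel[t - 1] + b * sigma[:, None] * rng.normal(
            size=(n, 3))
    pos = np.broadcast_to(structure.positions, (n_frames, n, 3)).copy()
    return TrajectoryWindow(structure=structure, positions=pos,
                            velocities=vel, dt=dt,
                            meta={"tau": tau, "temperature": temperature,
                                  "seed": seed})


# ---------------------------------------------------------------------------
# Toy 2D potential and well-tempered sampler
# ---------------------------------------------------------------------------

@dataclass
class ToyPotential2D:
    """Analytic free-energy landscape F_true(d, θ) for sampler tests.

    ``double_well_d``: quartic double well in d (minima at
    center ± half_sep, barrier height ``barrier`` at the center, linear
    ``tilt`` making it asymmetric) plus a ``k_theta (1 − cos(θ−θ0))``
    azimuthal term.  Separable by construction, so the exact projected
    profile along d is the d-part up to a constant.
    """

    form: str = "double_well_d"
    params: Dict[str, float] = field(default_factory=dict)
    temperature: float = 300.0
    d_range: Tuple[float, float] = (2.2, 4.4)   # nm

    def __post_init__(self):
        defaults = {"center": 3.3, "half_sep": 0.5, "barrier": 12.0,
                    "tilt": 3.0, "k_theta": 2.0, "theta0": 0.25}
        if self.form == "harmonic":
            defaults = {"center": 3.3, "k_d": 20.0, "k_theta": 2.0,
                        "theta0": 0.0}
        self.params = {**defaults, **self.params}

    @property
    def kt(self) -> float:
        return KB * self.temperature

    def d_part(self, d):
        p = self.params
        d = np.asarray(d, dtype=float)
        if self.form == "harmonic":
            return 0.5 * p["k_d"] * (d - p["center"]) ** 2
        u = (d - p["center"]) ** 2 - p["half_sep"] ** 2
        return (p["barrier"] * u ** 2 / p["half_sep"] ** 4
                + p["tilt"] * (d - p["center"]))

    def theta_part(self, theta):
        p = self.params
        return p["k_theta"] * (1.0 - np.cos(np.asarray(theta, float)
                                            - p["theta0"]))

    def energy(self, d, theta):
        return self.d_part(d) + self.theta_part(theta)

    def grad(self, d, theta):
        p = self.params
        if self.form == "harmonic":
            gd = p["k_d"] * (d - p["center"])
        else:
            u = (d - p["center"]) ** 2 - p["half_sep"] ** 2
            gd = (4.0 * p["barrier"] * u * (d - p["center"])
                  / p["half_sep"] ** 4 + p["tilt"])
        gt = p["k_theta"] * math.sin(theta - p["theta0"])
        return gd, gt

    def minima_d(self) -> Tuple[float, float]:
        """Locations of the two wells along d (numerical, exact to
        grid-free precision)."""
        from scipy.optimize import minimize_scalar
        p = self.params
        lo = minimize_scalar(self.d_part, bounds=(
            p["center"] - 2 * p["half_sep"], p["center"]), method="bounded")
        hi = minimize_scalar(self.d_part, bounds=(
            p["center"], p["center"] + 2 * p["half_sep"]), method="bounded")
        return float(lo.x), float(hi.x)

    def delta_f_true(self, d1: float, d2: float) -> float:
        """Exact F(d1) − F(d2) of the projected profile (the θ term is
        separable and cancels)."""
        return float(self.d_part(d1) - self.d_part(d2))


def _bias_and_grad(d, theta, hd, ht, sd, st, h):
    """Sum of deposited Gaussians (θ-periodic via ±2π images) and its
    gradient at one point."""
    if len(hd) == 0:
        return 0.0, 0.0, 0.0
    xd = (d - hd) / sd
    ed = np.exp(-0.5 * xd * xd)
    v = gd = gt = 0.0
    dt0 = theta - ht
    for shift in (-2 * np.pi, 0.0, 2 * np.pi):
        xt = (dt0 + shift) / st
        et = np.exp(-0.5 * xt * xt)
        g = h * ed * et
        v += g.sum()
        gd += (-g * xd / sd).sum()
        gt += (-g * xt / st).sum()
    return v, gd, gt


def run_langevin_wtmd(potential: ToyPotential2D, steps: int, dt: float,
                      friction: float = 10.0, hill_stride: int = 500,
                      hill_height0: float = 1.0,
                      hill_widths: Tuple[float, float] = (0.05, 0.20),
                      bias_factor: float = 10.0, seed: int = 0,
                      x0: Optional[Tuple[float, float]] = None
                      ) -> Tuple[np.ndarray, HillSeries]:
    """Overdamped Langevin dynamics on (d, θ) with well-tempered hill
    deposition.

    Every ``hill_stride`` steps a Gaussian of height
    ``h0·exp(−V_bias/(kT(γ−1)))`` is added at the current CV point
    (the standard well-tempered rescaling).  ``bias_factor`` γ = inf
    gives constant-height (non-tempered) deposition;
    ``hill_height0 = 0`` gives plain Langevin sampling of the
    potential.  Returns the CV trajectory (steps+1, 2) and the
    HillSeries.
    """
    if bias_factor <= 1:
        raise ValueError("bias_factor must exceed 1")
    rng = np.random.default_rng(seed)
    kt = potential.kt
    lo, hi = potential.d_range
    d, theta = x0 if x0 is not None else (
        0.5 * (lo + hi), float(potential.params.get("theta0", 0.0)))
    sd, st = hill_widths
    noise = math.sqrt(2.0 * kt * dt / friction)
    traj = np.empty((steps + 1, 2))
    traj[0] = (d, theta)
    hd_l, ht_l, hh_l, t_l = [], [], [], []
    hd = ht = hh = np.empty(0)
    xi = rng.normal(size=(steps, 2))
    for i in range(steps):
        gd0, gt0 = potential.grad(d, theta)
        _, gdb, gtb = _bias_and_grad(d, theta, hd, ht, sd, st, hh)
        d += -dt / friction * (gd0 + gdb) + noise * xi[i, 0]
        theta += -dt / friction * (gt0 + gtb) + noise * xi[i, 1]
        theta %= 2 * np.pi
        if not lo <= d <= hi:
            raise DomainViolationError(
                f"d = {d:.3f} nm left [{lo}, {hi}] at step {i}", i)
        if hill_height0 > 0 and (i + 1) % hill_stride == 0:
            vb, _, _ = _bias_and_grad(d, theta, hd, ht, sd, st, hh)
            if np.isfinite(bias_factor):
                h = hill_height0 * math.exp(-vb / (kt * (bias_factor - 1)))
            else:
                h = hill_height0
            hd_l.append(d); ht_l.append(theta); hh_l.append(h)
            t_l.append((i + 1) * dt)
            hd = np.array(hd_l); ht = np.array(ht_l); hh = np.array(hh_l)
        traj[i + 1] = (d, theta)
    series = HillSeries(
        times=np.array(t_l), centers_d=np.array(hd_l),
        centers_theta=np.array(ht_l),
        sigma_d=np.full(len(hd_l), sd), sigma_theta=np.full(len(ht_l), st),
        heights=np.array(hh_l), bias_factor=float(bias_factor),
        meta={"seed": seed, "steps": steps, "dt": dt,
              "temperature": potential.temperature})
    return traj, series
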