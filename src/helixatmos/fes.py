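"""Well-tempered metadynamics free-energy reconstruction over the
(d, θ) collective variables.

The deposited bias V(d, θ) is the sum of the recorded Gaussians
(θ-periodic via ±2π images, truncated at 3σ); the free energy follows
from the well-tempered identity F = −γ/(γ−1) · V, shifted so the
global minimum is zero.  γ = ∞ (non-tempered) reduces to F = −V.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .constants import KB
from .io import HillSeries


@dataclass
class FreeEnergySurface:
    """F(d, θ) on a regular grid; θ is periodic with period 2π and the
    minimum is shifted to zero."""

    d: np.ndarray                  # (nd,) nm
    theta: np.ndarray              # (nt,) rad in [0, 2π)
    f: np.ndarray                  # (nd, nt) kJ/mol
    bias_factor: float = 10.0
    temperature: float = 300.0
    meta: dict = field(default_factory=dict)

    @property
    def kt(self) -> float:
        return KB * self.temperature


@dataclass
class ConvergenceDiagnostics:
    """Hill-height decay and block-wise ΔF spread."""

    heights: np.ndarray
    times: np.ndarray
    block_delta_f: np.ndarray
    delta_f_spread: float
    initial_mean_height: float
    final_mean_height: float
    asymptotic: bool
    degraded: bool = False


def default_grids(d_range: Tuple[float, float] = (2.2, 4.2),
                  d_step: float = 0.02,
                  theta_step_deg: float = 2.0
                  ) -> Tuple[np.ndarray, np.ndarray]:
    d = np.arange(d_range[0], d_range[1] + 0.5 * d_step, d_step)
    theta = np.deg2rad(np.arange(0.0, 360.0, theta_step_deg))
    return d, theta


def _bias_on_grid(hills: HillSeries, d: np.ndarray, theta: np.ndarray,
                  upto: Optional[int] = None) -> np.ndarray:
    """Σ hills on the (d, θ) grid, θ-periodic via ±2π images within
    3σ."""
    v = np.zeros((len(d), len(theta)))
    n = len(hills) if upto is None else int(upto)
    for i in range(n):
        cd, ct = hills.centers_d[i], hills.centers_theta[i]
        sd, st = hills.sigma_d[i], hills.sigma_theta[i]
        h = hills.heights[i]
        xd = (d - cd) / sd
        gd = np.where(np.abs(xd) <= 3.0, np.exp(-0.5 * xd * xd), 0.0)
        gt = np.zeros(len(theta))
        for shift in (-2.0 * math.pi, 0.0, 2.0 * math.pi):
            xt = (theta - ct + shift) / st
            gt += np.where(np.abs(xt) <= 3.0, np.exp(-0.5 * xt * xt), 0.0)
        v += h * np.outer(gd, gt)
    return v


def reconstruct_fes(hills: HillSeries, d: Optional[np.ndarray] = None,
                    theta: Optional[np.ndarray] = None,
                    temperature: float = 300.0) -> FreeEnergySurface:
    """Reconstruct F(d, θ) = −γ/(γ−1)·V_bias from a hill series,
    shifted to min 0.  An empty series gives a flat zero surface."""
    if d is None or theta is None:
        dd, tt = default_grids()
        d = dd if d is None else np.asarray(d, float)
        theta = tt if theta is None else np.asarray(theta, float)
    d = np.asarray(d, float)
    theta = np.asarray(theta, float)
    if len(hills):
        if hills.centers_d.min() < d[0] - 1e-9 or \
           hills.centers_d.max() > d[-1] + 1e-9:
            bad = int(np.argmax((hills.centers_d < d[0])
                                | (hills.centers_d > d[-1])))
            raise ValueError(f"hill record {bad} at d = "
                             f"{hills.centers_d[bad]:.3f} nm outside grid "
                             f"[{d[0]}, {d[-1]}]")
    v = _bias_on_grid(hills, d, theta)
    gamma = hills.bias_factor
    scale = 1.0 if not np.isfinite(gamma) else gamma / (gamma - 1.0)
    f = -scale * v
    f -= f.min()
    return FreeEnergySurface(d=d, theta=theta, f=f, bias_factor=gamma,
                             temperature=temperature,
                             meta={"n_hills": len(hills)})


def project_1d(fes: FreeEnergySurface, axis: str = "d") -> Tuple[np.ndarray,
                                                                 np.ndarray]:
    """Boltzmann-weighted projection F(x) = −kT ln ∫ e^{−F/kT} dy,
    re-shifted to min 0.  Returns (grid, profile)."""
    kt = fes.kt
    if axis == "d":
        w = np.exp(-(fes.f - fes.f.min(axis=1, keepdims=True)) / kt)
        lse = np.log(np.trapezoid(w, fes.theta, axis=1))
        prof = fes.f.min(axis=1) - kt * lse
        grid = fes.d
    elif axis == "theta":
        w = np.exp(-(fes.f - fes.f.min(axis=0, keepdims=True)) / kt)
        lse = np.log(np.trapezoid(w, fes.d, axis=0))
        prof = fes.f.min(axis=0) - kt * lse
        grid = fes.theta
    else:
        raise ValueError("axis must be 'd' or 'theta'")
    return grid, prof - prof.min()


def locate_minima(fes: FreeEnergySurface,
                  prominence: float = 1.0) -> List[Tuple[float, float,
                                                         float]]:
    """All local minima (θ-periodic neighbourhoods) below
    max(F) − prominence, with sub-grid quadratic refinement, ordered
    by depth."""
    f = fes.f
    nd, nt = f.shape
    if np.ptp(f) < 1e-12:
        return []
    out = []
    for i in range(nd):
        for j in range(nt):
            nb = [f[i, (j - 1) % nt], f[i, (j + 1) % nt]]
            if i > 0:
                nb.append(f[i - 1, j])
            if i < nd - 1:
                nb.append(f[i + 1, j])
            if all(f[i, j] < v for v in nb) and \
               f[i, j] <= f.max() - prominence:
                di, tj = _refine(fes, i, j)
                out.append((di, tj % (2 * math.pi), float(f[i, j])))
    out.sort(key=lambda m: m[2])
    return out


def _refine(fes: FreeEnergySurface, i: int, j: int) -> Tuple[float, float]:
    """One-dimensional quadratic (three-point) refinement in each CV."""
    f, d, th = fes.f, fes.d, fes.theta
    nd, nt = f.shape

    def parab(fm, f0, fp):
        den = fm - 2 * f0 + fp
        return 0.0 if abs(den) < 1e-15 else 0.5 * (fm - fp) / den

    di = d[i]
    if 0 < i < nd - 1:
        di = d[i] + parab(f[i - 1, j], f[i, j], f[i + 1, j]) * (d[1] - d[0])
    dt = th[1] - th[0]
    tj = th[j] + parab(f[i, (j - 1) % nt], f[i, j],
                       f[i, (j + 1) % nt]) * dt
    return float(di), float(tj)


def delta_f(d_grid: np.ndarray, profile: np.ndarray,
            d_bound: float = 2.8, d_free: float = 4.0,
            n_bp: Optional[int] = None) -> float:
    """Binding free energy ΔF = F(d_bound) − F(d_free) (kJ/mol) by
    linear interpolation on a 1D profile; per-bp when ``n_bp`` is
    given."""
    d_grid = np.asarray(d_grid, float)
    for x in (d_bound, d_free):
        if not d_grid[0] - 1e-9 <= x <= d_grid[-1] + 1e-9:
            raise ValueError(f"d = {x} nm outside profile range "
                             f"[{d_grid[0]}, {d_grid[-1]}]")
    val = float(np.interp(d_bound, d_grid, profile)
                - np.interp(d_free, d_grid, profile))
    return val / n_bp if n_bp else val


def scale_delta_f(per_bp: float, n_bp: int) -> float:
    """Linear additivity of the pairwise interaction:
    ΔF_total(N_bp) = per-bp ΔF × N_bp (kJ/mol)."""
    return per_bp * n_bp


def convergence_diagnostics(hills: HillSeries,
                            d: Optional[np.ndarray] = None,
                            theta: Optional[np.ndarray] = None,
                            n_blocks: int = 4,
                            d_bound: float = 2.8, d_free: float = 4.0,
                            asymptote_fraction: float = 0.2,
                            temperature: float = 300.0
                            ) -> ConvergenceDiagnostics:
    """Hill-height decay plus block-wise ΔF estimates.

    The hill series is cut into ``n_blocks`` cumulative checkpoints;
    the spread of ΔF(d_bound, d_free) across checkpoint surfaces
    measures reconstruction convergence.  The asymptote flag requires
    the final-quarter mean height to fall below
    ``asymptote_fraction`` × the first-quarter mean.
    """
    n = len(hills)
    degraded = n < 2 * n_blocks
    if degraded:
        import warnings
        warnings.warn(f"only {n} hills; convergence diagnostics degraded",
                      stacklevel=2)
        n_blocks = max(1, min(n_blocks, n))
    if d is None or theta is None:
        dd, tt = default_grids((min(2.2, hills.centers_d.min() - 0.1),
                                max(4.2, hills.centers_d.max() + 0.1)))
        d = dd if d is None else d
        theta = tt if theta is None else theta
    block_df = []
    for b in range(1, n_blocks + 1):
        upto = int(round(n * b / n_blocks))
        sub = HillSeries(hills.times[:upto], hills.centers_d[:upto],
                         hills.centers_theta[:upto], hills.sigma_d[:upto],
                         hills.sigma_theta[:upto], hills.heights[:upto],
                         bias_factor=hills.bias_factor)
        surf = reconstruct_fes(sub, d, theta, temperature=temperature)
        grid, prof = project_1d(surf, "d")
        block_df.append(delta_f(grid, prof, d_bound, d_free))
    block_df = np.array(block_df)
    q = max(1, n // 4)
    h0 = float(hills.heights[:q].mean()) if n else 0.0
    h1 = float(hills.heights[-q:].mean()) if n else 0.0
    asym = n > 0 and h0 > 0 and h1 < asymptote_fraction * h0
    return ConvergenceDiagnostics(
        heights=hills.heights.copy(), times=hills.times.copy(),
        block_delta_f=block_df,
        delta_f_spread=float(np.ptp(block_df)) if len(block_df) else 0.0,
        initial_mean_height=h0, final_mean_height=h1,
        asymptotic=bool(asym), degraded=degraded)


def export_polar(fes: FreeEnergySurface):
    """Long-format table (d as radius, θ as angle, F) for polar
    heat-map plotting."""
    import pandas as pd
    dd, tt = np.meshgrid(fes.d, fes.theta, indexing="ij")
    return pd.DataFrame({"d_nm": dd.ravel(), "theta_rad": tt.ravel(),
                         "F_kJmol": fes.f.ravel()})
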