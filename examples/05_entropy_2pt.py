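"""Two-phase-thermodynamics entropy in its two exact limits.

A single oscillating atom is all solid-like (fluidicity f = 0) and
integrates to the quantum-harmonic-oscillator entropy; a diffusive
Maxwell–Boltzmann gas is all gas-like (f → 1) and lands on the
hard-sphere / Sackur–Tetrode value.  Real ions and water fall in
between, which is exactly what the fluidicity interpolates."""

import math

import numpy as np

from helixatmos import LabeledStructure, TrajectoryWindow, synth
from helixatmos import entropy as ent
from helixatmos.constants import H_PLANCK, KB, MVSQ_TO_KJMOL

T = 300.0


def atoms(n, mass, box, seed=0):
    rng = np.random.default_rng(seed)
    return LabeledStructure(
        positions=rng.uniform(0, box, size=(n, 3)),
        names=np.array(["NA"] * n, dtype=object),
        resnames=np.array(["ION"] * n, dtype=object),
        resids=np.arange(n) + 1, charges=np.zeros(n),
        masses=np.full(n, mass), box=np.array([box] * 3),
        groups={"ion:NA": np.arange(n)})


# solid limit: one atom oscillating at ~20 / ps
mass, dt, nsteps = 24.0, 0.004, 8192
nu0 = round(20.0 * nsteps * dt) / (nsteps * dt)
amp = math.sqrt(2 * KB * T / (mass * MVSQ_TO_KJMOL))
vel = np.zeros((nsteps, 1, 3))
vel[:, 0, 0] = amp * np.cos(2 * np.pi * nu0 * np.arange(nsteps) * dt)
w = TrajectoryWindow(structure=atoms(1, mass, 50.0),
                     positions=np.zeros((nsteps, 1, 3)),
                     velocities=vel, dt=dt)
dos = ent.compute_dos(w, "ion:NA", t_corr=nsteps * dt / 2, temperature=T)
part = ent.two_phase_partition(dos)
s = ent.entropy_from_dos(part)["total"]
x = H_PLANCK * nu0 / (KB * T)
qho = KB * 1e3 * (x / math.expm1(x) - math.log1p(-math.exp(-x)))
print(f"oscillator: f = {part.fluidicity:.3f}, "
      f"S = {s:.3f} J/mol/K (QHO closed form {qho:.3f})")

# gas limit: 500 diffusive atoms
n, mg, box = 500, 40.0, 60.0
wg = synth.sample_ou_velocities(atoms(n, mg, box), T, tau=20.0,
                                n_frames=6000, dt=0.05, seed=5)
dosg = ent.compute_dos(wg, "ion:NA", t_corr=100.0)
pg = ent.two_phase_partition(dosg)
sg = ent.entropy_from_dos(pg)["total"]
lam3 = (2 * math.pi * mg * MVSQ_TO_KJMOL * KB * dosg.temperature
        / H_PLANCK ** 2) ** 1.5
st = KB * 1e3 * n * (2.5 + math.log(lam3 * box ** 3 / n))
print(f"diffusive gas: f = {pg.fluidicity:.3f}, "
      f"S = {sg:.0f} J/mol/K (Sackur–Tetrode {st:.0f})")
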