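"""Density-of-states estimation, 2PT partition and entropy, and the
quasiharmonic macromolecule terms, against closed-form oracles."""

import math

import numpy as np
import pytest

from helixatmos import LabeledStructure, TrajectoryWindow, synth
from helixatmos import entropy as ent
from helixatmos.constants import H_PLANCK, KB, MVSQ_TO_KJMOL

from conftest import free_atoms

T = 300.0
KT = KB * T


def qho_closed_form(nu, temperature=T, n_modes=1):
    x = H_PLANCK * nu / (KB * temperature)
    return n_modes * KB * 1e3 * (x / np.expm1(x)
                                 - np.log1p(-np.exp(-x)))


def oscillator_window(nu0=20.0, mass=24.0, nsteps=8192, dt=0.004,
                      n_atoms=1, seed=None, box=50.0):
    """Atoms oscillating at ν₀ along x with thermal amplitude.

    The frequency is snapped to the spectral grid of a half-window
    correlation length (use ``t_corr = nsteps*dt/2``) so the
    undamped tone suffers no truncation leakage."""
    nu0 = round(nu0 * nsteps * dt) / (nsteps * dt)
    amp_v = math.sqrt(2 * KT / (mass * MVSQ_TO_KJMOL))
    t = np.arange(nsteps) * dt
    rng = np.random.default_rng(0 if seed is None else seed)
    phases = rng.uniform(0, 2 * np.pi, n_atoms) if seed is not None \
        else np.zeros(n_atoms)
    s = free_atoms(n_atoms, mass=mass, box=box)
    vel = np.zeros((nsteps, n_atoms, 3))
    vel[:, :, 0] = amp_v * np.cos(2 * np.pi * nu0 * t[:, None]
                                  + phases[None, :])
    pos = np.broadcast_to(s.positions, (nsteps, n_atoms, 3)).copy()
    return TrajectoryWindow(structure=s, positions=pos, velocities=vel,
                            dt=dt), nu0


class TestComputeDos:
    def test_oscillator_peak_and_integral(self):
        w, nu0 = oscillator_window()
        dos = ent.compute_dos(w, "ion:NA", t_corr=16.384,
                              temperature=T)
        assert dos.dof() == pytest.approx(1.0, rel=0.02)
        assert dos.nu[np.argmax(dos.total)] == pytest.approx(nu0,
                                                             abs=2 * dos.dnu)

    def test_free_particle_all_weight_at_zero(self):
        s = free_atoms(5, mass=24.0)
        vel = np.broadcast_to(
            np.random.default_rng(1).normal(0, 3, size=(5, 3)),
            (512, 5, 3)).copy()
        w = TrajectoryWindow(structure=s,
                             positions=np.zeros((512, 5, 3)),
                             velocities=vel, dt=0.01)
        dos = ent.compute_dos(w, "ion:NA", t_corr=1.0)
        assert np.argmax(dos.total) == 0
        assert dos.total[0] > 10 * dos.total[5:].max()

    def test_ideal_gas_dof_and_s0_green_kubo(self):
        n, mass, tau = 400, 40.0, 12.0
        s = free_atoms(n, mass=mass, box=60.0)
        w = synth.sample_ou_velocities(s, T, tau, 4500, 0.05, seed=5)
        dos = ent.compute_dos(w, "ion:NA", t_corr=80.0)
        assert dos.dof() == pytest.approx(3 * n, rel=0.01)
        d_gk = ent.diffusion_constant(w, "ion:NA", t_corr=80.0)
        s0_expect = 12 * mass * MVSQ_TO_KJMOL * n * d_gk \
            / (KB * dos.temperature)
        assert dos.s0 == pytest.approx(s0_expect, rel=0.02)

    def test_requires_velocities(self, small_pair):
        w = TrajectoryWindow.single_frame(small_pair)
        with pytest.raises(ent.CapabilityError):
            ent.compute_dos(w, "dna")

    def test_rigid_molecule_dof_split(self):
        """Equipartitioned rigid waters: 3 translational + 3
        rotational dof per molecule."""
        from scipy.spatial.transform import Rotation
        base = LabeledStructure(
            positions=np.empty((0, 3)), names=np.array([], dtype=object),
            resnames=np.array([], dtype=object),
            resids=np.array([], dtype=int), charges=np.empty(0),
            masses=np.empty(0), box=np.array([60.0] * 3), groups={})
        s = synth.place_waters(base, 25, seed=3, hard_core=0.0)
        rng = np.random.default_rng(8)
        nfr, dt = 400, 0.01
        pos = np.empty((nfr, s.n_atoms, 3))
        vel = np.empty_like(pos)
        for j in range(25):
            sub = slice(3 * j, 3 * j + 3)
            x0 = s.positions[sub]
            m = s.masses[sub]
            com = (m[:, None] * x0).sum(0) / m.sum()
            inertia = np.einsum("i,ij,ik->jk", m, x0 - com, x0 - com)
            inertia = np.trace(inertia) * np.eye(3) - inertia
            ivals, ivecs = np.linalg.eigh(inertia)
            vc = rng.normal(0, math.sqrt(KT / (m.sum() * 0.01)), 3)
            om_p = rng.normal(0, np.sqrt(
                KT / (np.maximum(ivals, 1e-9) * 0.01)))
            om = ivecs @ om_p
            for f in range(nfr):
                rot = Rotation.from_rotvec(om * f * dt)
                xs = rot.apply(x0 - com)
                pos[f, sub] = com + vc * f * dt + xs
                vel[f, sub] = vc + np.cross(om, xs)
        w = TrajectoryWindow(structure=s, positions=pos, velocities=vel,
                             dt=dt)
        dos = ent.compute_dos(w, "water", mode="rigid_molecule",
                              t_corr=2.0)
        assert dos.dof("trans") == pytest.approx(75.0, rel=0.15)
        assert dos.dof("rot") == pytest.approx(75.0, rel=0.15)
        assert dos.dof("total") == pytest.approx(150.0, rel=0.03)


class TestTwoPhasePartition:
    def test_pure_solid_limit(self):
        w, _ = oscillator_window()
        dos = ent.compute_dos(w, "ion:NA", t_corr=16.384,
                              temperature=T)
        part = ent.two_phase_partition(dos)
        assert part.fluidicity == 0.0
        assert np.all(part.gas == 0.0)

    def test_ideal_gas_fluidicity_near_one(self):
        s = free_atoms(500, mass=40.0, box=60.0)
        w = synth.sample_ou_velocities(s, T, 20.0, 6000, 0.05, seed=5)
        dos = ent.compute_dos(w, "ion:NA", t_corr=100.0)
        part = ent.two_phase_partition(dos)
        assert part.fluidicity == pytest.approx(1.0, abs=0.02)

    def test_components_sum_to_total(self):
        s = free_atoms(200, mass=30.0, box=50.0)
        w = synth.sample_ou_velocities(s, T, 3.0, 3000, 0.05, seed=9)
        dos = ent.compute_dos(w, "ion:NA", t_corr=40.0)
        part = ent.two_phase_partition(dos)
        # pre-clipping identity: gas + solid = total wherever the gas
        # model did not exceed the measured DoS
        unclipped = part.gas < dos.total
        resid = part.gas + part.solid - dos.total
        assert np.max(np.abs(resid[unclipped])) < 1e-9 * dos.total.max()
        assert np.trapezoid(part.gas, dos.nu) == pytest.approx(
            3 * 200 * part.fluidicity, rel=0.02)


class TestEntropyFromDos:
    def test_oscillator_matches_qho_closed_form(self):
        w, nu0 = oscillator_window()
        dos = ent.compute_dos(w, "ion:NA", t_corr=16.384,
                              temperature=T)
        part = ent.two_phase_partition(dos)
        s = ent.entropy_from_dos(part)["total"]
        assert s == pytest.approx(qho_closed_form(nu0), rel=0.01)

    def test_high_frequency_mode_frozen(self):
        w, nu0 = oscillator_window(nu0=2000.0, dt=0.0002, nsteps=16384)
        dos = ent.compute_dos(w, "ion:NA", t_corr=1.0, temperature=T)
        part = ent.two_phase_partition(dos)
        s = ent.entropy_from_dos(part)["total"]
        assert s < 1e-8 * KB * 1e3
        assert qho_closed_form(nu0) < 1e-8 * KB * 1e3

    def test_ideal_gas_matches_hard_sphere_closed_form(self):
        n, mass, box = 500, 40.0, 60.0
        s = free_atoms(n, mass=mass, box=box)
        w = synth.sample_ou_velocities(s, T, 20.0, 6000, 0.05, seed=5)
        dos = ent.compute_dos(w, "ion:NA", t_corr=100.0)
        part = ent.two_phase_partition(dos)
        got = ent.entropy_from_dos(part)["total"]
        lam3 = (2 * math.pi * mass * MVSQ_TO_KJMOL * KB
                * dos.temperature / H_PLANCK ** 2) ** 1.5
        sackur_tetrode = KB * 1e3 * n * (2.5 + math.log(
            lam3 * box ** 3 / n))
        assert got == pytest.approx(sackur_tetrode, rel=0.03)

    def test_monotone_in_temperature(self):
        w, _ = oscillator_window()
        vals = []
        for temp in (250.0, 300.0, 350.0):
            dos = ent.compute_dos(w, "ion:NA", t_corr=16.0,
                                  temperature=temp)
            part = ent.two_phase_partition(dos)
            vals.append(ent.entropy_from_dos(part)["total"])
        assert vals[0] < vals[1] < vals[2]


class TestMacromoleculeEntropy:
    def rigid_body_window(self, disp_sigma, n_frames=1500, rot_sigma=0.0,
                          seed=3):
        rng = np.random.default_rng(seed)
        base = rng.uniform(-6, 6, size=(12, 3))
        masses = np.full(12, 80.0)
        base -= (masses[:, None] * base).sum(0) / masses.sum()
        from scipy.spatial.transform import Rotation
        pos = np.empty((n_frames, 12, 3))
        for f in range(n_frames):
            x = base
            if rot_sigma > 0:
                x = Rotation.from_rotvec(
                    rng.normal(0, rot_sigma, 3)).apply(base)
            pos[f] = x + rng.normal(0, disp_sigma, 3)
        s = LabeledStructure(
            positions=pos[0], names=np.array(["P"] * 12, dtype=object),
            resnames=np.array(["DP"] * 12, dtype=object),
            resids=np.arange(12) + 1, charges=np.zeros(12),
            masses=masses, box=np.array([100.0] * 3),
            groups={"helix2": np.arange(12)})
        return TrajectoryWindow(structure=s, positions=pos)

    def test_frozen_helix_zero_entropy(self):
        w = self.rigid_body_window(disp_sigma=0.0, n_frames=50)
        r = ent.mcc_macromolecule_entropy(w, "helix2", T)
        assert r["total"] == 0.0

    def test_tethered_com_matches_qho(self):
        k_spring, mass_tot = 5.0, 12 * 80.0
        sigma = math.sqrt(KT / k_spring)
        w = self.rigid_body_window(disp_sigma=sigma, n_frames=4000)
        r = ent.mcc_macromolecule_entropy(w, "helix2", T)
        nu = math.sqrt(k_spring / (mass_tot * MVSQ_TO_KJMOL)) \
            / (2 * math.pi)
        assert r["transvib"] == pytest.approx(qho_closed_form(nu, T, 3),
                                              rel=0.02)

    def test_global_rotation_invariance(self):
        from scipy.spatial.transform import Rotation
        w = self.rigid_body_window(disp_sigma=0.3, rot_sigma=0.05,
                                   n_frames=800)
        r0 = ent.mcc_macromolecule_entropy(w, "helix2", T)
        rot = Rotation.from_euler("zxz", [0.8, 0.4, -1.2])
        w2 = TrajectoryWindow(structure=w.structure,
                              positions=rot.apply(
                                  w.positions.reshape(-1, 3)).reshape(
                                      w.positions.shape))
        r1 = ent.mcc_macromolecule_entropy(w2, "helix2", T)
        assert r1["total"] == pytest.approx(r0["total"], rel=1e-6)


class TestEntropyChangeReport:
    def ou_ion_window(self, seed, tau=5.0):
        s = free_atoms(100, mass=24.0, box=40.0, name="MG", seed=1)
        return synth.sample_ou_velocities(s, T, tau, 2500, 0.05,
                                          seed=seed)

    def test_identical_states_near_zero(self):
        wa = self.ou_ion_window(seed=2)
        wb = self.ou_ion_window(seed=2)
        rep = ent.entropy_change_report(wa, wb, T, n_blocks=5)
        assert rep.minus_t_ds["cation"] == pytest.approx(0.0, abs=1e-9)
        assert set(rep.missing) == {"dna", "water"}

    def test_oscillator_frequency_shift_closed_form(self):
        n = 50

        def osc_state(nu):
            w, nu_snap = oscillator_window(nu0=nu, nsteps=4096, dt=0.004,
                                           n_atoms=n, seed=4)
            w.structure.groups["ion:MG"] = \
                w.structure.groups.pop("ion:NA")
            return w, nu_snap

        wa, nu_a = osc_state(10.0)
        wb, nu_b = osc_state(20.0)
        rep = ent.entropy_change_report(wa, wb, T, n_blocks=2)
        expect = -T * 1e-3 * (qho_closed_form(nu_a, T, n)
                              - qho_closed_form(nu_b, T, n))
        assert rep.minus_t_ds["cation"] == pytest.approx(expect, rel=0.02)

    def test_total_is_component_sum(self):
        wa = self.ou_ion_window(seed=2)
        wb = self.ou_ion_window(seed=3)
        rep = ent.entropy_change_report(wa, wb, T, n_blocks=4)
        avail = [rep.minus_t_ds[c] for c in rep.components
                 if c not in rep.missing]
        assert rep.minus_t_ds["total"] == pytest.approx(sum(avail),
                                                        abs=1e-9)
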