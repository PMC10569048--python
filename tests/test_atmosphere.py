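"""Density fields, cylindrical concentration, excess-ion/charge
integrals and pair correlations, checked against counting and
quadrature oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from helixatmos import (IonPlacementSpec, RadialProfile, TrajectoryWindow,
                        place_ions)
from helixatmos import atmosphere as atm
from helixatmos.constants import A3_TO_L, N_AVOGADRO
from helixatmos.core import EmptySelectionError

from conftest import free_atoms


def ion_window(positions, box, name="MG", charge=2.0, frames=None):
    """Window of bare ions at given positions (one frame unless a
    (nf, n, 3) array is passed)."""
    from helixatmos.core import LabeledStructure
    pos = np.asarray(positions, float)
    if pos.ndim == 2:
        pos = pos[None]
    if frames is not None:
        pos = frames
    n = pos.shape[1]
    s = LabeledStructure(
        positions=pos[0],
        names=np.array([name] * n, dtype=object),
        resnames=np.array(["ION"] * n, dtype=object),
        resids=np.arange(n) + 1, charges=np.full(n, charge),
        masses=np.full(n, 24.0), box=np.asarray(box, float),
        groups={f"ion:{name}": np.arange(n)})
    return TrajectoryWindow(structure=s, positions=pos)


class TestNumberDensity:
    def test_single_ion_single_voxel(self):
        box = [10.0, 10.0, 10.0]
        w = ion_window([[3.5, 4.5, 5.5]], box)
        f = atm.number_density(w, "ion:MG", spacing=1.0)
        assert f.values[3, 4, 5] == pytest.approx(1.0)
        assert f.values.sum() == pytest.approx(1.0)

    def test_two_frame_average(self):
        box = [10.0, 10.0, 10.0]
        frames = np.array([[[1.5, 1.5, 1.5]], [[7.5, 7.5, 7.5]]])
        w = ion_window(frames[0], box, frames=frames)
        f = atm.number_density(w, "ion:MG", spacing=1.0)
        assert f.values[1, 1, 1] == pytest.approx(0.5)
        assert f.values[7, 7, 7] == pytest.approx(0.5)

    def test_conservation(self, duplex_pair):
        s = place_ions(duplex_pair, IonPlacementSpec(concentration=0.3,
                                                     seed=1))
        w = TrajectoryWindow.single_frame(s)
        f = atm.number_density(w, "ion:MG")
        n = len(s.group("ion:MG"))
        assert abs(f.integral() - n) / n < 1e-6

    def test_empty_group_errors(self, small_pair):
        w = TrajectoryWindow.single_frame(small_pair)
        with pytest.raises(EmptySelectionError):
            atm.number_density(w, "ion:MG")

    def test_poisson_voxel_statistics(self):
        rng = np.random.default_rng(5)
        box = np.array([20.0, 20.0, 20.0])
        nf, n = 50, 400
        frames = rng.uniform(0, 1, size=(nf, n, 3)) * box
        w = ion_window(frames[0], box, frames=frames)
        f = atm.number_density(w, "ion:MG", spacing=2.0)
        counts = f.values * f.voxel_volume * nf
        # per-voxel counts ~ Poisson: index of dispersion ≈ 1
        disp = counts.var() / counts.mean()
        assert disp == pytest.approx(1.0, abs=0.15)


class TestExports:
    def test_hdf5_and_opendx_round_trip(self, tmp_path):
        import h5py
        w = ion_window([[3.5, 4.5, 5.5]], [10.0, 10.0, 10.0])
        f = atm.number_density(w, "ion:MG", spacing=1.0)
        h5 = str(tmp_path / "field.h5")
        atm.export_hdf5(f, h5)
        with h5py.File(h5) as fh:
            assert np.allclose(fh["density"][...], f.values)
            assert fh["density"].attrs["spacing"] == 1.0
        dx = str(tmp_path / "field.dx")
        atm.export_opendx(f, dx)
        text = open(dx).read()
        assert "gridpositions counts 10 10 10" in text

    def test_profile_tsv(self, tmp_path):
        prof = RadialProfile(edges=np.arange(4.0),
                             values=np.array([1.0, 2.0, 3.0]),
                             kind="rdf", meta={"species": "MG"})
        p = str(tmp_path / "prof.tsv")
        atm.profile_to_tsv(prof, p)
        import pandas as pd
        df = pd.read_csv(p, sep="\t", comment="#")
        assert list(df["value"]) == [1.0, 2.0, 3.0]


class TestCylindricalConcentration:
    def test_uniform_flat(self, duplex_pair):
        s = place_ions(duplex_pair, IonPlacementSpec(
            concentration=0.5, seed=2, hard_core=0.0))
        w = TrajectoryWindow.single_frame(s)
        prof = atm.cylindrical_concentration(w, "ion:MG", bin_width=5.0,
                                             lambda_max=40.0)
        c0 = 0.5
        for value, count, edge_lo, edge_hi in zip(
                prof.values, prof.counts, prof.edges[:-1], prof.edges[1:]):
            vol_L = math.pi * (edge_hi ** 2 - edge_lo ** 2) \
                * duplex_pair.box[2] * A3_TO_L
            expect = c0 * N_AVOGADRO * vol_L
            sigma = math.sqrt(max(expect, 1.0))
            assert abs(count - expect) < 4 * sigma

    def test_delta_shell_closed_form(self):
        # ring of ions at λ = 10.2 Å about a 2-point axis marker
        box = [60.0, 60.0, 30.0]
        n, lam0 = 120, 10.2
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        ring = np.column_stack([30 + lam0 * np.cos(ang),
                                30 + lam0 * np.sin(ang),
                                np.linspace(0, 29, n)])
        markers = np.array([[30.0, 30.0, 0.0], [30.0, 30.0, 29.0]])
        w = ion_window(np.vstack([ring, markers]), box)
        w.structure.groups["ion:MG"] = np.arange(n)
        w.structure.groups["helix1"] = np.array([n, n + 1])
        prof = atm.cylindrical_concentration(w, "ion:MG", bin_width=0.5)
        occupied = np.nonzero(prof.counts)[0]
        assert len(occupied) == 1
        b = occupied[0]
        assert prof.edges[b] <= lam0 <= prof.edges[b + 1]
        assert prof.counts[b] == n
        shell_vol_L = (math.pi * (prof.edges[b + 1] ** 2
                                  - prof.edges[b] ** 2) * 30.0 * A3_TO_L)
        assert prof.values[b] == pytest.approx(
            n / (N_AVOGADRO * shell_vol_L), rel=1e-12)

    def test_profile_conserves_count(self):
        # all ions within λ_max: integral returns the exact count
        rng = np.random.default_rng(3)
        box = np.array([60.0, 60.0, 30.0])
        n = 500
        ang = rng.uniform(0, 2 * np.pi, n)
        rad = 25.0 * np.sqrt(rng.uniform(0, 1, n))
        pts = np.column_stack([30 + rad * np.cos(ang),
                               30 + rad * np.sin(ang),
                               rng.uniform(0, 30, n)])
        w = ion_window(pts, box)
        w.structure.groups["helix1"] = np.array([0, 1])
        w.structure.positions[:2] = [[30, 30, 0], [30, 30, 29]]
        w.positions[0, :2] = [[30, 30, 0], [30, 30, 29]]
        prof = atm.cylindrical_concentration(w, "ion:MG", bin_width=0.5)
        total = (prof.values * N_AVOGADRO * math.pi
                 * (prof.edges[1:] ** 2 - prof.edges[:-1] ** 2)
                 * 30.0 * A3_TO_L).sum()
        assert abs(total - n) / n < 1e-6

    def test_field_route_matches_direct(self, duplex_pair):
        s = place_ions(duplex_pair, IonPlacementSpec(concentration=0.4,
                                                     seed=9))
        w = TrajectoryWindow.single_frame(s)
        direct = atm.cylindrical_concentration(w, "ion:MG", bin_width=2.0,
                                               lambda_max=40.0)
        field = atm.number_density(w, "ion:MG", spacing=1.0)
        from helixatmos.core import fit_helix_axis
        c, _ = fit_helix_axis(s.positions[np.intersect1d(
            s.group("helix1"), s.group("phosphate_backbone"))])
        via_field = atm.cylindrical_from_field(field, c[:2],
                                               L=duplex_pair.box[2],
                                               bin_width=2.0,
                                               lambda_max=40.0)
        # both integrate to the same ion content over the cylinder
        def content(p):
            return (p.values * (p.edges[1:] ** 2 - p.edges[:-1] ** 2)).sum()
        assert content(via_field) == pytest.approx(content(direct),
                                                   rel=0.05)

    def test_lambda_max_out_of_range(self, duplex_pair):
        s = place_ions(duplex_pair, IonPlacementSpec(concentration=0.1,
                                                     seed=1))
        w = TrajectoryWindow.single_frame(s)
        with pytest.raises(ValueError):
            atm.cylindrical_concentration(w, "ion:MG", lambda_max=100.0)


class TestExcessIons:
    def flat_profile(self, c, edges=None):
        if edges is None:
            edges = np.arange(0.0, 30.5, 0.5)
        return RadialProfile(edges=edges, values=np.full(len(edges) - 1, c),
                             kind="cylindrical_concentration",
                             meta={"L": 68.0})

    def test_uniform_gives_zero(self):
        prof = self.flat_profile(0.1)
        for r in (5.0, 10.0, 20.0, 30.0):
            assert atm.excess_ions(prof, c_bulk=0.1, R=r) == 0.0

    def test_step_profile_matches_quadrature(self):
        c_bulk, l_ax = 0.1, 68.0
        edges = np.arange(0.0, 30.25, 0.25)
        centers = 0.5 * (edges[:-1] + edges[1:])
        vals = np.where(centers < 10.0, 2 * c_bulk, c_bulk)
        prof = RadialProfile(edges=edges, values=vals,
                             kind="cylindrical_concentration",
                             meta={"L": l_ax})
        got = atm.excess_ions(prof, c_bulk=c_bulk, R=20.0)
        ref, _ = quad(lambda lam: (np.interp(lam, centers, vals) - c_bulk)
                      * 2 * math.pi * lam, 0, 20.0, limit=400)
        ref *= N_AVOGADRO * l_ax * A3_TO_L
        assert got == pytest.approx(ref, rel=5e-3)
        # analytic: N_A · c_bulk · π · 10² · L (only the doubled core)
        analytic = N_AVOGADRO * c_bulk * math.pi * 100.0 * l_ax * A3_TO_L
        assert got == pytest.approx(analytic, rel=5e-3)

    def test_monotone_when_above_bulk(self):
        rng = np.random.default_rng(1)
        edges = np.arange(0.0, 20.5, 0.5)
        vals = 0.1 + rng.uniform(0, 0.3, len(edges) - 1)
        prof = RadialProfile(edges=edges, values=vals,
                             kind="cylindrical_concentration",
                             meta={"L": 68.0})
        rs = np.arange(1.0, 20.1, 1.0)
        out = atm.excess_ions(prof, c_bulk=0.1, R=rs)
        assert np.all(np.diff(out) >= -1e-12)

    def test_r_out_of_range(self):
        prof = self.flat_profile(0.1)
        with pytest.raises(ValueError):
            atm.excess_ions(prof, c_bulk=0.1, R=100.0)


class TestExcessChargeByShell:
    def test_single_ion_bracketing(self, small_pair):
        s = small_pair
        ref = s.positions[s.group("dna")]
        # point 5 Å outward from one phosphate, along +x from the axis
        p = ref[0] + np.array([5.0, 0.0, 0.0])
        from helixatmos.core import LabeledStructure
        ion = LabeledStructure(
            positions=p[None], names=np.array(["MG"], dtype=object),
            resnames=np.array(["ION"], dtype=object), resids=np.array([1]),
            charges=np.array([2.0]), masses=np.array([24.0]),
            box=s.box.copy(), groups={"ion:MG": np.array([0])})
        merged = s.concat(ion)
        w = TrajectoryWindow.single_frame(merged)
        d = atm.surface_distances(p[None], ref, s.box)
        assert d[0] <= 5.0 + 1e-9           # nearest atom may be closer
        rep = atm.excess_charge_by_shell(w)
        assert rep["R2"]["total"] == pytest.approx(2.0)
        assert rep["R3"]["total"] == pytest.approx(2.0)

    def test_constructed_r2_charge(self, small_pair):
        # 20 Mg²⁺ at 4 Å surface distance: R2 charge = +40e exactly
        rng = np.random.default_rng(2)
        s = small_pair
        ref = s.positions[s.group("dna")]
        picks = rng.choice(len(ref), 20, replace=False)
        dirs = rng.normal(size=(20, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        pts = []
        for i, k in enumerate(picks):
            cand = ref[k] + 4.0 * dirs[i]
            d = atm.surface_distances(cand[None], ref, s.box)[0]
            # keep only placements whose *nearest* surface distance is
            # still inside R2 and outside R1
            if 3.5 < d <= 6.0:
                pts.append(cand)
        from helixatmos.core import LabeledStructure
        n = len(pts)
        ion = LabeledStructure(
            positions=np.array(pts), names=np.array(["MG"] * n,
                                                    dtype=object),
            resnames=np.array(["ION"] * n, dtype=object),
            resids=np.arange(n) + 1, charges=np.full(n, 2.0),
            masses=np.full(n, 24.0), box=s.box.copy(),
            groups={"ion:MG": np.arange(n)})
        w = TrajectoryWindow.single_frame(s.concat(ion))
        rep = atm.excess_charge_by_shell(w)
        assert rep["R2"]["ion:MG"] == pytest.approx(2.0 * n, abs=1e-12)
        assert rep["R1"]["ion:MG"] == pytest.approx(0.0, abs=1e-12)

    def test_electroneutrality_whole_box(self, small_pair):
        s = place_ions(small_pair, IonPlacementSpec(
            species="MG", valence=2, concentration=0.3, seed=4))
        n_mg = s.meta["placements"]["MG"]["count"]
        dna_q = s.charges[s.group("dna")].sum()
        n_cl = int(2 * n_mg + dna_q)
        if n_cl > 0:
            s = place_ions(s, IonPlacementSpec(
                species="CL", valence=-1, concentration=0.0, seed=5,
                mode="helical_groove_chain", count=n_cl, chain_sigma=8.0))
        w = TrajectoryWindow.single_frame(s)
        big = float(np.linalg.norm(s.box)) + 1.0
        rep = atm.excess_charge_by_shell(
            w, shells={"R1": 3.5, "ALL": big})
        total = rep["ALL"]["total"] + rep["reference_charge"]
        assert abs(total) < 1e-9


class TestPairCorrelations:
    def test_rdf_two_atoms_single_peak(self):
        box = [40.0, 40.0, 40.0]
        w = ion_window([[10, 10, 10], [15, 10, 10]], box)
        w.structure.groups["a"] = np.array([0])
        w.structure.groups["b"] = np.array([1])
        prof = atm.rdf(w, "a", "b", bin_width=0.5, r_max=18.0)
        peak = np.nonzero(prof.counts)[0]
        assert len(peak) == 1
        assert prof.edges[peak[0]] <= 5.0 < prof.edges[peak[0] + 1]

    def test_rdf_ideal_gas_flat(self):
        rng = np.random.default_rng(8)
        box = np.array([30.0, 30.0, 30.0])
        nf = 40
        frames = rng.uniform(0, 1, size=(nf, 300, 3)) * box
        w = ion_window(frames[0], box, frames=frames)
        w.structure.groups["probe"] = np.array([0])
        prof = atm.rdf(w, "probe", "ion:MG", bin_width=1.0, r_max=14.0)
        sel = prof.centers > 2.0
        expect = prof.meta["rho_target"] * 4 / 3 * np.pi * (
            prof.edges[1:] ** 3 - prof.edges[:-1] ** 3) * nf
        sigma_g = np.sqrt(expect) / expect
        assert np.all(np.abs(prof.values[sel] - 1.0)
                      < 4 * sigma_g[sel] + 0.05)

    def test_rdf_coordination_count(self):
        # shell of exactly 12 ions at 5 Å around a probe
        box = [40.0, 40.0, 40.0]
        rng = np.random.default_rng(3)
        dirs = rng.normal(size=(12, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        pts = 20.0 + 5.0 * dirs
        w = ion_window(np.vstack([[[20, 20, 20]], pts]), box)
        w.structure.groups["probe"] = np.array([0])
        w.structure.groups["shell"] = np.arange(1, 13)
        prof = atm.rdf(w, "probe", "shell", bin_width=0.5, r_max=10.0)
        assert atm.coordination_number(prof, 7.0) == pytest.approx(
            12.0, rel=0.02)

    def test_sdf_point_reference_equals_rdf(self):
        rng = np.random.default_rng(4)
        box = np.array([30.0, 30.0, 30.0])
        frames = rng.uniform(0, 1, size=(20, 200, 3)) * box
        w = ion_window(frames[0], box, frames=frames)
        w.structure.groups["probe"] = np.array([0])
        kw = dict(bin_width=1.0, r_max=12.0)
        g_r = atm.rdf(w, "probe", "ion:MG", **kw)
        g_s = atm.sdf(w, "probe", "ion:MG", mc_samples=2_000_000, seed=1,
                      **kw)
        sel = (g_r.centers > 2.0) & (g_r.counts > 20)
        assert np.allclose(g_r.values[sel], g_s.values[sel], atol=0.25)

    def test_sdf_uniform_flat(self, duplex_pair):
        rng = np.random.default_rng(6)
        box = np.asarray(duplex_pair.box)
        nf, n = 25, 400
        ion_frames = rng.uniform(0, 1, size=(nf, n, 3)) * box
        from helixatmos.core import LabeledStructure, TrajectoryWindow
        na = duplex_pair.n_atoms
        ions = LabeledStructure(
            positions=ion_frames[0],
            names=np.array(["NA"] * n, dtype=object),
            resnames=np.array(["ION"] * n, dtype=object),
            resids=np.arange(n) + 1, charges=np.ones(n),
            masses=np.full(n, 23.0), box=box,
            groups={"ion:NA": np.arange(n)})
        merged = duplex_pair.concat(ions)
        pos = np.repeat(merged.positions[None], nf, axis=0)
        pos[:, na:, :] = ion_frames
        w = TrajectoryWindow(structure=merged, positions=pos)
        prof = atm.sdf(w, "dna", "ion:NA", bin_width=1.0, r_max=20.0,
                       mc_samples=2_000_000, seed=7)
        rho = prof.meta["rho_target"]
        vols = np.asarray(prof.meta["shell_volumes"])
        expect = rho * vols * nf
        ok = expect > 25
        sigma_g = np.sqrt(expect[ok]) / expect[ok]
        assert np.all(np.abs(prof.values[ok] - 1.0) < 3 * sigma_g + 0.03)

    def test_sdf_groove_mode_matches_guide_distance(self, duplex_pair):
        s = place_ions(duplex_pair, IonPlacementSpec(
            mode="helical_groove_chain", count=2000, chain_sigma=1.0,
            seed=9))
        w = TrajectoryWindow.single_frame(s)
        prof = atm.sdf(w, "dna", "ion:MG", bin_width=0.5, r_max=12.0,
                       mc_samples=500_000, seed=2)
        # oracle: surface distance of the σ→0 guide placements
        zero = place_ions(duplex_pair, IonPlacementSpec(
            mode="helical_groove_chain", count=2000, chain_sigma=1e-12,
            seed=9))
        d_guide = atm.surface_distances(
            zero.positions[zero.group("ion:MG")],
            duplex_pair.positions[duplex_pair.group("dna")],
            duplex_pair.box)
        mode_guide = np.median(d_guide)
        mode_bin = prof.centers[np.argmax(prof.counts)]
        assert abs(mode_bin - mode_guide) <= 1.0

    def test_sdf_resolution_error(self, duplex_pair):
        s = place_ions(duplex_pair, IonPlacementSpec(concentration=0.3,
                                                     seed=1))
        w = TrajectoryWindow.single_frame(s)
        with pytest.raises(atm.ResolutionError):
            atm.sdf(w, "dna", "ion:MG", bin_width=0.25, r_max=20.0,
                    mc_samples=500, seed=3, mc_rel_tol=0.02)
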