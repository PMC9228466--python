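"""Ground-truth generators: determinism and statistical self-consistency."""

import io

import numpy as np
import pytest

from cntdiff.descriptors import (hydration_count, make_whole, moiety_com,
                                 tilt_angle, axial_orientation,
                                 vertical_distribution, fit_peaks)
from cntdiff.diffusion import compute_msd, fit_diffusion
from cntdiff.geometry import UnwrappedPath, decompose_path, signed_vertical_distance
from cntdiff.synthetic import (AdsorbateModel, BrownianParams,
                               GaussianMixture1D, SolventModel, dopamine_like,
                               simulate_adsorbate, simulate_solvent,
                               simulate_surface_brownian,
                               simulate_wall_switching)
from cntdiff.trajio import read_lammps_dump, write_lammps_dump
from cntdiff.units import molar_mass


def _static_path(n, s_par=40.0, s_perp=40.0, dt=1.0):
    t = np.arange(n) * dt
    return UnwrappedPath(t, np.full(n, s_par), np.full(n, s_perp), np.zeros(n))


class TestBrownian:
    def test_zero_D_stationary(self, cnt_ext_spec):
        p = BrownianParams(D_par=0, D_perp=0, dt=0.1, n_steps=100, seed=1,
                           surface=cnt_ext_spec)
        path, traj = simulate_surface_brownian(p)
        assert np.ptp(path.s_par) == 0 and np.ptp(path.s_perp) == 0
        assert np.ptp(traj.coords, axis=0).max() == 0

    def test_seed_determinism(self, cnt_ext_spec):
        p = BrownianParams(D_par=1.4, D_perp=3.5, dt=0.1, n_steps=500, seed=42,
                           surface=cnt_ext_spec)
        path1, traj1 = simulate_surface_brownian(p)
        path2, traj2 = simulate_surface_brownian(p)
        assert np.array_equal(path1.s_par, path2.s_par)
        assert np.array_equal(traj1.coords, traj2.coords)

    def test_anisotropic_recovery_on_cylinder(self, cnt_int_spec):
        """D∥, D⊥ and their ratio recovered from the full estimator stack."""
        d_par, d_perp = 1.4, 3.5
        paths = []
        for s in range(10):
            p = BrownianParams(D_par=d_par, D_perp=d_perp, dt=0.1,
                               n_steps=100000, seed=1000 + s,
                               surface=cnt_int_spec)
            _, traj = simulate_surface_brownian(p)
            paths.append(decompose_path(traj.coords[:, 0, :], cnt_int_spec,
                                        times=traj.times))
        res = fit_diffusion(compute_msd(paths, "par", 20.0),
                            compute_msd(paths, "perp", 20.0))
        assert res.D_par == pytest.approx(d_par, rel=0.10)
        assert res.D_perp == pytest.approx(d_perp, rel=0.10)
        assert res.D_perp / res.D_par == pytest.approx(d_perp / d_par, rel=0.15)

    def test_isotropic_plane_components_agree(self, plane_spec):
        paths = []
        for s in range(8):
            p = BrownianParams(D_par=1.25, D_perp=1.25, dt=0.1, n_steps=50000,
                               seed=2000 + s, surface=plane_spec, s_par0=40,
                               s_perp0=40)
            path, _ = simulate_surface_brownian(p)
            paths.append(path)
        res = fit_diffusion(compute_msd(paths, "par", 20.0),
                            compute_msd(paths, "perp", 20.0))
        spread = np.hypot(res.err_par, res.err_perp)
        assert abs(res.D_par - res.D_perp) < 2 * spread + 0.05


class TestAdsorbate:
    def test_delta_distributions_exact_on_plane(self, plane_spec, dopamine):
        tpl, species, moi = dopamine
        model = AdsorbateModel(tpl, species, moi,
                               d_dist=GaussianMixture1D.delta(3.5),
                               tilt_dist=GaussianMixture1D.delta(0.0),
                               orient_dist=GaussianMixture1D.delta(0.0))
        traj = simulate_adsorbate(model, _static_path(5), plane_spec, seed=1)
        f = make_whole(traj.coords[0], plane_spec.box, plane_spec.periodic)
        com = moiety_com(f, moi, "amine")
        assert signed_vertical_distance(com[None], plane_spec)[0] == pytest.approx(3.5, abs=1e-9)
        assert tilt_angle(f[moi.c2], f[moi.c7], plane_spec) == pytest.approx(0.0, abs=1e-9)
        assert axial_orientation(f[moi.c2], f[moi.c7], axis=(1, 0, 0)) == pytest.approx(0.0, abs=1e-9)

    def test_nonzero_deltas_recovered(self, plane_spec, dopamine):
        tpl, species, moi = dopamine
        model = AdsorbateModel(tpl, species, moi,
                               d_dist=GaussianMixture1D.delta(4.2),
                               tilt_dist=GaussianMixture1D.delta(15.0),
                               orient_dist=GaussianMixture1D.delta(0.0))
        traj = simulate_adsorbate(model, _static_path(3), plane_spec, seed=2)
        f = make_whole(traj.coords[0], plane_spec.box, plane_spec.periodic)
        assert tilt_angle(f[moi.c2], f[moi.c7], plane_spec) == pytest.approx(15.0, abs=1e-9)
        com = moiety_com(f, moi, "amine")
        assert signed_vertical_distance(com[None], plane_spec)[0] == pytest.approx(4.2, abs=1e-9)

    def test_tilt_mixture_bimodal(self, plane_spec, dopamine):
        # modes at 0 and 15 deg appear as two histogram peaks
        tpl, species, moi = dopamine
        model = AdsorbateModel(
            tpl, species, moi,
            tilt_dist=GaussianMixture1D((0.55, 0.45), (0.0, 15.0), (2.0, 2.0)),
            corr_time=0.0)
        traj = simulate_adsorbate(model, _static_path(30000), plane_spec, seed=3)
        # static base path far from the box edge: no re-wrapping needed
        tilts = np.array([
            tilt_angle(traj.coords[i, moi.c2], traj.coords[i, moi.c7], plane_spec)
            for i in range(traj.n_frames)])
        h = vertical_distribution(tilts, 0.72, range_=(-8.0, 23.0))
        fit = fit_peaks(h, 2, centers_guess=[0.0, 15.0])
        assert fit.centers[0] == pytest.approx(0.0, abs=1.0)
        assert fit.centers[1] == pytest.approx(15.0, abs=1.0)

    def test_three_peak_amine_mixture_recovered(self, plane_spec, dopamine):
        tpl, species, moi = dopamine
        mix = GaussianMixture1D((0.30, 0.35, 0.35), (3.19, 4.21, 5.71),
                                (0.18, 0.22, 0.25))
        model = AdsorbateModel(tpl, species, moi, d_dist=mix, corr_time=0.0)
        traj = simulate_adsorbate(model, _static_path(60000), plane_spec, seed=4)
        amine = traj.coords[:, moi.amine, :]
        m = moi.masses[moi.amine]
        d = np.einsum("fij,i->fj", amine, m)[:, 2] / m.sum()
        h = vertical_distribution(d, 0.05, range_=(2.0, 7.5))
        fit = fit_peaks(h, 3)
        assert np.allclose(fit.centers, [3.19, 4.21, 5.71], atol=0.05)

    def test_dopamine_molar_mass(self, dopamine):
        assert round(molar_mass({"C": 8, "H": 11, "N": 1, "O": 2}), 2) == 153.18


class TestSolvent:
    def test_zero_density_zero_hydration(self, plane_spec, dopamine):
        tpl, _, moi = dopamine
        with pytest.raises(ValueError):
            simulate_solvent(SolventModel(layer_amplitudes=(0.0, 0.0),
                                          bulk_density=0.0), plane_spec, 2)

    def test_seed_determinism(self, plane_spec):
        w1 = simulate_solvent(SolventModel(), plane_spec, 3, seed=7)
        w2 = simulate_solvent(SolventModel(), plane_spec, 3, seed=7)
        assert np.array_equal(w1.coords, w2.coords)

    def test_hydration_count_in_first_shell_band(self, plane_spec, dopamine):
        """Default solvent puts ~26-33 waters in the 5 A shell of the adsorbate."""
        tpl, species, moi = dopamine
        model = AdsorbateModel(tpl, species, moi,
                               d_dist=GaussianMixture1D.delta(3.5))
        ads = simulate_adsorbate(model, _static_path(1), plane_spec, seed=8)
        frame = make_whole(ads.coords[0], plane_spec.box, plane_spec.periodic)
        water = simulate_solvent(SolventModel(), plane_spec, 40, seed=9)
        counts = [hydration_count(frame, water.coords[i], plane_spec, 5.0,
                                  box=plane_spec.box, periodic=plane_spec.periodic)
                  for i in range(water.n_frames)]
        assert 26 <= np.mean(counts) <= 33


class TestWallSwitching:
    def test_zero_rate_single_wall(self):
        labels, traj, spec = simulate_wall_switching(0.0, 5.0, 1.0, seed=10)
        assert np.all(labels.label == 0)

    def test_poisson_event_count(self):
        rate, T = 2.0, 100.0
        labels, _, _ = simulate_wall_switching(rate, T, 1.0, seed=11)
        n_events = int(np.count_nonzero(np.diff(labels.label)))
        assert abs(n_events - rate * T) <= 3 * np.sqrt(rate * T)

    def test_determinism(self):
        l1, t1, _ = simulate_wall_switching(1.9, 5.0, 1.0, seed=12)
        l2, t2, _ = simulate_wall_switching(1.9, 5.0, 1.0, seed=12)
        assert np.array_equal(l1.label, l2.label)
        assert np.array_equal(t1.coords, t2.coords)


class TestRoundtripThroughIO:
    def test_descriptors_survive_dump_roundtrip(self, cnt_ext_spec):
        p = BrownianParams(D_par=1.4, D_perp=3.5, dt=0.1, n_steps=2000,
                           seed=13, surface=cnt_ext_spec)
        _, traj = simulate_surface_brownian(p)
        buf = io.StringIO()
        write_lammps_dump(traj, buf)
        buf.seek(0)
        back = read_lammps_dump(buf, timestep=0.1)
        path_a = decompose_path(traj.coords[:, 0, :], cnt_ext_spec, times=traj.times)
        path_b = decompose_path(back.coords[:, 0, :], cnt_ext_spec, times=back.times)
        assert np.allclose(path_a.s_perp, path_b.s_perp, atol=1e-4)
        assert np.allclose(path_a.d, path_b.d, atol=1e-5)
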