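"""Adsorbate structural descriptors: COMs, angles, histograms, hydration."""

import numpy as np
import pytest

from cntdiff.descriptors import (DEFAULT_HYDRATION_CUTOFF, Histogram1D,
                                 MoietyMap, axial_orientation, fit_peaks,
                                 hydration_count, lateral_distribution,
                                 moiety_com, tilt_angle, vertical_distribution,
                                 water_density_profile)
from cntdiff.synthetic import GaussianMixture1D, SolventModel, simulate_solvent


class TestMoietyCom:
    def test_single_atom_moiety(self, dopamine):
        tpl, _, moi = dopamine
        single = MoietyMap(ring=moi.ring, diol_or_quinone=moi.diol_or_quinone,
                           amine=[9], c2=moi.c2, c7=moi.c7, masses=moi.masses)
        assert np.allclose(moiety_com(tpl, single, "amine"), tpl[9])

    def test_equal_mass_midpoint(self):
        moi = MoietyMap(ring=[0, 1, 2, 3, 4, 5], diol_or_quinone=[6, 7],
                        amine=[8], c2=0, c7=8, masses=np.ones(9))
        frame = np.zeros((9, 3))
        frame[6] = [0, 0, 0]
        frame[7] = [2, 0, 0]
        assert np.allclose(moiety_com(frame, moi, "diol_or_quinone"), [1, 0, 0])

    def test_split_across_boundary(self):
        # moiety wrapped around a periodic edge must be made whole first
        moi = MoietyMap(ring=[0, 1, 2, 3, 4, 5], diol_or_quinone=[6, 7],
                        amine=[8], c2=0, c7=8, masses=np.ones(9))
        frame = np.zeros((9, 3))
        frame[6] = [0.5, 0, 0]
        frame[7] = [99.5, 0, 0]   # image of -0.5
        com = moiety_com(frame, moi, "diol_or_quinone", box=[100, 100, 100])
        assert com[0] % 100 == pytest.approx(0.0, abs=1e-9)

    def test_missing_index_rejected(self, dopamine):
        tpl, _, moi = dopamine
        with pytest.raises(ValueError):
            moiety_com(tpl[:5], moi, "ring")


class TestAngles:
    def test_tilt_parallel_vector_is_zero(self, plane_spec):
        assert tilt_angle([0, 0, 3.4], [3, 0, 3.4], plane_spec) == pytest.approx(0.0)

    def test_tilt_normal_vector_is_90(self, plane_spec):
        assert tilt_angle([0, 0, 3.0], [0, 0, 6.0], plane_spec) == pytest.approx(90.0)

    def test_tilt_sign_toward_surface(self, plane_spec):
        up = tilt_angle([0, 0, 3.0], [2, 0, 4.0], plane_spec)
        down = tilt_angle([0, 0, 4.0], [2, 0, 3.0], plane_spec)
        assert up > 0 > down and up == pytest.approx(-down)

    def test_tilt_on_cylinder_uses_local_tangent(self, cnt_ext_spec):
        # a vector along z at any azimuth is tangent: tilt 0
        r = cnt_ext_spec.radius + 3.0
        for ang in (0.0, 1.0, 2.5):
            c2 = [30 + r * np.cos(ang), 30 + r * np.sin(ang), 10.0]
            c7 = [30 + r * np.cos(ang), 30 + r * np.sin(ang), 14.0]
            assert tilt_angle(c2, c7, cnt_ext_spec) == pytest.approx(0.0, abs=1e-9)

    def test_orientation_wrapping(self):
        v = np.array([np.cos(np.radians(135)), 0, np.sin(np.radians(135))])
        # raw 135 deg wraps to 45 deg
        assert axial_orientation([0, 0, 0], v, axis=(0, 0, 1)) == pytest.approx(45.0)
        assert axial_orientation([0, 0, 0], [0, 0, 2], axis=(0, 0, 1)) == pytest.approx(0.0)

    def test_orientation_range_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            v = rng.normal(size=3)
            th = axial_orientation([0, 0, 0], v)
            assert 0.0 <= th <= 90.0

    def test_degenerate_vector_rejected(self, plane_spec):
        with pytest.raises(ValueError):
            tilt_angle([1, 1, 1], [1, 1, 1], plane_spec)
        with pytest.raises(ValueError):
            axial_orientation([1, 1, 1], [1, 1, 1])


class TestHistograms:
    def test_vertical_distribution_normalized(self):
        rng = np.random.default_rng(1)
        h = vertical_distribution(rng.normal(5, 0.5, 5000), 0.05)
        assert np.isclose((h.density * np.diff(h.edges)).sum(), 1.0)

    def test_lateral_distribution_normalized_and_flat_for_uniform(self):
        rng = np.random.default_rng(2)
        cell = (2.456, 4.254)
        s_par = rng.uniform(0, 200, 200000)
        s_perp = rng.uniform(0, 200, 200000)
        h = lateral_distribution(s_par, s_perp, cell, bin_width=0.5, n_cells=4)
        assert h.density.sum() == pytest.approx(1.0)
        mean = h.density.mean()
        assert h.density.max() / max(h.density.min(), 1e-12) < 2.0
        assert np.allclose(h.density, mean, rtol=0.5)

    def test_lateral_bias_survives_folding(self):
        # samples concentrated at one in-cell position peak there after folding
        cell = (2.456, 4.254)
        rng = np.random.default_rng(3)
        cells = rng.integers(0, 20, size=(5000, 2))
        pos = cells * cell + np.array([1.1, 2.3]) + rng.normal(0, 0.05, (5000, 2))
        h = lateral_distribution(pos[:, 0], pos[:, 1], cell, bin_width=0.1, n_cells=1)
        i, j = np.unravel_index(np.argmax(h.density), h.density.shape)
        assert h.x_edges[i] == pytest.approx(1.1, abs=0.15)
        assert h.y_edges[j] == pytest.approx(2.3, abs=0.15)

    def test_oversized_bin_rejected(self):
        with pytest.raises(ValueError):
            lateral_distribution([1.0], [1.0], (2.456, 4.254), bin_width=50.0)


class TestPeakFit:
    def test_single_narrow_peak(self):
        rng = np.random.default_rng(4)
        h = vertical_distribution(rng.normal(5.9, 0.15, 20000), 0.05)
        fit = fit_peaks(h, 1)
        assert fit.centers[0] == pytest.approx(5.9, abs=0.05)

    def test_three_component_mixture_recovery(self):
        """Amine-like 3-Gaussian mixture: centers back within 0.05 A."""
        rng = np.random.default_rng(5)
        mix = GaussianMixture1D((0.30, 0.35, 0.35), (3.19, 4.21, 5.71),
                                (0.18, 0.22, 0.25))
        samples = mix.sample(rng, 120000)
        h = vertical_distribution(samples, 0.05, range_=(2.0, 7.5))
        fit = fit_peaks(h, 3)
        assert np.allclose(fit.centers, [3.19, 4.21, 5.71], atol=0.05)
        assert np.allclose(fit.weights, [0.30, 0.35, 0.35], atol=0.05)
        assert fit.weights.sum() <= 1.0 + 1e-6

    def test_centers_sorted(self):
        rng = np.random.default_rng(6)
        mix = GaussianMixture1D((0.5, 0.5), (6.0, 3.0), (0.2, 0.2))
        h = vertical_distribution(mix.sample(rng, 50000), 0.05)
        fit = fit_peaks(h, 2, centers_guess=[6.0, 3.0])
        assert np.all(np.diff(fit.centers) > 0)


class TestHydration:
    def test_no_waters(self, plane_spec):
        assert hydration_count(np.zeros((3, 3)) + [10, 10, 3.4],
                               np.empty((0, 3)), plane_spec) == 0

    def test_counts_within_cutoff(self, plane_spec):
        ads = np.array([[50.0, 50.0, 3.4]])
        waters = np.array([[54.0, 50.0, 3.4], [50.0, 54.0, 3.4],
                           [50.0, 50.0, 7.4], [60.0, 50.0, 3.4]])
        assert hydration_count(ads, waters, plane_spec, cutoff=5.0) == 3

    def test_opposite_side_excluded(self, plane_spec):
        ads = np.array([[50.0, 50.0, 3.4]])
        below = np.array([[50.0, 50.0, -1.0], [51.0, 50.0, -2.0]])
        assert hydration_count(ads, below, plane_spec, cutoff=5.0) == 0

    def test_opposite_side_excluded_on_cylinder(self, cnt_ext_spec):
        r = cnt_ext_spec.radius
        ads = np.array([[30 + r + 3.4, 30.0, 10.0]])
        inside = np.array([[30 + r - 2.0, 30.0, 10.0]])  # within 5.4 A but interior
        assert hydration_count(ads, inside, cnt_ext_spec, cutoff=6.0) == 0

    def test_monotone_in_cutoff(self, plane_spec):
        rng = np.random.default_rng(8)
        ads = np.array([[50.0, 50.0, 3.4]])
        waters = np.column_stack([rng.uniform(40, 60, 200),
                                  rng.uniform(40, 60, 200),
                                  rng.uniform(0.1, 12, 200)])
        counts = [hydration_count(ads, waters, plane_spec, cutoff=c)
                  for c in (2.0, 4.0, 6.0, 8.0)]
        assert counts == sorted(counts)


class TestWaterProfile:
    def test_layer_peaks_recovered(self, plane_spec):
        water = simulate_solvent(SolventModel(), plane_spec, n_frames=20, seed=9)
        prof = water_density_profile(water.coords, plane_spec, 0.1, d_max=7.4)
        fit = fit_peaks(prof, 2, centers_guess=[3.3, 6.2])
        assert np.allclose(fit.centers, [3.3, 6.2], atol=0.1)

    def test_first_minimum_near_hydration_cutoff(self, plane_spec):
        # the trough between the two layers motivates the 5 A shell cutoff
        water = simulate_solvent(SolventModel(), plane_spec, n_frames=20, seed=10)
        prof = water_density_profile(water.coords, plane_spec, 0.1, d_max=7.4)
        c = prof.centers
        sel = (c > 3.3) & (c < 6.2)
        trough = c[sel][np.argmin(prof.density[sel])]
        assert trough == pytest.approx(DEFAULT_HYDRATION_CUTOFF, abs=0.8)

    def test_uniform_fill_flat_after_shell_correction(self, cnt_ext_spec):
        model = SolventModel(layer_centers=(1.0,), layer_widths=(0.1,),
                             layer_amplitudes=(0.0,), bulk_density=0.03,
                             bulk_start=0.0)
        water = simulate_solvent(model, cnt_ext_spec, n_frames=30, seed=11)
        prof = water_density_profile(water.coords, cnt_ext_spec, 0.5, d_max=10.0)
        dens = prof.density[prof.density > 0]
        assert dens.max() / dens.min() < 1.35
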