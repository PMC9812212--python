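import numpy as np
import pytest

from xtalsim.crystal_model import (
    Ensemble,
    LabeledAtomSet,
    SupercellSpec,
    UnitCell,
    build_supercell,
)
from xtalsim.geometry import RotationSeries, detector_q_grid, rotate_coordinates
from xtalsim.fixtures import make_point_lattice
from xtalsim.photograph import (
    amplitude_at_pixel,
    fft_photograph,
    intensity_at_q,
    simulate_frame,
    simulate_series,
    wavelet_phase,
)
from xtalsim.scattering import form_factor

from conftest import brute_force_amplitude


class TestWaveletPhase:
    def test_reference_path_has_zero_phase(self):
        k = np.array([0.0, 0.0, 1.0])
        kp = np.array([0.5, 0.0, 0.75])
        assert wavelet_phase(np.zeros(3), k, kp) == 0.0

    def test_half_integer_projection_gives_pi(self):
        k = np.array([0.0, 0.0, 1.0])
        kp = np.array([0.0, 0.0, 0.5])  # q = (0,0,0.5)
        r = np.array([0.0, 0.0, 1.0])
        assert wavelet_phase(r, k, kp) == pytest.approx(np.pi)

    def test_integer_lattice_shift_leaves_wavelet_unchanged(self, rng):
        k = np.array([0.0, 0.0, 1.0 / 1.54])
        kp = k + np.array([0.21, -0.13, 0.05])
        q = k - kp
        r = rng.normal(size=3)
        # translation with t.q integer changes the phase by a 2pi multiple
        t = q * 2.0 / (q @ q)  # t.q = 2
        d1 = wavelet_phase(r, k, kp)
        d2 = wavelet_phase(r + t, k, kp)
        assert np.exp(1j * d1) == pytest.approx(np.exp(1j * d2), abs=1e-10)


class TestAmplitude:
    def test_single_atom_at_origin_is_pure_form_factor(self, small_geom, rng):
        atom = LabeledAtomSet.from_arrays(element=["N"], xyz=[[0.0, 0.0, 0.0]])
        p = np.stack([rng.uniform(0, 39, 20), rng.uniform(0, 31, 20)], axis=1)
        a = amplitude_at_pixel(atom, p, small_geom)
        from xtalsim.geometry import momentum_transfer

        s = momentum_transfer(p, small_geom)
        np.testing.assert_allclose(a.real, form_factor("N", s), rtol=1e-12)
        np.testing.assert_allclose(a.imag, 0.0, atol=1e-12)

    def test_two_source_interference_closed_form(self, small_geom, rng):
        """|A|^2 = 2 f^2 (1 + cos(2 pi dr.q)) for two identical atoms."""
        dr = np.array([1.7, -0.9, 2.4])
        atoms = LabeledAtomSet.from_arrays(element=["O", "O"],
                                           xyz=[[0.0, 0.0, 0.0], dr])
        q, s = detector_q_grid(small_geom)
        a = amplitude_at_pixel(
            atoms,
            np.stack(np.meshgrid(np.arange(40.0), np.arange(32.0)),
                     axis=-1).reshape(-1, 2),
            small_geom).reshape(32, 40)
        f = form_factor("O", s)
        expected = 2.0 * f ** 2 * (1.0 + np.cos(2 * np.pi * (q @ dr)))
        np.testing.assert_allclose(np.abs(a) ** 2, expected, rtol=1e-9,
                                   atol=1e-9 * expected.max())

    def test_matches_brute_force_oracle(self, small_geom, rng, table):
        n = 50
        xyz = rng.uniform(-8, 8, size=(n, 3))
        els = rng.choice(["C", "N", "O", "S", "H"], size=n)
        occ = rng.uniform(0.3, 1.0, size=n)
        b = rng.uniform(0.0, 15.0, size=n)
        atoms = LabeledAtomSet.from_arrays(element=els, xyz=xyz,
                                           occupancy=occ, b_factor=b)
        p = np.stack([rng.uniform(0, 39, 100), rng.uniform(0, 31, 100)],
                     axis=1)
        from xtalsim.geometry import momentum_transfer, pixel_to_kprime

        q = small_geom.k_in - pixel_to_kprime(p, small_geom)
        s = momentum_transfer(p, small_geom)
        for honor_b in (False, True):
            a = amplitude_at_pixel(atoms, p, small_geom, honor_b=honor_b)
            ref = brute_force_amplitude(xyz, els, occ, q, s, table,
                                        b=b if honor_b else None)
            np.testing.assert_allclose(a, ref, rtol=1e-10)


class TestFrameAccumulation:
    def test_duplicated_ensemble_doubles_intensity(self, small_geom, rng):
        xyz = rng.uniform(-4, 4, size=(10, 3))
        base = LabeledAtomSet.from_arrays(element=["C"] * 10, xyz=xyz)
        series = RotationSeries(frame_width=1.0, substep=0.5, total_range=1.0)
        single = Ensemble(base, np.stack([xyz, xyz + 0.1]))
        double = Ensemble(base, np.stack([xyz, xyz + 0.1, xyz, xyz + 0.1]))
        p1 = simulate_frame(single, small_geom, series, None, 0)
        p2 = simulate_frame(double, small_geom, series, None, 0)
        np.testing.assert_allclose(p2.data, 2.0 * p1.data, rtol=1e-12)

    def test_degenerate_plan_equals_single_rotated_snapshot(self, small_geom,
                                                            rng):
        xyz = rng.uniform(-4, 4, size=(8, 3))
        atoms = LabeledAtomSet.from_arrays(element=["O"] * 8, xyz=xyz)
        series = RotationSeries(frame_width=2.0, substep=2.0, total_range=2.0)
        photo = simulate_frame(atoms, small_geom, series, None, 0)
        rot = rotate_coordinates(atoms, (1, 0, 0), 1.0)  # substep midpoint
        grid = np.stack(np.meshgrid(np.arange(40.0), np.arange(32.0)),
                        axis=-1).reshape(-1, 2)
        a = amplitude_at_pixel(rot, grid, small_geom).reshape(32, 40)
        np.testing.assert_allclose(photo.data, np.abs(a) ** 2, rtol=1e-10)

    def test_finite_lattice_interference_function(self, small_geom):
        """An 8x1x1 point row reproduces sin^2(8 pi u)/sin^2(pi u)."""
        n, a = 8, 3.0
        row = make_point_lattice(n, 1, 1, a)
        q, s = detector_q_grid(small_geom)
        pixels = np.stack([np.arange(40.0), np.full(40, 16.0)], axis=1)
        amp = amplitude_at_pixel(row, pixels, small_geom)
        u = a * q[16, :, 0]  # fast-axis row through the beam center
        f = form_factor("C", s[16, :])
        sin_u = np.sin(np.pi * u)
        ok = np.abs(sin_u) > 0.05  # stay clear of principal maxima
        expected = f[ok] ** 2 * np.sin(n * np.pi * u[ok]) ** 2 / sin_u[ok] ** 2
        np.testing.assert_allclose(np.abs(amp[ok]) ** 2, expected, rtol=1e-6)

    def test_series_count_and_purity(self, small_geom, rng):
        xyz = rng.uniform(-3, 3, size=(6, 3))
        atoms = LabeledAtomSet.from_arrays(element=["C"] * 6, xyz=xyz)
        series = RotationSeries(frame_width=1.0, substep=0.5, total_range=4.0)
        photos = simulate_series(atoms, small_geom, series)
        assert len(photos) == 4
        # per-frame results independent of processing order
        again = simulate_frame(atoms, small_geom, series, None, 2)
        np.testing.assert_array_equal(photos[2].data, again.data)

    def test_empty_ensemble_rejected(self, small_geom):
        series = RotationSeries(frame_width=1.0, substep=1.0, total_range=1.0)
        with pytest.raises((ValueError, TypeError)):
            simulate_frame(None, small_geom, series, None, 0)


class TestIntensityAtQ:
    def test_friedel_symmetry(self, rng):
        xyz = rng.uniform(-6, 6, size=(30, 3))
        els = rng.choice(["C", "N", "O"], size=30)
        ens = Ensemble(LabeledAtomSet.from_arrays(element=els, xyz=xyz),
                       np.stack([xyz, xyz + rng.normal(0, 0.2, xyz.shape)]))
        qs = rng.uniform(-0.5, 0.5, size=(25, 3))
        ip = intensity_at_q(ens, qs)
        im = intensity_at_q(ens, -qs)
        np.testing.assert_allclose(ip, im, rtol=1e-10)

    def test_forward_scattering_sums_all_electrons(self, rng, table):
        xyz = rng.uniform(-4, 4, size=(12, 3))
        els = rng.choice(["C", "O"], size=12)
        atoms = LabeledAtomSet.from_arrays(element=els, xyz=xyz)
        total_f0 = sum(table[e].evaluate(0.0) for e in els)
        assert intensity_at_q(atoms, np.zeros(3)) == \
            pytest.approx(total_f0 ** 2, rel=1e-12)

    def test_lattice_point_factorizes_into_cells(self, rng, table):
        """I(G) = N_cells^2 |F_cell|^2 on a 3x3x3 block of identical cells."""
        cell = UnitCell(7.0, 7.0, 7.0)
        xyz = rng.uniform(0, 6, size=(4, 3))
        els = np.array(["C", "N", "O", "C"], dtype=object)
        contents = LabeledAtomSet.from_arrays(element=els, xyz=xyz)
        block = build_supercell(contents, SupercellSpec(3, 3, 3, cell=cell))
        g = np.array([2, -1, 1]) / 7.0  # reciprocal-lattice point
        s = np.linalg.norm(g) / 2.0
        f_cell = sum(table[e].evaluate(s) * np.exp(2j * np.pi * (r @ g))
                     for e, r in zip(els, xyz))
        expected = 27 ** 2 * abs(f_cell) ** 2
        assert intensity_at_q(block, g) == pytest.approx(expected, rel=1e-9)


class TestFFTEngine:
    def test_single_atom_flat_phase(self, small_geom):
        atom = LabeledAtomSet.from_arrays(element=["C"],
                                          xyz=[[0.0, 0.0, 0.0]])
        series = RotationSeries(frame_width=1.0, substep=1.0, total_range=1.0)
        photo = fft_photograph(atom, small_geom, series, 0, grid_spacing=0.5)
        _, s = detector_q_grid(small_geom)
        expected = form_factor("C", s) ** 2
        sel = photo.mask
        np.testing.assert_allclose(photo.data[sel], expected[sel], rtol=2e-2)

    def test_matches_direct_engine_on_toy_crystal(self, small_geom,
                                                  toy_crystal):
        series = RotationSeries(frame_width=1.0, substep=0.5, total_range=1.0)
        direct = simulate_frame(toy_crystal, small_geom, series, None, 0)
        gridded = fft_photograph(toy_crystal, small_geom, series, 0,
                                 grid_spacing=0.5)
        sel = gridded.mask
        num = np.sqrt(np.mean((gridded.data[sel] - direct.data[sel]) ** 2))
        den = np.sqrt(np.mean(direct.data[sel] ** 2))
        assert num / den < 0.02

    def test_refining_grid_reduces_deviation(self, rng):
        # wide-angle detector (q up to ~0.57 1/A) so that the coarse grid's
        # discretization error, not roundoff, dominates the comparison
        from xtalsim.geometry import DetectorGeometry

        geom = DetectorGeometry(1.54, 10.0, 0.5, 40, 32, (20.0, 16.0))
        xyz = rng.uniform(-6, 6, size=(60, 3))
        atoms = LabeledAtomSet.from_arrays(element=["C"] * 60, xyz=xyz)
        series = RotationSeries(frame_width=1.0, substep=1.0, total_range=1.0)
        direct = simulate_frame(atoms, geom, series, None, 0)

        _, s = detector_q_grid(geom)

        def shell_dev(spacing):
            # per-pixel relative error in the outer resolution shell, where
            # the gridded engine's discretization error concentrates
            photo = fft_photograph(atoms, geom, series, 0,
                                   grid_spacing=spacing, d_min=1.667)
            sel = photo.mask & (s >= 0.25)
            rel = (photo.data[sel] - direct.data[sel]) / direct.data[sel]
            return np.sqrt(np.mean(rel ** 2))

        assert shell_dev(0.27) < shell_dev(0.54)

    def test_coarse_grid_rejected_with_implied_resolution(self, small_geom):
        atom = LabeledAtomSet.from_arrays(element=["C"], xyz=[[0.0, 0.0, 0.0]])
        series = RotationSeries(frame_width=1.0, substep=1.0, total_range=1.0)
        with pytest.raises(ValueError, match="d >= 2.4"):
            fft_photograph(atom, small_geom, series, 0, grid_spacing=0.8,
                           d_min=1.5)

    def test_amplitude_averaging_suppresses_diffuse(self, small_geom, rng):
        """Averaging densities before squaring removes the diffuse floor."""
        base = make_point_lattice(4, 4, 4, 3.0)
        disp = rng.normal(0, 0.25, size=(8,) + base.xyz.shape)
        ens = Ensemble(base, base.xyz[None] + disp)
        series = RotationSeries(frame_width=1.0, substep=1.0, total_range=1.0)
        by_int = fft_photograph(ens, small_geom, series, 0, 0.5)
        by_amp = fft_photograph(ens, small_geom, series, 0, 0.5,
                                snapshot_average="amplitude")
        sel = by_int.mask
        # per-snapshot intensity accumulation keeps strictly more signal
        assert by_amp.data[sel].sum() < by_int.data[sel].sum() / 8.0 * 1.05
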