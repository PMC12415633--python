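import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

import edpat as ep
from edpat.simulate import _disc_offsets


def _brute_force_excited(basis, beam, wavelength, g_max, s_max):
    """Independent oracle: quadratic root for the along-beam sphere distance.

    Solves |g + t·b̂ + (1/λ)·b̂| = 1/λ for t per candidate and keeps the
    root of smaller magnitude — a numerical path sharing no code with the
    production excitation formula.
    """
    R = 1.0 / wavelength
    out = []
    for hkl in ep.enumerate_candidate_hkl(basis, g_max):
        g = hkl @ basis.matrix
        # t² + 2t(b·(g + R b)) + |g + R b|² − R² = 0
        c_vec = g + R * beam
        bcoef = 2.0 * (beam @ c_vec)
        ccoef = c_vec @ c_vec - R * R
        roots = np.roots([1.0, bcoef, ccoef])
        roots = roots[np.isreal(roots)].real
        if len(roots) == 0:
            continue
        t = roots[np.argmin(np.abs(roots))]
        if abs(t) <= s_max:
            out.append(tuple(int(x) for x in hkl))
    return sorted(out)


class TestElectronWavelength:
    def test_200kv_matches_printed_value(self):
        assert round(ep.electron_wavelength(200), 4) == 0.0251

    def test_closed_form_at_300kv(self):
        from scipy.constants import c, e, h, m_e
        U = 300e3
        expect = h / math.sqrt(2 * m_e * e * U * (1 + e * U / (2 * m_e * c**2)))
        assert ep.electron_wavelength(300) == pytest.approx(expect * 1e10,
                                                            rel=1e-12)

    def test_monotone_decreasing_in_voltage(self):
        lams = [ep.electron_wavelength(kv) for kv in (100, 200, 300)]
        assert lams[0] > lams[1] > lams[2]

    def test_nonpositive_voltage(self):
        with pytest.raises(ValueError):
            ep.electron_wavelength(0)


class TestFibonacciSphere:
    def test_unit_norm(self):
        dirs = np.array([o.beam_direction for o in ep.fibonacci_sphere(1000)])
        assert len(dirs) == 1000
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0,
                                   atol=1e-12)

    def test_two_points_symmetric(self):
        z = [o.beam_direction[2] for o in ep.fibonacci_sphere(2)]
        assert z[0] == pytest.approx(-z[1])

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ep.fibonacci_sphere(0)

    def test_better_spread_than_random(self):
        # minimum pairwise separation beats uniform-random directions in
        # ≥ 95 of 100 trials (golden-angle spiral is near-optimal packing)
        def min_sep(dirs):
            d, _ = cKDTree(dirs).query(dirs, k=2)
            return d[:, 1].min()

        fib = min_sep(np.array([o.beam_direction
                                for o in ep.fibonacci_sphere(1000)]))
        rng = np.random.default_rng(0)
        wins = 0
        for _ in range(100):
            v = rng.normal(size=(1000, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            wins += fib > min_sep(v)
        assert wins >= 95


class TestEnumerateCandidates:
    def test_cubic_exhaustive(self):
        basis = ep.reciprocal_basis(ep.UnitCell(10, 10, 10, 90, 90, 90))
        got = {tuple(t) for t in ep.enumerate_candidate_hkl(basis, 1.0)}
        expect = {(h, k, l)
                  for h in range(-10, 11) for k in range(-10, 11)
                  for l in range(-10, 11)
                  if (h, k, l) != (0, 0, 0) and h*h + k*k + l*l <= 100}
        assert got == expect

    def test_below_first_shell_empty(self):
        basis = ep.reciprocal_basis(ep.UnitCell(10, 10, 10, 90, 90, 90))
        assert len(ep.enumerate_candidate_hkl(basis, 0.05)) == 0

    def test_origin_excluded_random_cells(self, random_cells):
        for cell in random_cells:
            hkl = ep.enumerate_candidate_hkl(ep.reciprocal_basis(cell), 1.0,
                                             cell=cell)
            assert not (np.all(hkl == 0, axis=1)).any()


class TestExcitedReflections:
    def test_zone_axis_sag_cutoff(self):
        # beam along c of a cubic cell: ZOLZ excitation bounded by the
        # sphere sag, |g| ≤ sqrt(2·s_max/λ)
        cell = ep.UnitCell(10, 10, 10, 90, 90, 90)
        basis = ep.reciprocal_basis(cell)
        orient = ep.Orientation(beam_direction=np.array([0.0, 0.0, 1.0]))
        refl = ep.excited_reflections(basis, orient, 0.0251, 1.0, 0.01)
        cutoff = math.sqrt(2 * 0.01 / 0.0251)
        gnorms = [np.linalg.norm(r.g) for r in refl]
        assert all(ln == 0 for (_, _, ln) in (r.hkl for r in refl))
        assert max(gnorms) <= cutoff + 1e-9
        assert max(gnorms) >= cutoff - 0.1  # within one reciprocal spacing

    def test_filter_contract(self, random_cells):
        orient = ep.Orientation(beam_direction=np.array([0.3, -0.5, 0.8]))
        for cell in random_cells:
            basis = ep.reciprocal_basis(cell)
            for r in ep.excited_reflections(basis, orient, 0.0251, 1.0, 0.01):
                assert abs(r.s) <= 0.01
                assert np.linalg.norm(r.g) <= 1.0 + 1e-12
                np.testing.assert_allclose(
                    r.g, np.asarray(r.hkl) @ basis.matrix, atol=1e-12)

    def test_matches_bruteforce_oracle(self, random_cells):
        rng = np.random.default_rng(42)
        for cell in random_cells:
            basis = ep.reciprocal_basis(cell)
            for _ in range(4):
                beam = rng.normal(size=3)
                beam /= np.linalg.norm(beam)
                orient = ep.Orientation(beam_direction=beam)
                got = sorted(r.hkl for r in ep.excited_reflections(
                    basis, orient, 0.0251, 1.0, 0.01))
                expect = _brute_force_excited(basis, beam, 0.0251, 1.0, 0.01)
                assert got == expect

    def test_roll_never_changes_the_hkl_set(self):
        cell = ep.random_unit_cell(1000.0, seed=5)
        basis = ep.reciprocal_basis(cell)
        beam = np.array([0.2, 0.3, 0.93])
        sets = []
        for roll in (0.0, 117.3, 301.9):
            orient = ep.Orientation(beam_direction=beam, inplane_angle=roll)
            sets.append(sorted(r.hkl for r in ep.excited_reflections(
                basis, orient, 0.0251, 1.0, 0.01)))
        assert sets[0] == sets[1] == sets[2]

    def test_extinct_reflections_removed(self):
        cell = ep.UnitCell(4, 10, 12, 90, 105, 90, lattice_system="monoclinic")
        basis = ep.reciprocal_basis(cell)
        orient = ep.Orientation(beam_direction=np.array([1.0, 0.0, 0.0]))
        plain = {r.hkl for r in ep.excited_reflections(
            basis, orient, 0.0251, 1.0, 0.01)}
        absent = {r.hkl for r in ep.excited_reflections(
            basis, orient, 0.0251, 1.0, 0.01, extinctions=[ep.SCREW_21_B])}
        assert any(h == 0 and l == 0 and k % 2 for (h, k, l) in plain)
        assert not any(h == 0 and l == 0 and k % 2 for (h, k, l) in absent)


class TestProjection:
    def test_axis_aligned(self):
        orient = ep.Orientation(beam_direction=np.array([0.0, 0.0, 1.0]))
        xy = ep.project_to_detector(np.array([0.3, 0.4, 0.7]), orient)
        np.testing.assert_allclose(xy, [0.3, 0.4], atol=1e-12)

    def test_norm_invariant_under_roll(self):
        g = np.array([0.2, -0.1, 0.4])
        beam = np.array([0.0, 0.6, 0.8])
        norms = [np.linalg.norm(ep.project_to_detector(
            g, ep.Orientation(beam_direction=beam, inplane_angle=a)))
            for a in (0, 45, 123.4, 270)]
        np.testing.assert_allclose(norms, norms[0], atol=1e-12)

    def test_parallel_projects_to_origin(self):
        beam = np.array([0.0, 0.6, 0.8])
        orient = ep.Orientation(beam_direction=beam)
        np.testing.assert_allclose(
            ep.project_to_detector(0.5 * beam, orient), [0.0, 0.0],
            atol=1e-12)


class TestRendering:
    def test_empty_pattern_has_only_central_spot(self):
        spec = ep.RenderSpec(image_size=128, spot_radius=2,
                             central_spot_radius=5)
        img = ep.render_pattern([], spec)
        assert img.shape == (128, 128)
        assert set(np.unique(img)) <= {0, 255}
        assert (img == 255).sum() == len(_disc_offsets(5))

    def test_linear_mapping_of_spot_position(self):
        spec = ep.RenderSpec(image_size=256, gmax_to_edge=1.0, spot_radius=2,
                             central_spot_radius=4)
        refl = ep.Reflection(hkl=(1, 0, 0), g=np.zeros(3), s=0.0,
                             detector_xy=np.array([0.5, 0.0]))
        img = ep.render_pattern([refl], spec)
        centre = (256 - 1) / 2.0
        expect_col = round(centre + 0.5 * 128)
        ys, xs = np.nonzero(img)
        spot = (xs > centre + 20)
        assert np.mean(xs[spot]) == pytest.approx(expect_col, abs=0.5)
        assert np.mean(ys[spot]) == pytest.approx(centre, abs=0.5)

    def test_friedel_pair_gives_180deg_symmetry(self):
        # odd size puts the rotation centre exactly on the central pixel
        spec = ep.RenderSpec(image_size=129, spot_radius=2,
                             central_spot_radius=4)
        xy = np.array([0.31, -0.17])
        refl = [ep.Reflection(hkl=(1, 0, 0), g=np.zeros(3), s=0.0,
                              detector_xy=xy),
                ep.Reflection(hkl=(-1, 0, 0), g=np.zeros(3), s=0.0,
                              detector_xy=-xy)]
        img = ep.render_pattern(refl, spec)
        np.testing.assert_array_equal(img, np.rot90(img, 2))

    def test_offcanvas_spots_clipped_silently(self):
        spec = ep.RenderSpec(image_size=64, gmax_to_edge=0.5, spot_radius=2,
                             central_spot_radius=4)
        refl = [ep.Reflection(hkl=(9, 0, 0), g=np.zeros(3), s=0.0,
                              detector_xy=np.array([5.0, 5.0]))]
        img = ep.render_pattern(refl, spec)
        assert (img == 255).sum() == len(_disc_offsets(4))

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            ep.RenderSpec(spot_radius=0)
        with pytest.raises(ValueError):
            ep.RenderSpec(spot_radius=4, central_spot_radius=3)


class TestSimulatePatterns:
    def test_counts_and_determinism(self):
        cell = ep.random_unit_cell(700.0, seed=2, cell_id="x")
        phys = ep.PhysicsConfig()
        a = ep.simulate_patterns(cell, 20, phys,
                                 rng=np.random.default_rng(9))
        b = ep.simulate_patterns(cell, 20, phys,
                                 rng=np.random.default_rng(9))
        assert len(a) == len(b) == 20
        for pa, pb in zip(a, b):
            assert pa.orientation.inplane_angle == pb.orientation.inplane_angle
            assert np.array_equal(pa.hkl_array, pb.hkl_array)

    def test_reflection_density_grows_with_cell_volume(self):
        phys = ep.PhysicsConfig()
        means = []
        for vol in (500.0, 700.0, 1000.0):
            cell = ep.random_unit_cell(vol, seed=31, cell_id=f"v{vol:.0f}")
            pats = ep.simulate_patterns(cell, 300, phys,
                                        rng=np.random.default_rng(0))
            means.append(np.mean([len(p.reflections) for p in pats]))
        assert means[0] < means[1] < means[2]
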