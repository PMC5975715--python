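"""Inlet velocity profile families, secondary flow, and normalization."""

import numpy as np
import pytest

from hemobc import fixtures as fx
from hemobc.inlet_profiles import (
    SHAPES,
    ProfileSpec,
    SecondaryFlowSpec,
    axial_shape,
    calibrate_K,
    discrete_flux,
    export_profile,
    generate_profile,
    read_profile,
    secondary_flow_unit_field,
    systole_window,
    womersley_profile,
)
from hemobc.waveform import FourierWaveform

BLOOD_NU = 0.004 / 1060.0


class TestAxialShape:
    def test_plug_is_unity_everywhere(self, unit_circle_patch):
        vals = axial_shape("plug", 1, unit_circle_patch.node_coords,
                           unit_circle_patch)
        assert np.all(vals == 1.0)

    def test_parabolic_poiseuille_limits(self, unit_circle_patch):
        center = axial_shape("parabolic", 1, np.array([[0.0, 0.0]]),
                             unit_circle_patch)
        boundary = axial_shape("parabolic", 1, np.array([[1.0, 0.0]]),
                               unit_circle_patch)
        assert center[0] == pytest.approx(2.0, abs=1e-12)
        assert boundary[0] == pytest.approx(0.0, abs=5e-3)

    @pytest.mark.parametrize("shape,sigma", [("linear_shear_1", 1),
                                             ("linear_shear_2", -1)])
    def test_linear_shear_wall_values(self, unit_circle_patch, shape, sigma):
        vals = axial_shape(shape, sigma,
                           np.array([[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0]]),
                           unit_circle_patch)
        R = unit_circle_patch.effective_radius
        np.testing.assert_allclose(
            vals, 1.0 + sigma * np.array([-1.0, 0.0, 1.0]) / R, rtol=1e-9
        )

    @pytest.mark.parametrize("shape", ["cubic_shear_1", "cubic_shear_2"])
    def test_cubic_shear_area_mean_is_unity(self, unit_circle_patch, shape):
        """The odd cubic moment vanishes on a disk (quadrature oracle)."""
        sigma = -1 if shape.endswith("2") else 1
        vals = axial_shape(shape, sigma, unit_circle_patch.node_coords,
                           unit_circle_patch)
        mean = (vals @ unit_circle_patch.nodal_areas) / unit_circle_patch.area
        assert mean == pytest.approx(1.0, abs=1e-3)

    def test_unknown_shape_raises(self, unit_circle_patch):
        with pytest.raises(ValueError, match="unknown shape"):
            axial_shape("swirly", 1, unit_circle_patch.node_coords,
                        unit_circle_patch)


class TestGenerateProfile:
    def test_plug_constant_flow_is_uniform(self, circle_patch, constant_fourier):
        field = generate_profile(circle_patch, ProfileSpec("plug"),
                                 constant_fourier, [0.0])
        expected = constant_fourier.mean_flow / circle_patch.area
        np.testing.assert_allclose(field.axial[0], expected, rtol=1e-10)

    def test_parabolic_centerline_is_twice_mean(self, fine_circle_patch,
                                                constant_fourier):
        field = generate_profile(fine_circle_patch, ProfileSpec("parabolic"),
                                 constant_fourier, [0.0])
        u_mean = constant_fourier.mean_flow / fine_circle_patch.area
        center = np.argmin(np.hypot(*fine_circle_patch.node_coords.T))
        assert field.axial[0, center] == pytest.approx(2 * u_mean, rel=5e-3)

    def test_linear_shear_wall_velocities(self, fine_circle_patch,
                                          constant_fourier):
        """Closed form 1 + s/R scaled by the quadrature-exact normalization."""
        field = generate_profile(fine_circle_patch,
                                 ProfileSpec("linear_shear_1"),
                                 constant_fourier, [0.0])
        u_mean = constant_fourier.mean_flow / fine_circle_patch.area
        s = fine_circle_patch.node_coords[:, 0]
        lo, hi = np.argmin(s), np.argmax(s)
        assert field.axial[0, lo] == pytest.approx(0.0, abs=5e-3 * u_mean)
        assert field.axial[0, hi] == pytest.approx(2 * u_mean, rel=5e-3)

    @pytest.mark.parametrize("shape", SHAPES)
    def test_flux_conservation_at_random_times(self, circle_patch,
                                               aortic_fourier, shape):
        """Discrete flux equals Q(t) to 1e-12 relative for every family."""
        rng = np.random.default_rng(11)
        times = rng.uniform(0.0, aortic_fourier.period, 100)
        spec = ProfileSpec(shape, kinematic_viscosity=BLOOD_NU)
        field = generate_profile(circle_patch, spec, aortic_fourier, times)
        Q = aortic_fourier.evaluate(times)
        np.testing.assert_allclose(field.flux(), Q, rtol=1e-12)

    @pytest.mark.parametrize("family", ["linear_shear", "cubic_shear"])
    def test_variant_two_mirrors_variant_one(self, circle_patch,
                                             constant_fourier, family):
        """Reflection equivalence: variant 2 equals variant 1 with e1 negated."""
        f1 = generate_profile(circle_patch, ProfileSpec(f"{family}_1"),
                              constant_fourier, [0.0])
        f2 = generate_profile(circle_patch, ProfileSpec(f"{family}_2"),
                              constant_fourier, [0.0])
        xy = circle_patch.node_coords
        # match each node to its mirror image across the e2 axis
        mirrored = xy.copy()
        mirrored[:, 0] *= -1
        from scipy.spatial import cKDTree

        _, idx = cKDTree(xy).query(mirrored)
        np.testing.assert_allclose(f2.axial[0], f1.axial[0, idx], rtol=1e-9)

    def test_profiles_are_periodic(self, circle_patch, aortic_fourier):
        T = aortic_fourier.period
        t0 = np.array([0.1, 0.4])
        f_a = generate_profile(circle_patch, ProfileSpec("parabolic"),
                               aortic_fourier, t0)
        f_b = generate_profile(circle_patch, ProfileSpec("parabolic"),
                               aortic_fourier, t0 + T)
        np.testing.assert_allclose(f_a.velocities, f_b.velocities,
                                   rtol=1e-9, atol=1e-15)

    def test_negative_flow_flips_axial_sign(self, circle_patch):
        fw = FourierWaveform(-1.0e-4, np.zeros(0), np.zeros(0), 2 * np.pi)
        field = generate_profile(circle_patch, ProfileSpec("parabolic"), fw, [0.0])
        assert np.all(field.axial[0] <= 1e-18)


class TestWomersley:
    def test_mean_only_waveform_reproduces_parabolic(self, circle_patch,
                                                     constant_fourier):
        wom = generate_profile(
            circle_patch,
            ProfileSpec("womersley", kinematic_viscosity=BLOOD_NU),
            constant_fourier, [0.25],
        )
        par = generate_profile(circle_patch, ProfileSpec("parabolic"),
                               constant_fourier, [0.25])
        scale = np.max(np.abs(par.axial))
        np.testing.assert_allclose(wom.axial, par.axial, rtol=0,
                                   atol=1e-10 * scale)

    def test_low_womersley_limit_is_quasi_steady(self, fine_circle_patch):
        """alpha = 0.01: profile tracks instantaneous Poiseuille within 0.1%."""
        R = fine_circle_patch.effective_radius
        alpha = 0.01
        w = alpha**2 * BLOOD_NU / R**2
        fw = FourierWaveform(4e-4, np.array([1e-4]), np.array([0.0]), w)
        t = 0.2 * 2 * np.pi / w
        u = womersley_profile(fine_circle_patch, fw, BLOOD_NU, t)
        rho = fine_circle_patch.boundary_rho()
        quasi = 2 * fw.evaluate(t) / (np.pi * R**2) * (1 - rho**2)
        np.testing.assert_allclose(u, quasi, rtol=0, atol=1e-3 * np.abs(quasi).max())

    def test_high_womersley_wall_phase_lead(self, circle_patch):
        """alpha = 10: near-wall velocity peaks before the centerline."""
        R = circle_patch.effective_radius
        w = 10.0**2 * BLOOD_NU / R**2
        fw = FourierWaveform(0.0, np.array([1e-4]), np.array([0.0]), w)
        T = 2 * np.pi / w
        times = np.linspace(0.0, T, 256, endpoint=False)
        u = womersley_profile(circle_patch, fw, BLOOD_NU, times)
        rho = circle_patch.boundary_rho()
        center = np.argmin(rho)
        near_wall = np.argmin(np.abs(rho - 0.95))
        t_peak_center = times[np.argmax(u[:, center])]
        t_peak_wall = times[np.argmax(u[:, near_wall])]
        assert (t_peak_center - t_peak_wall) % T < 0.5 * T
        assert t_peak_wall != t_peak_center

    def test_flux_matches_prescribed_flow(self, circle_patch):
        R = circle_patch.effective_radius
        w = 10.0**2 * BLOOD_NU / R**2
        fw = FourierWaveform(2e-4, np.array([1e-4]), np.array([5e-5]), w)
        times = np.linspace(0.0, 2 * np.pi / w, 16, endpoint=False)
        field = generate_profile(
            circle_patch, ProfileSpec("womersley", kinematic_viscosity=BLOOD_NU),
            fw, times,
        )
        np.testing.assert_allclose(field.flux(), fw.evaluate(times), rtol=1e-12)

    def test_missing_viscosity_rejected(self):
        with pytest.raises(ValueError, match="viscosity"):
            ProfileSpec("womersley")


class TestSecondaryFlow:
    def test_zero_at_vortex_centers_and_cores(self, unit_circle_patch):
        spec = SecondaryFlowSpec()
        field = secondary_flow_unit_field(unit_circle_patch, spec)
        xy = unit_circle_patch.node_coords
        R = unit_circle_patch.effective_radius
        for cx, cy in spec.centers_m(unit_circle_patch):
            d = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)
            in_core = d < 0.15 * R
            assert in_core.any()
            assert np.all(field[in_core] == 0.0)

    def test_smallest_nonzero_node_outside_core(self, unit_circle_patch):
        spec = SecondaryFlowSpec()
        field = secondary_flow_unit_field(unit_circle_patch, spec)
        xy = unit_circle_patch.node_coords
        R = unit_circle_patch.effective_radius
        nonzero = np.any(field != 0.0, axis=1)
        for cx, cy in spec.centers_m(unit_circle_patch):
            d = np.hypot(xy[nonzero, 0] - cx, xy[nonzero, 1] - cy)
            assert d.min() >= 0.15 * R

    def test_symmetric_centers_cancel_along_shear_axis(self, unit_circle_patch):
        """Direct two-term arithmetic oracle at the origin."""
        a = 0.4
        spec = SecondaryFlowSpec(vortex_centers=((a, 0.0), (-a, 0.0)))
        field = secondary_flow_unit_field(unit_circle_patch, spec)
        origin = np.argmin(np.hypot(*unit_circle_patch.node_coords.T))
        x0, y0 = unit_circle_patch.node_coords[origin]
        a_m = a * unit_circle_patch.effective_radius
        d1sq = (x0 - a_m) ** 2 + y0**2
        d2sq = (x0 + a_m) ** 2 + y0**2
        expected_u = -(y0 - 0.0) / d1sq + (y0 - 0.0) / d2sq
        expected_v = (x0 - a_m) / d1sq - (x0 + a_m) / d2sq
        assert field[origin, 0] == pytest.approx(expected_u, abs=1e-12)
        assert field[origin, 1] == pytest.approx(expected_v, rel=1e-12)
        # along e1 the two contributions cancel; the resultant is along e2
        assert abs(field[origin, 0]) < 1e-9 * abs(field[origin, 1])

    def test_literal_radial_kernel_matches_printed_form(self, unit_circle_patch):
        spec = SecondaryFlowSpec(kernel_interpretation="literal_radial")
        field = secondary_flow_unit_field(unit_circle_patch, spec)
        xy = unit_circle_patch.node_coords
        R = unit_circle_patch.effective_radius
        (x1, y1), (x2, y2) = spec.centers_m(unit_circle_patch)
        r = np.hypot(xy[:, 0], xy[:, 1])
        r1, r2 = np.hypot(x1, y1), np.hypot(x2, y2)
        k = np.argmax(r)  # a boundary node, far from both cores
        exp_u = -(xy[k, 1] - y1) / (r[k] - r1) ** 2 + (xy[k, 1] - y2) / (r[k] - r2) ** 2
        exp_v = (xy[k, 0] - x1) / (r[k] - r1) ** 2 - (xy[k, 0] - x2) / (r[k] - r2) ** 2
        assert field[k, 0] == pytest.approx(exp_u, rel=1e-12)
        assert field[k, 1] == pytest.approx(exp_v, rel=1e-12)

    def test_centers_outside_patch_rejected(self, unit_circle_patch):
        spec = SecondaryFlowSpec(vortex_centers=((1.5, 0.0), (-0.4, 0.0)))
        with pytest.raises(ValueError, match="outside"):
            secondary_flow_unit_field(unit_circle_patch, spec)

    def test_secondary_flow_adds_no_axial_flux(self, circle_patch,
                                               aortic_fourier):
        spec = ProfileSpec("parabolic", secondary=SecondaryFlowSpec())
        times = np.linspace(0.1, 0.3, 5)
        field = generate_profile(circle_patch, spec, aortic_fourier, times)
        np.testing.assert_allclose(field.flux(), aortic_fourier.evaluate(times),
                                   rtol=1e-12)


class TestCalibrateK:
    def test_zero_target_ratio_gives_zero_K(self, circle_patch,
                                            constant_fourier):
        spec = SecondaryFlowSpec(target_speed_ratio=0.0)
        field = generate_profile(circle_patch, ProfileSpec("parabolic"),
                                 constant_fourier, [0.0])
        unit = secondary_flow_unit_field(circle_patch, spec)
        K = calibrate_K(field.axial, unit, spec, field.times, circle_patch)
        assert np.all(K == 0.0)

    def test_speed_ratio_hits_target_at_systole(self, circle_patch,
                                                aortic_fourier):
        spec = ProfileSpec("parabolic", secondary=SecondaryFlowSpec())
        t_sys = 0.5 * sum(systole_window(aortic_fourier))
        field = generate_profile(circle_patch, spec, aortic_fourier, [t_sys])
        ratio = field.mean_in_plane_speed()[0] / field.mean_axial_speed()[0]
        assert ratio == pytest.approx(0.24, abs=1e-10)

    def test_K_scales_linearly_with_flow(self, circle_patch):
        spec = SecondaryFlowSpec()
        unit = secondary_flow_unit_field(circle_patch, spec)
        fw1 = FourierWaveform(2e-4, np.zeros(0), np.zeros(0), 2 * np.pi)
        fw2 = FourierWaveform(4e-4, np.zeros(0), np.zeros(0), 2 * np.pi)
        f1 = generate_profile(circle_patch, ProfileSpec("parabolic"), fw1, [0.0])
        f2 = generate_profile(circle_patch, ProfileSpec("parabolic"), fw2, [0.0])
        K1 = calibrate_K(f1.axial, unit, spec, f1.times, circle_patch)
        K2 = calibrate_K(f2.axial, unit, spec, f2.times, circle_patch)
        assert K2[0] == pytest.approx(2.0 * K1[0], rel=1e-12)

    def test_zero_secondary_field_rejected(self, circle_patch,
                                           constant_fourier):
        spec = SecondaryFlowSpec()
        field = generate_profile(circle_patch, ProfileSpec("plug"),
                                 constant_fourier, [0.0])
        with pytest.raises(ValueError, match="zero mean speed"):
            calibrate_K(field.axial, np.zeros((circle_patch.n_nodes, 2)),
                        spec, field.times, circle_patch)


class TestExport:
    def test_round_trip_is_lossless(self, tmp_path, circle_patch,
                                    aortic_fourier):
        spec = ProfileSpec("parabolic", secondary=SecondaryFlowSpec())
        field = generate_profile(circle_patch, spec, aortic_fourier,
                                 [0.1, 0.2])
        path = tmp_path / "profile.csv"
        export_profile(field, path)
        back = read_profile(path, circle_patch)
        np.testing.assert_allclose(back.velocities, field.velocities,
                                   rtol=0, atol=1e-15)

    def test_empty_time_list_writes_header_only(self, tmp_path, circle_patch):
        from hemobc.inlet_profiles import VelocityField

        field = VelocityField(np.zeros(0),
                              np.zeros((0, circle_patch.n_nodes, 3)),
                              circle_patch)
        path = tmp_path / "empty.csv"
        export_profile(field, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("time_s,")

    def test_row_count_is_nodes_times_instants(self, tmp_path, circle_patch,
                                               constant_fourier):
        field = generate_profile(circle_patch, ProfileSpec("plug"),
                                 constant_fourier, [0.0, 0.5])
        path = tmp_path / "p.csv"
        export_profile(field, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) - 1 == 2 * circle_patch.n_nodes


def test_discrete_flux_matches_dot_product(circle_patch):
    rng = np.random.default_rng(3)
    u = rng.normal(size=circle_patch.n_nodes)
    f = discrete_flux(u, circle_patch.nodal_areas)
    assert f[0] == pytest.approx(float(u @ circle_patch.nodal_areas), rel=1e-12)
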