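import numpy as np
import pytest
import trimesh

from airwaykit import (
    DeformationConfig,
    ParameterError,
    PivotalPlaneSpec,
    TriangleMesh,
    build_displacement_field,
    compare_sections,
    deform_mesh,
    estimate_plane_anatomy,
    plane_params_from_expansion,
    resolve_anatomy,
    slice_mesh,
)

from conftest import planning_config


@pytest.fixture(scope="module")
def resolved(airway):
    return resolve_anatomy(airway, planning_config())


@pytest.fixture(scope="module")
def field(resolved):
    return build_displacement_field(resolved)


def one_sided_derivative_jump(f, at, h=0.1):
    """Difference of the two one-sided 3-point derivative estimates at a
    boundary; exact for piecewise quadratics, so a C1 field gives ~0."""
    left = (3 * f(at) - 4 * f(at - h) + f(at - 2 * h)) / (2 * h)
    right = (-3 * f(at) + 4 * f(at + h) - f(at + 2 * h)) / (2 * h)
    return np.abs(np.asarray(right) - np.asarray(left)).max()


class TestConfig:
    def test_plane_ordering_enforced(self):
        with pytest.raises((ParameterError, ValueError)):
            DeformationConfig(
                top_plane=PivotalPlaneSpec(z=-610.0),
                middle_plane=PivotalPlaneSpec(z=-587.0),
                lower_plane=PivotalPlaneSpec(z=-566.0),
            )

    def test_top_plane_must_be_fixed(self):
        with pytest.raises((ParameterError, ValueError)):
            DeformationConfig(
                top_plane=PivotalPlaneSpec(z=-566.0, dY=1.0),
                middle_plane=PivotalPlaneSpec(z=-587.0),
                lower_plane=PivotalPlaneSpec(z=-610.0),
            )

    def test_yc_below_ys(self):
        with pytest.raises((ParameterError, ValueError)):
            PivotalPlaneSpec(z=0.0, Ys=-20.0, Yc=-10.0)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            PivotalPlaneSpec(z=0.0, dY=-1.0)

    def test_json_round_trip(self, table_config):
        back = DeformationConfig(**table_config.model_dump())
        assert back == table_config

    def test_surgeon_estimate_to_parameters(self):
        # soft-palate section: 4 mm forward, 2 mm lateral expansion
        assert plane_params_from_expansion(4.0, 2.0) == (4.0, 1.0)
        # epiglottis section: 6 mm forward, 4 mm lateral
        assert plane_params_from_expansion(6.0, 4.0) == (6.0, 2.0)


class TestDisplacementField:
    def test_zero_parameters_zero_field(self, airway, zero_config):
        f = build_displacement_field(resolve_anatomy(airway, zero_config))
        rng = np.random.default_rng(5)
        pts = rng.uniform([-10, -25, -620], [10, -5, -540], size=(1000, 3))
        assert np.abs(f(pts)).max() == 0.0

    def test_fixed_above_top_plane(self, field):
        rng = np.random.default_rng(6)
        pts = rng.uniform([-10, -25, -566.0], [10, -5, -540], size=(500, 3))
        assert np.abs(field(pts)).max() == 0.0

    def test_fixed_spine_side(self, field, resolved):
        """Points at or behind the interpolated Ys never move (exact zero)."""
        rng = np.random.default_rng(7)
        z = rng.uniform(-615, -567, 300)
        ys = np.polyval(
            np.polyfit(
                [p.z for p in resolved.planes], [p.Ys for p in resolved.planes], 2
            ),
            z,
        )
        pts = np.column_stack([rng.uniform(-10, 10, 300), ys + rng.uniform(0, 5, 300), z])
        assert np.abs(field(pts)).max() == 0.0

    def test_anterior_extreme_moves_by_dY(self, field, resolved):
        mid = resolved.middle_plane
        disp = field(np.array([[mid.x_c, mid.Yc, mid.z]]))[0]
        assert disp[1] == pytest.approx(-4.0, abs=1e-9)
        low = resolved.lower_plane
        disp = field(np.array([[low.x_c, low.Yc, low.z]]))[0]
        assert disp[1] == pytest.approx(-6.0, abs=1e-9)

    def test_lateral_extreme_moves_by_dX_half(self, field, resolved):
        mid = resolved.middle_plane
        disp = field(np.array([[mid.x_c + mid.w_half, mid.y_wide, mid.z]]))[0]
        assert disp[0] == pytest.approx(1.0, abs=1e-9)

    def test_linear_in_parameters(self, airway, field):
        half = resolve_anatomy(airway, planning_config(2.0, 0.5, 3.0, 1.0))
        f_half = build_displacement_field(half)
        rng = np.random.default_rng(8)
        pts = rng.uniform([-9, -21, -615], [9, -11, -570], size=(500, 3))
        np.testing.assert_allclose(field(pts), 2.0 * f_half(pts), atol=1e-12)

    def test_c1_across_pivotal_planes(self, field):
        probes = [(0.0, -22.0), (5.0, -18.0), (-8.0, -14.0), (2.0, -11.0)]
        for zb in (-610.0, -598.5, -587.0, -566.0):
            for x, y in probes:
                jump = one_sided_derivative_jump(
                    lambda z: field(np.array([[x, y, z]]))[0], zb
                )
                assert jump < 1e-3

    def test_c1_across_spine_boundary(self, field):
        for z in (-570.0, -587.0, -600.0, -610.0):
            for x in (0.0, 4.0, -7.0):
                jump = one_sided_derivative_jump(
                    lambda y: field(np.array([[x, y, z]]))[0], -10.0
                )
                assert jump < 1e-3

    def test_incomplete_anatomy_rejected(self, table_config):
        with pytest.raises(ParameterError, match="anatomy"):
            build_displacement_field(table_config)


class TestDeformMesh:
    def test_zero_config_is_bit_exact_identity(self, airway, zero_config):
        out = deform_mesh(airway, zero_config)
        assert np.array_equal(out.vertices, airway.vertices)
        assert np.array_equal(out.faces, airway.faces)

    def test_achieved_widths_at_control_planes(self, airway, table_config):
        deformed = deform_mesh(airway, table_config)
        mid = compare_sections(slice_mesh(airway, -587.0), slice_mesh(deformed, -587.0))
        assert mid.achieved_dY == pytest.approx(4.0, abs=0.05)
        assert mid.achieved_dX_total == pytest.approx(2.0, abs=0.05)
        low = compare_sections(slice_mesh(airway, -610.0), slice_mesh(deformed, -610.0))
        assert low.achieved_dY == pytest.approx(6.0, abs=0.05)
        assert low.achieved_dX_total == pytest.approx(4.0, abs=0.05)

    def test_topology_unchanged(self, airway, table_config):
        deformed = deform_mesh(airway, table_config)
        assert deformed.n_vertices == airway.n_vertices
        np.testing.assert_array_equal(deformed.faces, airway.faces)

    def test_enlargement_never_shrinks_area(self, airway, table_config):
        deformed = deform_mesh(airway, table_config)
        for z in np.linspace(-615.0, -567.0, 13):
            assert slice_mesh(deformed, z).area >= slice_mesh(airway, z).area - 1e-9

    def test_mesh_above_top_plane_warns_identity(self, table_config):
        tube = trimesh.creation.cylinder(radius=5.0, height=10.0, sections=16)
        tube.apply_translation([0, 0, -500.0])  # entirely above z = -566
        mesh = TriangleMesh(np.asarray(tube.vertices), np.asarray(tube.faces))
        with pytest.warns(UserWarning, match="above the top"):
            out = deform_mesh(mesh, table_config)
        np.testing.assert_array_equal(out.vertices, mesh.vertices)


class TestPlaneAnatomy:
    def test_elliptical_tube_exact(self, airway):
        anatomy = estimate_plane_anatomy(airway, -590.0)
        assert anatomy.Ys == pytest.approx(-10.0, abs=1e-6)
        assert anatomy.Yc == pytest.approx(-22.0, abs=1e-6)
        assert anatomy.x_c == pytest.approx(0.0, abs=1e-6)
        assert anatomy.w_half == pytest.approx(10.0, abs=1e-6)

    def test_circle_symmetry(self):
        from airwaykit import SyntheticAirwaySpec, generate_airway

        mesh = generate_airway(SyntheticAirwaySpec(a_coeffs=[10.0], b_coeffs=[10.0]))
        anatomy = estimate_plane_anatomy(mesh, -600.0)
        assert anatomy.Ys - anatomy.Yc == pytest.approx(2 * anatomy.w_half, abs=1e-6)

    def test_multi_contour_uses_larger(self):
        big = trimesh.creation.cylinder(radius=5.0, height=10.0, sections=64)
        small = trimesh.creation.cylinder(radius=2.0, height=10.0, sections=64)
        small.apply_translation([12.0, 0.0, 0.0])
        both = trimesh.util.concatenate([big, small])
        mesh = TriangleMesh(np.asarray(both.vertices), np.asarray(both.faces))
        anatomy = estimate_plane_anatomy(mesh, 0.0)
        assert anatomy.w_half == pytest.approx(5.0, abs=0.05)
        assert anatomy.x_c == pytest.approx(0.0, abs=0.05)

    def test_empty_slice_rejected(self, airway):
        from airwaykit import SliceRangeError

        with pytest.raises(SliceRangeError):
            estimate_plane_anatomy(airway, 100.0)
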