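import numpy as np
import pytest
import trimesh

from efeg.forward_bem import (
    assemble_bem,
    bem_potential,
    bem_tangential_field,
    head_shaped_shell_meshes,
    sensor_frames_on_scalp,
    solid_angles,
    spherical_shell_meshes,
)
from efeg.forward_spherical import CurrentDipole, Shell, SphericalHeadModel, spherical_potential
from efeg.geometry import icosphere


def analytic_isotropic_model(n_max=300):
    return SphericalHeadModel(
        shells=(Shell(0.091, 0.3, 0.3), Shell(0.097, 0.006, 0.006), Shell(0.102, 0.3, 0.3)),
        n_max=n_max,
    )


@pytest.fixture(scope="module")
def bem_coarse():
    """Quick model for structural tests: all shells at subdivision 2."""
    return assemble_bem(spherical_shell_meshes(level=(2, 2, 2)))


@pytest.fixture(scope="module")
def bem_default():
    """Default resolution (inner skull level 4, outer shells level 3)."""
    return assemble_bem(spherical_shell_meshes(level=3))


def rel_rms(a, b):
    a = a - a.mean()
    b = b - b.mean()
    return np.linalg.norm(a - b) / np.linalg.norm(b)


class TestSolidAngles:
    def test_closed_surface_totals(self):
        mesh = icosphere(2, 0.1)
        tri = np.asarray(mesh.triangles)
        inside = np.array([[0.0, 0.01, 0.02]])
        outside = np.array([[0.0, 0.0, 0.5]])
        assert solid_angles(inside, tri).sum() == pytest.approx(4 * np.pi, rel=1e-12)
        assert solid_angles(outside, tri).sum() == pytest.approx(0.0, abs=1e-12)


class TestAssembly:
    def test_row_sums_satisfy_deflation_identity(self, bem_coarse):
        # the nested-conductivity telescoping makes every row of the double
        # layer sum to one, i.e. constants are a fixed point
        rows = bem_coarse.double_layer.sum(axis=1)
        assert np.max(np.abs(rows - 1.0)) < 1e-10

    def test_constant_vector_is_fixed_point(self, bem_coarse):
        ones = np.ones(bem_coarse.n_vertices)
        assert np.max(np.abs(bem_coarse.double_layer @ ones - 1.0)) < 1e-10

    def test_open_mesh_rejected(self):
        meshes = spherical_shell_meshes(level=(2, 2, 2))
        broken = trimesh.Trimesh(
            vertices=meshes[0].vertices, faces=meshes[0].faces[:-1], process=False
        )
        with pytest.raises(ValueError):
            assemble_bem([broken, meshes[1], meshes[2]])

    def test_inverted_mesh_rejected(self):
        meshes = spherical_shell_meshes(level=(2, 2, 2))
        inverted = trimesh.Trimesh(
            vertices=meshes[0].vertices, faces=meshes[0].faces[:, ::-1], process=False
        )
        with pytest.raises(ValueError):
            assemble_bem([inverted, meshes[1], meshes[2]])

    def test_content_hash_tracks_inputs(self, bem_coarse):
        other = assemble_bem(spherical_shell_meshes(level=(2, 2, 2)), (0.3, 0.012, 0.3))
        assert bem_coarse.content_hash() != other.content_hash()


class TestAccuracy:
    def test_matches_analytic_within_five_percent(self, bem_default):
        analytic = analytic_isotropic_model()
        dip = CurrentDipole((0, 0, 0.06), (0, 0, 1e-9))
        got = bem_default.scalp_potential(dip)
        pts = np.asarray(bem_default.scalp.vertices)
        expected = spherical_potential(analytic, dip, pts)
        assert rel_rms(got, expected) <= 0.05

    def test_isolated_skull_reformulation_is_exact(self):
        meshes = spherical_shell_meshes(level=(2, 2, 2))
        with_isa = assemble_bem(meshes, isolated_skull=True)
        without = assemble_bem(meshes, isolated_skull=False)
        dip = CurrentDipole((0.01, 0, 0.05), (1e-9, 0, 1e-9))
        va = with_isa.scalp_potential(dip)
        vb = without.scalp_potential(dip)
        assert rel_rms(va, vb) < 1e-9

    def test_refinement_halves_the_error(self):
        analytic = analytic_isotropic_model()
        dip = CurrentDipole((0, 0, 0.055), (0, 0, 1e-9))
        errors = []
        for level in ((2, 2, 2), (3, 3, 3)):
            bem = assemble_bem(spherical_shell_meshes(level=level))
            pts = np.asarray(bem.scalp.vertices)
            errors.append(rel_rms(bem.scalp_potential(dip), spherical_potential(analytic, dip, pts)))
        assert errors[1] <= 0.55 * errors[0]

    def test_mirror_symmetric_dipole_pair(self, bem_coarse):
        # the icosphere vertex set is symmetric under x -> -x, so the summed
        # field of mirrored dipoles must be mirror-symmetric vertex to vertex
        d1 = CurrentDipole((0.03, 0.01, 0.05), (0, 0, 1e-9))
        d2 = CurrentDipole((-0.03, 0.01, 0.05), (0, 0, 1e-9))
        v = bem_coarse.solve(d1) + bem_coarse.solve(d2)
        verts = np.vstack([m.vertices for m in bem_coarse.meshes])
        mirrored = verts * np.array([-1.0, 1.0, 1.0])
        # match mirrored vertices by coordinates
        order = np.lexsort(verts.T)
        order_m = np.lexsort(mirrored.T)
        assert np.allclose(verts[order], mirrored[order_m], atol=1e-12)
        diff = np.abs(v[order] - v[order_m])
        assert np.max(diff) < 1e-8 * np.max(np.abs(v))

    def test_linearity(self, bem_coarse):
        d1 = CurrentDipole((0.01, 0.02, 0.04), (1e-9, 0, 0))
        d2 = CurrentDipole((-0.02, 0.0, 0.05), (0, 1e-9, 1e-9))
        v1 = bem_coarse.solve(d1)
        v2 = bem_coarse.solve(d2)
        v12 = bem_coarse.solve_many(
            np.array([d1.pos, d2.pos]), np.array([d1.mom, d2.mom])
        ).sum(axis=1)
        assert np.allclose(v12, v1 + v2, rtol=1e-12, atol=1e-15)


class TestPotentialInterpolation:
    def test_vertex_evaluation_returns_vertex_potential(self, bem_coarse):
        dip = CurrentDipole((0, 0, 0.05), (0, 0, 1e-9))
        v = bem_coarse.scalp_potential(dip)
        pts = np.asarray(bem_coarse.scalp.vertices)[[3, 77, 150]]
        got = bem_potential(bem_coarse, dip, pts, vertex_potentials=v)
        assert np.allclose(got, v[[3, 77, 150]], rtol=1e-9)

    def test_zero_moment_gives_zeros(self, bem_coarse):
        dip = CurrentDipole((0, 0, 0.05), (0, 0, 0))
        pts = np.asarray(bem_coarse.scalp.vertices)[:5]
        assert np.all(bem_potential(bem_coarse, dip, pts) == 0.0)

    def test_far_off_surface_points_rejected(self, bem_coarse):
        dip = CurrentDipole((0, 0, 0.05), (0, 0, 1e-9))
        with pytest.raises(ValueError):
            bem_potential(bem_coarse, dip, np.array([[0, 0, 0.12]]))


class TestTangentialField:
    def test_frames_are_orthonormal_tangents(self, bem_coarse):
        sites = np.asarray(icosphere(1, 0.102).vertices)[:10]
        frames = sensor_frames_on_scalp(bem_coarse, sites)
        for f in frames:
            assert abs(f.azimuthal @ f.inclinational) < 1e-9
            assert np.linalg.norm(f.azimuthal) == pytest.approx(1.0, abs=1e-9)
            from efeg.forward_bem import closest_on_surface
            normal = bem_coarse.scalp.face_normals[
                closest_on_surface(bem_coarse.scalp, [f.position])[2][0]
            ]
            assert abs(f.azimuthal @ normal) < 1e-9
            assert abs(f.inclinational @ normal) < 1e-9

    def test_uniform_potential_gives_zero_field(self, bem_coarse):
        frames = sensor_frames_on_scalp(
            bem_coarse, np.asarray(icosphere(1, 0.102).vertices)[:8]
        )
        const = np.full(len(bem_coarse.scalp.vertices), 3.7)
        dip = CurrentDipole((0, 0, 0.05), (0, 0, 1e-9))
        field = bem_tangential_field(bem_coarse, dip, frames, vertex_potentials=const)
        assert np.max(np.abs(field)) < 1e-9

    def test_reference_shift_invariance(self, bem_coarse):
        dip = CurrentDipole((0, 0, 0.05), (0, 0, 1e-9))
        frames = sensor_frames_on_scalp(
            bem_coarse, np.asarray(icosphere(1, 0.102).vertices)[:8]
        )
        v = bem_coarse.scalp_potential(dip)
        f1 = bem_tangential_field(bem_coarse, dip, frames, vertex_potentials=v)
        f2 = bem_tangential_field(bem_coarse, dip, frames, vertex_potentials=v + 1.23e-5)
        assert np.allclose(f1, f2, atol=1e-12)

    def test_forward_close_to_central_difference(self, bem_default):
        # a deep source gives a smooth scalp field; away from facet
        # boundaries of the linear interpolant the one-sided difference
        # tracks the centered one, so compare in the RMS sense
        from efeg.experiment_data import make_montage

        dip = CurrentDipole((0, 0, 0.035), (0, 0, 1e-9))
        sites = make_montage(64, 0.0, ("V",), allow_any_count=True).sites
        frames = sensor_frames_on_scalp(bem_default, sites)
        v = bem_default.scalp_potential(dip)
        fwd = bem_tangential_field(bem_default, dip, frames, vertex_potentials=v)

        base = np.array([f.position for f in frames])
        incl = np.array([f.inclinational for f in frames])
        azim = np.array([f.azimuthal for f in frames])
        h = 1e-3
        central = np.column_stack(
            [
                -(
                    bem_potential(bem_default, dip, base + h * incl, vertex_potentials=v)
                    - bem_potential(bem_default, dip, base - h * incl, vertex_potentials=v)
                )
                / (2 * h),
                -(
                    bem_potential(bem_default, dip, base + h * azim, vertex_potentials=v)
                    - bem_potential(bem_default, dip, base - h * azim, vertex_potentials=v)
                )
                / (2 * h),
            ]
        )
        assert np.linalg.norm(fwd - central) < 0.02 * np.linalg.norm(central)

    def test_radial_source_ring_tangential_source_dumbbell(self, bem_default):
        # |E_t| of a radial source dips at its scalp projection (ring); a
        # tangential source peaks there (dumbbell)
        from efeg.experiment_data import make_montage

        sites = make_montage(128, 0.0, ("V",)).sites
        frames = sensor_frames_on_scalp(bem_default, sites)
        polar = np.arccos(np.clip(sites[:, 2] / 0.102, -1, 1))

        radial = CurrentDipole((0, 0, 0.05), (0, 0, 1e-9))
        mag_r = np.linalg.norm(
            bem_tangential_field(bem_default, radial, frames), axis=1
        )
        at_projection = mag_r[polar < 0.12].max()
        on_ring = mag_r[(polar > 0.3) & (polar < 0.8)].max()
        assert at_projection < 0.5 * on_ring

        tangential = CurrentDipole((0, 0, 0.05), (1e-9, 0, 0))
        mag_t = np.linalg.norm(
            bem_tangential_field(bem_default, tangential, frames), axis=1
        )
        assert mag_t[polar < 0.12].max() > 0.9 * mag_t.max()

    def test_nonpositive_step_rejected(self, bem_coarse):
        dip = CurrentDipole((0, 0, 0.05), (0, 0, 1e-9))
        frames = sensor_frames_on_scalp(bem_coarse, np.array([[0, 0, 0.102]]))
        with pytest.raises(ValueError):
            bem_tangential_field(bem_coarse, dip, frames, h=0.0)


def test_head_shaped_shells_nested_and_closed():
    meshes = head_shaped_shell_meshes(level=(2, 2, 2))
    for mesh in meshes:
        assert mesh.is_watertight and mesh.volume > 0
    # shells at equal subdivision share unit directions, so nesting is a
    # vertex-wise radius comparison
    for inner, outer in zip(meshes, meshes[1:]):
        r_in = np.linalg.norm(np.asarray(inner.vertices), axis=1)
        r_out = np.linalg.norm(np.asarray(outer.vertices), axis=1)
        assert np.all(r_in < r_out)
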