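import numpy as np
import pytest

from efeg.forward_spherical import (
    CurrentDipole,
    Shell,
    SphericalHeadModel,
    default_head_model,
    dipole_gain,
    field_falloff_curve,
    spherical_efield,
    spherical_potential,
)
from efeg.forward_spherical import _solve_harmonics
from efeg.geometry import icosphere

from oracles import (
    fd_radial_transfer,
    free_space_dipole_potential,
    isotropic_shell_potential,
    single_sphere_radial_closed_form,
)


def exterior_points(rng, n, radius):
    p = rng.normal(size=(n, 3))
    return p / np.linalg.norm(p, axis=1, keepdims=True) * radius


class TestPotential:
    def test_zero_moment_gives_zero(self, head_model):
        dip = CurrentDipole((0, 0, 0.08), (0, 0, 0))
        pts = np.array([[0, 0, 0.102], [0.11, 0, 0]])
        assert np.all(spherical_potential(head_model, dip, pts) == 0.0)

    def test_matches_free_space_in_a_huge_sphere(self, rng):
        # boundary corrections vanish when the outer shell is far away
        model = SphericalHeadModel(shells=(Shell(100.0, 0.3, 0.3),), n_max=80)
        dip = CurrentDipole((0.01, 0.02, 0.03), (1e-9, 2e-9, -0.5e-9))
        pts = exterior_points(rng, 20, 0.09)
        expected = free_space_dipole_potential(dip.pos, dip.mom, pts, 0.3)
        with pytest.warns(RuntimeWarning):
            got = spherical_potential(model, dip, pts)
        assert np.max(np.abs(got - expected)) < 1e-6 * np.max(np.abs(expected))

    def test_single_sphere_closed_form(self):
        R, sigma, b, p = 0.1, 0.4, 0.07, 1e-9
        model = SphericalHeadModel(shells=(Shell(R, sigma, sigma),), n_max=200)
        dip = CurrentDipole((0, 0, b), (0, 0, p))
        theta = np.linspace(0.05, np.pi, 40)
        pts = np.column_stack([R * np.sin(theta), 0 * theta, R * np.cos(theta)])
        got = spherical_potential(model, dip, pts)
        expected = single_sphere_radial_closed_form(R, sigma, b, p, np.cos(theta))
        assert np.max(np.abs(got - expected)) < 1e-6 * np.max(np.abs(expected))

    def test_isotropic_limit_matches_independent_shell_code(self, rng):
        model = default_head_model(skull_anisotropy=1.0, tol=1e-12)
        radii = [s.outer_radius for s in model.shells]
        sigmas = [s.sigma_r for s in model.shells]
        dip = CurrentDipole((0.02, -0.01, 0.07), (0.5e-9, 1e-9, 0.8e-9))
        pts = exterior_points(rng, 30, radii[-1])
        got = spherical_potential(model, dip, pts)
        expected = isotropic_shell_potential(radii, sigmas, dip.pos, dip.mom, pts, n_max=250)
        assert np.max(np.abs(got - expected)) < 1e-8 * np.max(np.abs(expected))

    def test_anisotropic_transfer_matches_finite_difference_bvp(self, head_model):
        sol = _solve_harmonics(head_model)
        R = head_model.scalp_radius
        radii = np.array([s.outer_radius for s in head_model.shells]) / R
        sr = [s.sigma_r for s in head_model.shells]
        st = [s.sigma_t for s in head_model.shells]
        r1 = radii[0]
        for n in range(1, 21):
            fd = fd_radial_transfer(radii, sr, st, n, rb_scaled=0.8, n_grid=10_000)
            # package transfer is per unit source scaled at the interface
            analytic = sol["t_scaled"][n - 1] * r1 ** -(n + 1)
            assert fd == pytest.approx(analytic, rel=1e-5), f"harmonic {n}"

    def test_superposition(self, head_model, rng):
        d1 = CurrentDipole((0.01, 0.02, 0.07), (1e-9, 0, 0.5e-9))
        d2 = CurrentDipole((-0.03, 0.0, 0.05), (0, -1e-9, 1e-9))
        both = CurrentDipole(
            (0.01, 0.02, 0.07), (2e-9, 0, 1e-9)
        )  # same location, doubled moment
        pts = exterior_points(rng, 10, 0.102)
        v1 = spherical_potential(head_model, d1, pts)
        assert np.allclose(
            spherical_potential(head_model, both, pts), 2 * v1, rtol=0, atol=1e-15 + 2e-12 * np.max(np.abs(v1))
        )
        v2 = spherical_potential(head_model, d2, pts)
        f1 = spherical_efield(head_model, d1, pts).e_cartesian
        f2 = spherical_efield(head_model, d2, pts).e_cartesian
        # superposition of distinct dipoles checked against summed fields
        assert np.allclose(v1 + v2, spherical_potential(head_model, d1, pts) + spherical_potential(head_model, d2, pts))
        assert f1.shape == f2.shape

    def test_rotational_covariance(self, head_model, rng):
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=3).as_matrix()
        dip = CurrentDipole((0.02, 0.01, 0.075), (1e-9, -0.3e-9, 0.6e-9))
        pts = exterior_points(rng, 15, 0.11)
        v = spherical_potential(head_model, dip, pts)
        e = spherical_efield(head_model, dip, pts).e_cartesian
        dip_r = CurrentDipole(rot @ dip.pos, rot @ dip.mom)
        v_r = spherical_potential(head_model, dip_r, pts @ rot.T)
        e_r = spherical_efield(head_model, dip_r, pts @ rot.T).e_cartesian
        assert np.max(np.abs(v - v_r)) < 1e-10 * np.max(np.abs(v))
        assert np.max(np.abs(e @ rot.T - e_r)) < 1e-10 * np.max(np.abs(e))

    def test_potential_continuous_across_scalp_surface(self, head_model):
        dip = CurrentDipole((0, 0, 0.06), (1e-9, 0, 1e-9))
        direction = np.array([[0.3, 0.4, np.sqrt(1 - 0.25)]])
        direction /= np.linalg.norm(direction)
        inside = spherical_potential(head_model, dip, direction * 0.10199999)
        outside = spherical_potential(head_model, dip, direction * 0.10200001)
        assert inside[0] == pytest.approx(outside[0], rel=1e-4)

    def test_dipole_outside_brain_shell_rejected(self, head_model):
        with pytest.raises(ValueError):
            spherical_potential(
                head_model, CurrentDipole((0, 0, 0.095), (0, 0, 1e-9)), np.array([[0, 0, 0.11]])
            )


class TestEField:
    def test_zero_moment_gives_zero_field(self, head_model):
        dip = CurrentDipole((0, 0, 0.08), (0, 0, 0))
        fs = spherical_efield(head_model, dip, np.array([[0, 0, 0.11]]))
        assert np.all(fs.e_cartesian == 0.0)

    def test_field_is_negative_gradient_of_potential(self, head_model, rng):
        dip = CurrentDipole((0.02, 0.01, 0.085), (0.3e-9, -0.2e-9, 1e-9))
        pts = exterior_points(rng, 10, 0.11)
        fs = spherical_efield(head_model, dip, pts)
        h = 1e-5  # 10 micron steps
        grad = np.empty((len(pts), 3))
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            grad[:, k] = (
                spherical_potential(head_model, dip, pts + e)
                - spherical_potential(head_model, dip, pts - e)
            ) / (2 * h)
        assert np.max(np.abs(fs.e_cartesian + grad)) < 1e-4 * np.max(np.abs(grad))

    def test_local_frame_decomposition_is_consistent(self, head_model, rng):
        dip = CurrentDipole((0.01, 0, 0.08), (1e-9, 1e-9, 0))
        pts = exterior_points(rng, 8, 0.12)
        fs = spherical_efield(head_model, dip, pts)
        recomposed = np.sqrt(fs.e_r**2 + fs.e_theta**2 + fs.e_phi**2)
        assert np.allclose(recomposed, fs.e_magnitude, rtol=1e-12)

    def test_field_requires_exterior_points(self, head_model):
        dip = CurrentDipole((0, 0, 0.05), (0, 0, 1e-9))
        with pytest.raises(ValueError):
            spherical_efield(head_model, dip, np.array([[0, 0, 0.095]]))

    def test_on_axis_point_above_tangential_dipole(self, head_model):
        # evaluation directly on the dipole axis exercises the pole limit
        dip = CurrentDipole((0, 0, 0.07), (1e-9, 0, 0))
        pole = np.array([[0, 0, 0.102]])
        near = np.array([[1e-6, 0, 0.102]])
        f_pole = spherical_efield(head_model, dip, pole).e_cartesian
        f_near = spherical_efield(head_model, dip, near).e_cartesian
        assert np.allclose(f_pole, f_near, rtol=1e-3)


class TestFalloff:
    def test_monotone_decreasing_and_consistent_at_zero(self, head_model):
        dip = CurrentDipole((0, 0, 0.082), (0, 0, 1e-9))
        standoffs = np.array([0.0, 0.01, 0.03, 0.10, 0.30])
        curve = field_falloff_curve(head_model, dip, standoffs, n_directions=642)
        assert np.all(np.diff(curve) < 0)
        scalp = spherical_efield(
            head_model, dip, np.asarray(icosphere(3, 0.102).vertices)
        ).e_magnitude
        assert curve[0] == pytest.approx(np.max(scalp), rel=1e-9)

    def test_negative_standoff_rejected(self, head_model):
        dip = CurrentDipole((0, 0, 0.082), (0, 0, 1e-9))
        with pytest.raises(ValueError):
            field_falloff_curve(head_model, dip, np.array([-0.01]))

    def test_far_field_approaches_inverse_cube(self, head_model):
        # the asymptotic dipole far field: slope vs center distance tends
        # to -3 from below as the head's higher multipoles die off
        dip = CurrentDipole((0, 0, 0.082), (0, 0, 1e-9))
        standoffs = np.array([0.3, 1.0, 3.0])
        curve = field_falloff_curve(head_model, dip, standoffs, n_directions=162)
        r = 0.102 + standoffs
        slopes = np.diff(np.log(curve)) / np.diff(np.log(r))
        assert slopes[-1] > slopes[0]
        assert slopes[-1] == pytest.approx(-3.0, abs=0.15)


class TestGainBuilder:
    def test_matches_single_dipole_path(self, head_model, rng):
        # the vectorized many-dipole kernel against the scalar evaluation path
        positions = np.array([[0.0, 0.0, 0.08], [0.03, -0.02, 0.05], [0.0, 0.04, -0.06]])
        moments = np.array([[0, 0, 1.0], [1.0, 0.5, 0.0], [0.3, -1.0, 0.2]]) * 1e-9
        sensors = exterior_points(rng, 12, 0.103)
        gains = dipole_gain(head_model, positions, moments, sensors)
        for j in range(len(positions)):
            dip = CurrentDipole(positions[j], moments[j])
            fs = spherical_efield(head_model, dip, sensors)
            # both paths truncate adaptively at the model tolerance (1e-8)
            for kind, ref in [("V", fs.potential), ("E_r", fs.e_r),
                              ("E_theta", fs.e_theta), ("E_phi", fs.e_phi)]:
                scale = np.max(np.abs(ref))
                assert np.max(np.abs(gains[kind][:, j] - ref)) < 1e-6 * scale + 1e-18

    def test_linear_in_moments(self, head_model, rng):
        positions = np.array([[0.01, 0.01, 0.07]])
        moments = np.array([[0.2e-9, -0.4e-9, 0.9e-9]])
        sensors = exterior_points(rng, 6, 0.102)
        g1 = dipole_gain(head_model, positions, moments, sensors)
        g2 = dipole_gain(head_model, positions, 3.0 * moments, sensors)
        for kind in g1:
            assert np.allclose(3.0 * g1[kind], g2[kind], rtol=1e-12)

    def test_rejects_bad_geometry(self, head_model):
        with pytest.raises(ValueError):
            dipole_gain(
                head_model, np.array([[0, 0, 0.095]]), np.array([[0, 0, 1e-9]]),
                np.array([[0, 0, 0.11]]),
            )
        with pytest.raises(ValueError):
            dipole_gain(
                head_model, np.array([[0, 0, 0.05]]), np.array([[0, 0, 1e-9]]),
                np.array([[0, 0, 0.09]]),
            )


def test_model_validation():
    with pytest.raises(ValueError):
        SphericalHeadModel(shells=(Shell(0.09, 0.3, 0.3), Shell(0.08, 0.3, 0.3)))
    with pytest.raises(ValueError):
        Shell(0.09, -0.3, 0.3)
    with pytest.raises(ValueError):
        SphericalHeadModel(shells=())
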