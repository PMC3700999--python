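"""Analytic potential and electric-field vector of a current dipole in a
concentric-shell head model with per-shell radial/tangential conductivity.

Model
-----
Inside shell ``k`` with radial conductivity ``sigma_r`` and tangential
conductivity ``sigma_t`` the quasi-static potential obeys

    sigma_r (1/r^2) d/dr (r^2 dV/dr) + (sigma_t / r^2) Lap_S V = 0,

which separates into (associated) Legendre angular parts and radial power
laws ``r**alpha`` with ``alpha (alpha + 1) = n (n + 1) sigma_t / sigma_r``:
two real exponents per shell per harmonic degree ``n`` (the familiar ``n``
and ``-(n+1)`` in the isotropic limit).  Coefficients are fixed by
continuity of ``V`` and of the radial current ``sigma_r dV/dr`` at the
interfaces, regularity at the center, zero radial current into the air at
the outer scalp boundary, and the free-space multipole expansion of the
dipole's primary source.

Outside the head the potential is continued harmonically
(``r**-(n+1)`` terms matched to the scalp-surface potential) and the field
in air is the negative gradient of that continuation; "scalp" field values
are the air-side limits, where EFEG sensors would sit.

Every evaluation works in scalp-radius units internally; per-shell power
bases are normalized at the shell boundaries so the interface systems stay
well conditioned up to high harmonic degree.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = [
    "Shell",
    "SphericalHeadModel",
    "CurrentDipole",
    "FieldSample",
    "default_head_model",
    "spherical_potential",
    "spherical_efield",
    "field_falloff_curve",
    "dipole_gain",
]


@dataclasses.dataclass(frozen=True)
class Shell:
    """One concentric shell: outer radius (m) and radial/tangential
    conductivities (S/m)."""

    outer_radius: float
    sigma_r: float
    sigma_t: float

    def __post_init__(self):
        if self.outer_radius <= 0:
            raise ValueError("shell radius must be positive")
        if self.sigma_r <= 0 or self.sigma_t <= 0:
            raise ValueError("conductivities must be positive")


@dataclasses.dataclass(frozen=True)
class SphericalHeadModel:
    """Ordered concentric shells, innermost first.

    Attributes
    ----------
    shells
        Shells with strictly increasing outer radii.
    n_max
        Hard truncation order of the Legendre series.
    tol
        Relative tail tolerance for adaptive truncation.
    """

    shells: tuple[Shell, ...]
    n_max: int = 400
    tol: float = 1e-8

    def __post_init__(self):
        radii = [s.outer_radius for s in self.shells]
        if len(radii) == 0:
            raise ValueError("model needs at least one shell")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("shell radii must be strictly increasing")

    @property
    def brain_radius(self) -> float:
        return self.shells[0].outer_radius

    @property
    def scalp_radius(self) -> float:
        return self.shells[-1].outer_radius


def default_head_model(skull_anisotropy: float = 10.0, **kwargs) -> SphericalHeadModel:
    """The 4-shell anisotropic head: brain / CSF / skull / scalp with outer
    radii 9.1 / 9.2 / 9.7 / 10.2 cm and radial conductivities
    0.3 / 1.5 / 0.006 / 0.3 S/m; the skull's tangential conductivity is
    ``skull_anisotropy`` times its radial one (10-fold by default, for the
    conductive diploe layer between the skull tables)."""
    return SphericalHeadModel(
        shells=(
            Shell(0.091, 0.3, 0.3),
            Shell(0.092, 1.5, 1.5),
            Shell(0.097, 0.006, 0.006 * skull_anisotropy),
            Shell(0.102, 0.3, 0.3),
        ),
        **kwargs,
    )


@dataclasses.dataclass(frozen=True)
class CurrentDipole:
    """Point current dipole: position (m, inside the innermost shell) and
    moment vector (A*m)."""

    position: tuple[float, float, float]
    moment: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "position", tuple(float(v) for v in self.position))
        object.__setattr__(self, "moment", tuple(float(v) for v in self.moment))

    @property
    def pos(self) -> np.ndarray:
        return np.array(self.position)

    @property
    def mom(self) -> np.ndarray:
        return np.array(self.moment)


@dataclasses.dataclass
class FieldSample:
    """Potential and E-vector samples in the local spherical frame of the
    head (radial, inclinational, azimuthal), plus Cartesian E."""

    positions: np.ndarray  # (m, 3)
    potential: np.ndarray  # (m,) volts
    e_r: np.ndarray  # (m,) V/m
    e_theta: np.ndarray
    e_phi: np.ndarray
    e_cartesian: np.ndarray  # (m, 3)
    converged: bool = True

    @property
    def e_tangential(self) -> np.ndarray:
        return np.hypot(self.e_theta, self.e_phi)

    @property
    def e_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.e_cartesian, axis=1)


# --------------------------------------------------------------------------
# per-harmonic radial boundary-value solve (cached per model)

_HARMONIC_CACHE: dict[tuple, dict] = {}


def _shell_exponents(n: int, shell: Shell) -> tuple[float, float]:
    """Radial power-law exponents in a (sigma_r, sigma_t) shell at degree n:
    roots of a(a+1) = n(n+1) sigma_t/sigma_r."""
    disc = np.sqrt(1.0 + 4.0 * n * (n + 1) * shell.sigma_t / shell.sigma_r)
    return (-1.0 + disc) / 2.0, (-1.0 - disc) / 2.0


def _solve_harmonics(model: SphericalHeadModel) -> dict:
    """Solve the per-degree interface systems for n = 1..n_max.

    Returns the scalp-surface transfer ``t_scaled[n-1]`` (response to a unit
    *scaled* singular source, see below) and the per-shell coefficients in
    boundary-normalized bases, for interior evaluation.

    Scaling: within the innermost shell the dipole's primary potential
    contributes a singular term ``s * r~**-(n+1)`` (``r~`` = radius in scalp
    units).  The system is solved for the particular solution normalized to 1
    at the first interface, i.e. ``(r~/r1)**-(n+1)``; physical source
    strengths are reattached during evaluation so that no large powers ever
    meet in the linear solve.
    """
    key = (model.shells, model.n_max)
    cached = _HARMONIC_CACHE.get(key)
    if cached is not None:
        return cached

    K = len(model.shells)
    R = model.scalp_radius
    r_out = np.array([s.outer_radius for s in model.shells]) / R  # scaled
    r_in = np.concatenate([[0.0], r_out[:-1]])
    nmax = model.n_max

    t_scaled = np.empty(nmax)
    coeffs = np.zeros((nmax, K, 2))
    exps = np.zeros((nmax, K, 2))

    for n in range(1, nmax + 1):
        size = 2 * K - 1
        A = np.zeros((size, size))
        b = np.zeros(size)
        al = np.array([_shell_exponents(n, s) for s in model.shells])  # (K, 2)
        exps[n - 1] = al

        def basis(k: int, r: float) -> tuple[np.ndarray, np.ndarray]:
            """Values and radial derivatives of the two power bases of shell
            k at scaled radius r (bases normalized at the shell edges)."""
            ap, am = al[k]
            vp = (r / r_out[k]) ** ap
            ref = r_in[k] if k > 0 else r_out[k]
            vm = (r / ref) ** am
            return np.array([vp, vm]), np.array([ap * vp / r, am * vm / r])

        # unknown layout: [A1, A2, B2, ..., AK, BK]
        def cols(k: int) -> slice:
            return slice(0, 1) if k == 0 else slice(2 * k - 1, 2 * k + 1)

        row = 0
        for k in range(K - 1):
            r = r_out[k]
            v_in, d_in = basis(k, r)
            v_out, d_out = basis(k + 1, r)
            n_in = 1 if k == 0 else 2
            # particular solution (r/r1)^-(n+1), unit at r1, lives in shell 0
            part_v = 1.0 if k == 0 else 0.0
            part_d = -(n + 1) / r if k == 0 else 0.0
            sig_in = model.shells[k].sigma_r
            sig_out = model.shells[k + 1].sigma_r
            A[row, cols(k)] = v_in[:n_in]
            A[row, cols(k + 1)] = -v_out
            b[row] = -part_v
            row += 1
            A[row, cols(k)] = sig_in * d_in[:n_in]
            A[row, cols(k + 1)] = -sig_out * d_out
            b[row] = -sig_in * part_d
            row += 1
        # outer boundary: zero radial current into air
        v, d = basis(K - 1, 1.0)
        n_last = 1 if K == 1 else 2
        A[row, cols(K - 1)] = model.shells[-1].sigma_r * d[:n_last]
        if K == 1:
            b[row] = model.shells[0].sigma_r * (n + 1)  # -sigma * d(particular)/dr at 1
        u = np.linalg.solve(A, b)

        coeffs[n - 1, 0, 0] = u[0]
        for k in range(1, K):
            coeffs[n - 1, k] = u[2 * k - 1 : 2 * k + 1]
        v_surf, _ = basis(K - 1, 1.0)
        t = coeffs[n - 1, K - 1] @ v_surf[:n_last] if K > 1 else u[0] * v_surf[0] + 1.0
        t_scaled[n - 1] = t

    out = {"t_scaled": t_scaled, "coeffs": coeffs, "exps": exps,
           "r_out": r_out, "r_in": r_in}
    _HARMONIC_CACHE[key] = out
    return out


# --------------------------------------------------------------------------
# series evaluation


def _dipole_frame(dipole: CurrentDipole):
    """Decompose a dipole into its radial/tangential parts: returns
    (b, bhat, p_r, p_t, that) with ``that`` the tangential moment direction."""
    pos = dipole.pos
    mom = dipole.mom
    b = float(np.linalg.norm(pos))
    if b < 1e-15:
        m = float(np.linalg.norm(mom))
        bhat = mom / m if m > 0 else np.array([0.0, 0.0, 1.0])
        return 0.0, bhat, m, 0.0, _any_orthonormal(bhat)
    bhat = pos / b
    p_r = float(mom @ bhat)
    p_tan = mom - p_r * bhat
    p_t = float(np.linalg.norm(p_tan))
    that = p_tan / p_t if p_t > 1e-300 else _any_orthonormal(bhat)
    return b, bhat, p_r, p_t, that


def _any_orthonormal(v: np.ndarray) -> np.ndarray:
    helper = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t = np.cross(v, helper)
    return t / np.linalg.norm(t)


def _n_terms(model: SphericalHeadModel, rb_scaled: float, rev_scaled: float) -> int:
    """Adaptive truncation: series terms decay like (rb/rev)**n."""
    q = max(rb_scaled, 1e-6) / max(rev_scaled, 1.0)
    if q >= 1.0:
        return model.n_max
    n = int(np.ceil(np.log(model.tol * (1.0 - q)) / np.log(q))) + 10
    return min(max(n, 20), model.n_max)


def _check_dipole(model: SphericalHeadModel, dipole: CurrentDipole) -> None:
    if np.linalg.norm(dipole.pos) >= model.brain_radius:
        raise ValueError("dipole must lie strictly inside the innermost shell")


def _pair_geometry(bhat, that, points_unit):
    """Angular geometry of evaluation directions relative to the dipole axis."""
    x = np.clip(points_unit @ bhat, -1.0, 1.0)  # cos(gamma)
    perp = points_unit - np.outer(x, bhat)
    s = np.linalg.norm(perp, axis=1)  # sin(gamma)
    bxt = np.cross(bhat, that)
    with np.errstate(invalid="ignore", divide="ignore"):
        cphi = np.where(s > 1e-12, (perp @ that) / s, 1.0)
        sphi = np.where(s > 1e-12, (perp @ bxt) / s, 0.0)
    e_phi_d = np.cross(np.broadcast_to(bhat, points_unit.shape), points_unit)
    e_phi_d = np.where(s[:, None] > 1e-12, e_phi_d / np.where(s[:, None] > 1e-12, s[:, None], 1.0), 0.0)
    e_theta_d = np.cross(e_phi_d, points_unit)
    return x, s, cphi, sphi, e_theta_d, e_phi_d


def _evaluate_dipole(
    model: SphericalHeadModel,
    dipole: CurrentDipole,
    points: np.ndarray,
    want_field: bool,
):
    """Series evaluation for one dipole at arbitrary points with radius larger
    than the dipole's.  Fields are only defined on/above the scalp (in air)."""
    _check_dipole(model, dipole)
    sol = _solve_harmonics(model)
    R = model.scalp_radius
    sigma1 = model.shells[0].sigma_r
    r1 = sol["r_out"][0]

    points = np.atleast_2d(np.asarray(points, dtype=float))
    rad = np.linalg.norm(points, axis=1)
    r_ev = rad / R
    b, bhat, p_r, p_t, that = _dipole_frame(dipole)
    rb = b / R
    if np.any(r_ev < rb - 1e-12):
        raise ValueError("evaluation points must lie outside the dipole's radius")
    if want_field and np.any(r_ev < 1.0 - 1e-9):
        raise ValueError("electric field evaluation requires points on or above the scalp")

    unit = points / np.where(rad[:, None] > 0, rad[:, None], 1.0)
    x, s, cphi, sphi, e_theta_d, e_phi_d = _pair_geometry(bhat, that, unit)
    pole = s <= 1e-8

    m = len(points)
    V = np.zeros(m)
    Er = np.zeros(m)
    Et_d = np.zeros(m)
    Ep_d = np.zeros(m)
    Epole = np.zeros(m)  # tangential-moment field magnitude along `that` at gamma ~ 0

    exterior = r_ev >= 1.0 - 1e-9
    interior = ~exterior
    n_terms = _n_terms(model, rb, float(np.min(r_ev)))

    # rolling Legendre recurrences
    P_prev = np.ones(m)  # P_0
    P = x.copy()  # P_1
    dP_prev = np.zeros(m)  # P'_0
    dP = np.ones(m)  # P'_1

    pow_b = 1.0  # (rb/r1)^(n-1)
    inv_rev = 1.0 / r_ev
    ext_fac = inv_rev**2  # r_ev^-(n+1) at n=1
    K_pot = 1.0 / (4.0 * np.pi * sigma1 * R**2)
    converged = True
    tail = np.inf

    for n in range(1, n_terms + 1):
        if n > 1:
            P_new = ((2 * n - 1) * x * P - (n - 1) * P_prev) / n
            dP_new = dP_prev + (2 * n - 1) * P
            P_prev, P = P, P_new
            dP_prev, dP = dP, dP_new
            pow_b *= rb / r1
            ext_fac *= inv_rev

        # radial factor per point
        radf = np.empty(m)
        if np.any(exterior):
            radf[exterior] = (
                sol["t_scaled"][n - 1] * pow_b / r1**2 * ext_fac[exterior]
            )
        if np.any(interior):
            radf[interior] = pow_b / r1**2 * _interior_radial(
                sol, model, n, r_ev[interior]
            )

        ang0 = n * p_r * P
        ang1 = p_t * s * dP * cphi
        dV = radf * (ang0 + ang1)
        V += dV
        if want_field:
            Er += radf * (n + 1) * inv_rev * (ang0 + ang1)
            Et_d += -radf * inv_rev * (
                -n * p_r * s * dP + p_t * (n * x * dP - (n + 1) * dP_prev) * cphi
            )
            Ep_d += radf * inv_rev * p_t * dP * sphi
            Epole += -radf * inv_rev * p_t * (n * (n + 1) / 2.0)

        # convergence bound on the whole term (fields grow an extra factor of
        # n over the potential, and V vanishes identically on the dipole
        # axis, so the potential increment alone is not a safe tail measure)
        term_bound = np.max(np.abs(radf)) * (n + 1) ** 2 * (abs(p_r) + abs(p_t))
        bound_sum = bound_sum + term_bound if n > 1 else term_bound
        tail = term_bound / max(bound_sum, 1e-300)
        if n > 5 and tail < model.tol:
            break
    else:
        if tail > model.tol * 10:
            converged = False
            warnings.warn(
                f"Legendre series not converged at n_max={model.n_max} "
                f"(relative tail {tail:.2e})",
                RuntimeWarning,
            )

    V = K_pot * V
    if not want_field:
        return V, converged

    K_field = K_pot / R
    Er *= K_field
    Et_d *= K_field
    Ep_d *= K_field
    Epole *= K_field

    e_cart = (
        Er[:, None] * unit + Et_d[:, None] * e_theta_d + Ep_d[:, None] * e_phi_d
    )
    if np.any(pole):
        # directly above the dipole the m=1 tangential pattern limits to a
        # uniform vector along the tangential moment direction
        e_cart[pole] = Er[pole, None] * unit[pole] + Epole[pole, None] * that
    return V, e_cart, converged


def _interior_radial(sol: dict, model: SphericalHeadModel, n: int, r_ev: np.ndarray):
    """Radial profile (per unit scaled source) below the scalp surface."""
    out = np.empty_like(r_ev)
    r_out, r_in = sol["r_out"], sol["r_in"]
    for k in range(len(model.shells)):
        lo = 0.0 if k == 0 else r_out[k - 1]
        sel = (r_ev >= lo - 1e-12) & (r_ev <= r_out[k] + 1e-12)
        if not np.any(sel):
            continue
        ap, am = sol["exps"][n - 1, k]
        ck = sol["coeffs"][n - 1, k]
        r = r_ev[sel]
        vp = (r / r_out[k]) ** ap
        ref = r_in[k] if k > 0 else r_out[k]
        vm = (r / ref) ** am
        val = ck[0] * vp + (ck[1] * vm if k > 0 else 0.0)
        if k == 0:
            val = val + (r / r_out[0]) ** (-(n + 1))  # particular (scaled)
        out[sel] = val
    return out


# --------------------------------------------------------------------------
# public operations


def spherical_potential(
    model: SphericalHeadModel, dipole: CurrentDipole, points: np.ndarray
) -> np.ndarray:
    """Potential (V) at ``points`` (on/above the scalp, or inside the shells
    at radii beyond the dipole's).  Reference-free: the series carries no
    monopole term, so the potential averages to zero over any full sphere of
    evaluation."""
    if not np.any(dipole.mom):
        return np.zeros(len(np.atleast_2d(points)))
    V, _ = _evaluate_dipole(model, dipole, points, want_field=False)
    return V


def spherical_efield(
    model: SphericalHeadModel, dipole: CurrentDipole, points: np.ndarray
) -> FieldSample:
    """Potential and full E-vector at exterior (air-side) points, expressed
    in the head's local spherical frame at each point."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.any(dipole.mom):
        z = np.zeros(len(points))
        return FieldSample(points, z, z.copy(), z.copy(), z.copy(), np.zeros_like(points))
    V, e_cart, converged = _evaluate_dipole(model, dipole, points, want_field=True)
    e_r, e_th, e_ph = _to_local_spherical(points, e_cart)
    return FieldSample(points, V, e_r, e_th, e_ph, e_cart, converged)


def _to_local_spherical(points: np.ndarray, vec: np.ndarray):
    """Project Cartesian vectors onto the local (r, theta, phi) head frame."""
    r = np.linalg.norm(points, axis=1, keepdims=True)
    rhat = points / r
    z = np.array([0.0, 0.0, 1.0])
    cos_t = np.clip(rhat @ z, -1.0, 1.0)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi_hat = np.cross(np.broadcast_to(z, rhat.shape), rhat)
    nrm = np.linalg.norm(phi_hat, axis=1, keepdims=True)
    # at the head poles theta/phi directions degenerate; pick x/y by convention
    safe = nrm[:, 0] > 1e-12
    phi_hat[safe] /= nrm[safe]
    phi_hat[~safe] = np.array([0.0, 1.0, 0.0])
    theta_hat = np.cross(phi_hat, rhat)
    return (
        np.sum(vec * rhat, axis=1),
        np.sum(vec * theta_hat, axis=1),
        np.sum(vec * phi_hat, axis=1),
    )


def field_falloff_curve(
    model: SphericalHeadModel,
    dipole: CurrentDipole,
    standoffs: np.ndarray,
    n_directions: int = 2562,
) -> np.ndarray:
    """Maximum |E| over a scalp-concentric sphere at each standoff (m) above
    the scalp surface.  Beyond ~10 cm the curve falls off as the inverse cube
    of the distance from the head center (the far-field dipole law)."""
    standoffs = np.asarray(standoffs, dtype=float)
    if np.any(standoffs < 0):
        raise ValueError("standoff distances must be >= 0")
    from .geometry import icosphere

    level = {12: 0, 42: 1, 162: 2, 642: 3, 2562: 4, 10242: 5}.get(n_directions, 4)
    dirs = np.asarray(icosphere(level, 1.0).vertices)
    out = np.empty(len(standoffs))
    for i, d in enumerate(standoffs):
        pts = dirs * (model.scalp_radius + d)
        out[i] = float(np.max(spherical_efield(model, dipole, pts).e_magnitude))
    return out


# --------------------------------------------------------------------------
# vectorized gain builder (many dipoles x many sensors, exterior points only)


def dipole_gain(
    model: SphericalHeadModel,
    positions: np.ndarray,
    moments: np.ndarray,
    sensors: np.ndarray,
    chunk: int = 1024,
) -> dict[str, np.ndarray]:
    """Forward gain of unit-moment dipoles at exterior sensor sites.

    Parameters
    ----------
    positions : (n_dip, 3)
        Dipole positions, strictly inside the innermost shell.
    moments : (n_dip, 3)
        Moment direction vectors (A*m); columns of the gain are linear in
        these, so unit vectors give the gain per unit moment.
    sensors : (n_sens, 3)
        Evaluation points on or above the scalp.

    Returns
    -------
    dict
        Arrays ``V``, ``E_r``, ``E_theta``, ``E_phi``, each (n_sens, n_dip);
        field components in the local spherical head frame at each sensor.
    """
    positions = np.asarray(positions, dtype=float)
    moments = np.asarray(moments, dtype=float)
    sensors = np.atleast_2d(np.asarray(sensors, dtype=float))
    nd, ns = len(positions), len(sensors)
    R = model.scalp_radius
    sigma1 = model.shells[0].sigma_r

    rb_all = np.linalg.norm(positions, axis=1)
    if np.any(rb_all >= model.brain_radius):
        raise ValueError("all dipoles must lie strictly inside the innermost shell")
    r_sens = np.linalg.norm(sensors, axis=1)
    if np.any(r_sens < R - 1e-9):
        raise ValueError("sensors must be on or above the scalp surface")

    sol = _solve_harmonics(model)
    r1 = sol["r_out"][0]
    t_sc = sol["t_scaled"]

    # local spherical frame at each sensor
    s_unit = sensors / r_sens[:, None]
    z = np.array([0.0, 0.0, 1.0])
    phi_hat = np.cross(np.broadcast_to(z, s_unit.shape), s_unit)
    nrm = np.linalg.norm(phi_hat, axis=1, keepdims=True)
    safe = nrm[:, 0] > 1e-12
    phi_hat[safe] /= nrm[safe]
    phi_hat[~safe] = np.array([0.0, 1.0, 0.0])
    theta_hat = np.cross(phi_hat, s_unit)

    out = {k: np.empty((ns, nd)) for k in ("V", "E_r", "E_theta", "E_phi")}
    r_ev = r_sens / R  # (ns,)

    for start in range(0, nd, chunk):
        stop = min(start + chunk, nd)
        dsl = slice(start, stop)
        V, Ec = _gain_chunk(
            model, sol, positions[dsl], moments[dsl], sensors, s_unit,
            r_ev, rb_all[dsl] / R, r1, t_sc, sigma1, R,
        )
        out["V"][:, dsl] = V
        out["E_r"][:, dsl] = np.einsum("sdk,sk->sd", Ec, s_unit)
        out["E_theta"][:, dsl] = np.einsum("sdk,sk->sd", Ec, theta_hat)
        out["E_phi"][:, dsl] = np.einsum("sdk,sk->sd", Ec, phi_hat)
    return out


def _gain_chunk(model, sol, positions, moments, sensors, s_unit, r_ev, rb, r1,
                t_sc, sigma1, R):
    nd = len(positions)
    ns = len(sensors)

    b = rb * R
    with np.errstate(invalid="ignore", divide="ignore"):
        bhat = np.where(b[:, None] > 0, positions / np.where(b[:, None] > 0, b[:, None], 1.0), 0.0)
    central = b < 1e-15
    if np.any(central):
        mnorm = np.linalg.norm(moments[central], axis=1, keepdims=True)
        bhat[central] = np.where(mnorm > 0, moments[central] / np.where(mnorm > 0, mnorm, 1.0), [0.0, 0.0, 1.0])
    p_r = np.einsum("dk,dk->d", moments, bhat)
    p_tan = moments - p_r[:, None] * bhat
    p_t = np.linalg.norm(p_tan, axis=1)
    that = np.where(p_t[:, None] > 1e-300, p_tan / np.where(p_t[:, None] > 0, p_t[:, None], 1.0), 0.0)
    degen = p_t <= 1e-300
    if np.any(degen):
        for i in np.where(degen)[0]:
            that[i] = _any_orthonormal(bhat[i])

    # pairwise geometry (ns, nd)
    x = np.clip(s_unit @ bhat.T, -1.0, 1.0)
    perp = s_unit[:, None, :] - x[:, :, None] * bhat[None, :, :]
    s = np.linalg.norm(perp, axis=2)
    bxt = np.cross(bhat, that)
    with np.errstate(invalid="ignore", divide="ignore"):
        cphi = np.where(s > 1e-12, np.einsum("snk,nk->sn", perp, that) / np.where(s > 0, s, 1.0), 1.0)
        sphi = np.where(s > 1e-12, np.einsum("snk,nk->sn", perp, bxt) / np.where(s > 0, s, 1.0), 0.0)
    e_phi_d = np.cross(np.broadcast_to(bhat[None, :, :], perp.shape), s_unit[:, None, :], axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_phi_d = np.where(s[:, :, None] > 1e-12, e_phi_d / np.where(s[:, :, None] > 0, s[:, :, None], 1.0), 0.0)
    e_theta_d = np.cross(e_phi_d, s_unit[:, None, :], axis=2)
    pole = s <= 1e-8

    n_terms = _n_terms(model, float(np.max(rb)), float(np.min(r_ev)))

    P_prev = np.ones((ns, nd))
    P = x.copy()
    dP_prev = np.zeros((ns, nd))
    dP = np.ones((ns, nd))

    pow_b = np.ones(nd)  # (rb/r1)^(n-1)
    inv_rev = 1.0 / r_ev  # (ns,)
    ext_fac = inv_rev**2  # r^-(n+1), n=1
    V = np.zeros((ns, nd))
    Er = np.zeros((ns, nd))
    Et = np.zeros((ns, nd))
    Ep = np.zeros((ns, nd))
    Epole = np.zeros((ns, nd))

    for n in range(1, n_terms + 1):
        if n > 1:
            P_new = ((2 * n - 1) * x * P - (n - 1) * P_prev) / n
            dP_new = dP_prev + (2 * n - 1) * P
            P_prev, P = P, P_new
            dP_prev, dP = dP, dP_new
            pow_b *= rb / r1
            ext_fac *= inv_rev
        radf = (t_sc[n - 1] / r1**2) * ext_fac[:, None] * pow_b[None, :]
        ang = (n * p_r)[None, :] * P + p_t[None, :] * s * dP * cphi
        V += radf * ang
        Er += radf * (n + 1) * inv_rev[:, None] * ang
        Et += -radf * inv_rev[:, None] * (
            -(n * p_r)[None, :] * s * dP
            + p_t[None, :] * (n * x * dP - (n + 1) * dP_prev) * cphi
        )
        Ep += radf * inv_rev[:, None] * p_t[None, :] * dP * sphi
        Epole += -radf * inv_rev[:, None] * p_t[None, :] * (n * (n + 1) / 2.0)

    K_pot = 1.0 / (4.0 * np.pi * sigma1 * R**2)
    V *= K_pot
    K_field = K_pot / R
    Ec = (
        (Er * K_field)[:, :, None] * s_unit[:, None, :]
        + (Et * K_field)[:, :, None] * e_theta_d
        + (Ep * K_field)[:, :, None] * e_phi_d
    )
    if np.any(pole):
        w = np.where(pole)
        Ec[w[0], w[1], :] = (
            (Er[w] * K_field)[:, None] * s_unit[w[0]]
            + (Epole[w] * K_field)[:, None] * that[w[1]]
        )
    return V, Ec
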