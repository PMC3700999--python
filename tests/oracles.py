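"""Independent reference implementations used as test oracles.

Everything here is deliberately coded along different algorithmic routes than
the package (transfer matrices instead of a global interface solve, finite
differences instead of closed-form exponents, explicit loops instead of
vectorized kernels) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse
import scipy.sparse.linalg
from scipy.special import eval_legendre, lpmv


def free_space_dipole_potential(position, moment, points, sigma):
    """Exact potential of a current dipole in an unbounded homogeneous
    conductor."""
    d = np.atleast_2d(points) - np.asarray(position)
    r = np.linalg.norm(d, axis=1)
    return d @ np.asarray(moment) / (4.0 * np.pi * sigma * r**3)


def single_sphere_radial_closed_form(R, sigma, b, p, cos_theta):
    """Closed-form surface potential of a radial dipole at radius ``b`` on
    the axis of a homogeneous sphere of radius ``R`` (insulated outside),
    from the generating-function summation of the Legendre series."""
    f = b / R
    x = np.asarray(cos_theta, dtype=float)
    d = np.sqrt(1.0 - 2.0 * f * x + f**2)
    return p / (4.0 * np.pi * sigma * R**2) * (1.0 / f) * (
        2.0 * f * (x - f) / d**3 + 1.0 / d - 1.0
    )


def isotropic_shell_potential(radii, sigmas, dipole_pos, dipole_mom, points, n_max=200):
    """Scalp-surface potential in an isotropic concentric-shell head via
    2x2 transfer matrices propagated outward shell by shell.

    ``radii``/``sigmas`` are ordered innermost to outermost; ``points`` must
    lie on the outer surface.
    """
    radii = np.asarray(radii, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    R = radii[-1]
    points = np.atleast_2d(points)

    pos = np.asarray(dipole_pos, dtype=float)
    mom = np.asarray(dipole_mom, dtype=float)
    b = np.linalg.norm(pos)
    if b < 1e-15:
        bhat = np.array([0.0, 0.0, 1.0])
    else:
        bhat = pos / b
    p_r = mom @ bhat
    p_tan = mom - p_r * bhat
    p_t = np.linalg.norm(p_tan)
    that = p_tan / p_t if p_t > 0 else np.array([1.0, 0.0, 0.0])
    if abs(bhat @ that) > 1e-12:
        that = that - (bhat @ that) * bhat
        that /= np.linalg.norm(that)

    x = np.clip(points @ bhat / np.linalg.norm(points, axis=1), -1.0, 1.0)
    perp = points / np.linalg.norm(points, axis=1, keepdims=True) - x[:, None] * bhat
    s = np.linalg.norm(perp, axis=1)
    cphi = np.where(s > 1e-12, perp @ that / np.where(s > 0, s, 1.0), 1.0)

    V = np.zeros(len(points))
    for n in range(1, n_max + 1):
        # state (V_n, sigma V_n') propagated from the first interface out
        # sources: singular coefficient of r^-(n+1) from the free-space dipole
        s_rad = p_r * n * b ** (n - 1) / (4.0 * np.pi * sigmas[0])
        s_tan = p_t * b ** (n - 1) / (4.0 * np.pi * sigmas[0])

        def transfer(source_coeff):
            # within shell k: V = a r^n + c r^-(n+1); unknown a1 with unit
            # source; propagate (a, c) via continuity of V and sigma V'
            # coefficients as linear functions of a1: (alpha, beta) pairs
            a = np.array([1.0, 0.0])  # a_k = alpha * a1 + beta
            c = np.array([0.0, source_coeff])
            for k in range(len(radii) - 1):
                r = radii[k]
                s_in, s_out = sigmas[k], sigmas[k + 1]
                v_val = a * r**n + c * r ** -(n + 1)
                dv_val = s_in * (a * n * r ** (n - 1) - c * (n + 1) * r ** -(n + 2))
                m = np.array(
                    [
                        [r**n, r ** -(n + 1)],
                        [s_out * n * r ** (n - 1), -s_out * (n + 1) * r ** -(n + 2)],
                    ]
                )
                sol = np.linalg.solve(m, np.vstack([v_val, dv_val]))
                a, c = sol[0], sol[1]
            # outer boundary: sigma V'(R) = 0
            num = a[1] * n * R ** (n - 1) - c[1] * (n + 1) * R ** -(n + 2)
            den = a[0] * n * R ** (n - 1) - c[0] * (n + 1) * R ** -(n + 2)
            a1 = -num / den
            a_f = a[0] * a1 + a[1]
            c_f = c[0] * a1 + c[1]
            return a_f * R**n + c_f * R ** -(n + 1)

        v_rad = transfer(s_rad) if s_rad != 0.0 else 0.0
        v_tan = transfer(s_tan) if s_tan != 0.0 else 0.0
        # scipy's lpmv includes the Condon-Shortley phase, hence the minus
        V += v_rad * eval_legendre(n, x) + v_tan * (-lpmv(1, n, x)) * cphi
        if n > 5 and b > 0 and (b / radii[0]) ** n < 1e-12:
            break
    return V


def fd_radial_transfer(radii_scaled, sigma_r, sigma_t, n, rb_scaled, n_grid=10_000,
                       richardson=True):
    """Scalp-surface potential per unit singular source coefficient for one
    harmonic degree, by dense finite differences of the radial equation
    d/dr (sigma_r r^2 V') = sigma_t n(n+1) V through the (possibly
    anisotropic) outer shells.

    The innermost shell (isotropic) is treated exactly as
    ``A r^n + s r^-(n+1)`` with ``s = 1``; the FD grid covers the outer
    shells with jump conditions at the first interface.  Returns V at the
    outer surface (radius 1 in scaled units).

    The conservative scheme is first-order at the material-interface nodes;
    ``richardson`` removes that leading error by extrapolating two grids.
    """
    if richardson:
        coarse = fd_radial_transfer(
            radii_scaled, sigma_r, sigma_t, n, rb_scaled, n_grid, richardson=False
        )
        fine = fd_radial_transfer(
            radii_scaled, sigma_r, sigma_t, n, rb_scaled, 2 * n_grid, richardson=False
        )
        return 2.0 * fine - coarse
    r1 = radii_scaled[0]
    # piecewise-uniform grid with interfaces exactly on nodes
    knots = list(radii_scaled[1:-1]) + [1.0]
    segments = []
    lo = r1
    total = 1.0 - r1
    for hi in knots:
        n_pts = max(int(round(n_grid * (hi - lo) / total)), 50)
        seg = np.linspace(lo, hi, n_pts + 1)
        segments.append(seg if not segments else seg[1:])
        lo = hi
    grid = np.concatenate(segments)
    n_grid = len(grid)
    h = np.diff(grid)

    def sig(r, which):
        for k in range(1, len(radii_scaled)):
            if r <= radii_scaled[k] + 1e-12:
                return (sigma_r[k], sigma_t[k])[which]
        return (sigma_r[-1], sigma_t[-1])[which]

    m = n_grid + 1  # grid unknowns + A (coefficient of r^n in shell 1)
    rows, cols, vals = [], [], []
    rhs = np.zeros(m)

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    # interior conservative stencil
    for i in range(1, n_grid - 1):
        rm = 0.5 * (grid[i - 1] + grid[i])
        rp = 0.5 * (grid[i] + grid[i + 1])
        sm = sig(rm, 0) * rm**2 / h[i - 1]
        sp = sig(rp, 0) * rp**2 / h[i]
        add(i, i - 1, sm)
        add(i, i, -(sm + sp) - sig(grid[i], 1) * n * (n + 1) * 0.5 * (h[i - 1] + h[i]))
        add(i, i + 1, sp)
    # inner boundary: continuity of V and flux with the exact shell-1 form
    # V(r1-) = A r1^n + r1^-(n+1)  must equal grid[0] value
    add(0, 0, 1.0)
    add(0, n_grid, -(r1**n))
    rhs[0] = r1 ** -(n + 1)
    # flux: sigma1 (A n r1^(n-1) - (n+1) r1^-(n+2)) = sigma2 V'(r1+)
    s2 = sig(grid[0] + 1e-12, 0)
    add(n_grid, 0, s2 * (-3.0 / (2 * h[0])))
    add(n_grid, 1, s2 * (4.0 / (2 * h[0])))
    add(n_grid, 2, s2 * (-1.0 / (2 * h[0])))
    add(n_grid, n_grid, -sigma_r[0] * n * r1 ** (n - 1))
    rhs[n_grid] = -sigma_r[0] * (n + 1) * r1 ** -(n + 2)
    # outer boundary: V'(1) = 0 (one-sided second order)
    add(n_grid - 1, n_grid - 1, 3.0 / (2 * h[-1]))
    add(n_grid - 1, n_grid - 2, -4.0 / (2 * h[-1]))
    add(n_grid - 1, n_grid - 3, 1.0 / (2 * h[-1]))

    A = scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(m, m))
    sol = scipy.sparse.linalg.spsolve(A.tocsc(), rhs)
    return sol[n_grid - 1]


def brute_force_covariance(x):
    """Literal two-pass covariance loop over channels and observations."""
    x = np.asarray(x, dtype=float)
    n_ch, n_obs = x.shape
    means = [sum(x[i]) / n_obs for i in range(n_ch)]
    C = np.empty((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(n_ch):
            acc = 0.0
            for t in range(n_obs):
                acc += (x[i, t] - means[i]) * (x[j, t] - means[j])
            C[i, j] = acc / n_obs
    return C
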