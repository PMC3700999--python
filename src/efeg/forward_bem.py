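"""Three-shell isotropic boundary-element forward solver for scalp potential,
with tangential E-field components by 1-mm surface finite differences.

The solver discretizes the surface-integral form of the piecewise-homogeneous
volume-conduction problem (nested scalp / skull / inner-skull compartments)
with per-vertex collocation: triangle solid angles are computed analytically
(van Oosterom & Strackee) and lumped to the triangle vertices, the diagonal is
fixed by the closed-surface solid-angle identity, the interior Neumann null
space is removed by deflation, and the isolated-skull approach is used by
default to keep the weakly conducting skull from amplifying discretization
error.  The radial E component is deliberately not computed here: a boundary
potential solve only supports tangential differencing on the scalp, which is
also how a surface sensor triplet would measure it.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np
import scipy.linalg
import trimesh

from .forward_spherical import CurrentDipole
from .geometry import icosphere

__all__ = [
    "BemHeadModel",
    "SensorFrame",
    "assemble_bem",
    "bem_potential",
    "bem_tangential_field",
    "spherical_shell_meshes",
    "head_shaped_shell_meshes",
    "sensor_frames_on_scalp",
]

DEFAULT_CONDUCTIVITIES = (0.3, 0.006, 0.3)  # inner (CSF+brain), skull, scalp, S/m


@dataclasses.dataclass(frozen=True)
class SensorFrame:
    """A scalp sensor site with its tangential measurement directions."""

    position: np.ndarray  # on the scalp surface
    azimuthal: np.ndarray  # unit tangent, local phi direction
    inclinational: np.ndarray  # unit tangent, local theta direction

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "azimuthal", np.asarray(self.azimuthal, dtype=float))
        object.__setattr__(self, "inclinational", np.asarray(self.inclinational, dtype=float))


def solid_angles(observers: np.ndarray, triangles: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Signed solid angles (van Oosterom & Strackee) subtended by each
    triangle at each observer; positive when the outward face normal points
    away from the observer side that closes to 4 pi from inside.

    Parameters
    ----------
    observers : (n_obs, 3)
    triangles : (n_tri, 3, 3)

    Returns
    -------
    (n_obs, n_tri) array of solid angles (steradian).
    """
    n_obs = len(observers)
    out = np.empty((n_obs, len(triangles)))
    t = triangles[None, :, :, :]  # (1, n_tri, 3, 3)
    for start in range(0, n_obs, chunk):
        stop = min(start + chunk, n_obs)
        r = t - observers[start:stop, None, None, :]  # (c, n_tri, 3, 3)
        r1, r2, r3 = r[:, :, 0], r[:, :, 1], r[:, :, 2]
        l1 = np.linalg.norm(r1, axis=-1)
        l2 = np.linalg.norm(r2, axis=-1)
        l3 = np.linalg.norm(r3, axis=-1)
        numer = np.einsum("ctk,ctk->ct", r1, np.cross(r2, r3))
        denom = (
            l1 * l2 * l3
            + np.einsum("ctk,ctk->ct", r1, r2) * l3
            + np.einsum("ctk,ctk->ct", r1, r3) * l2
            + np.einsum("ctk,ctk->ct", r2, r3) * l1
        )
        out[start:stop] = 2.0 * np.arctan2(numer, denom)
    return out


def closest_on_surface(mesh: trimesh.Trimesh, points: np.ndarray, k: int = 16):
    """Closest surface point, distance and triangle index for each query.

    Candidate triangles come from a KD-tree over triangle centroids; exact
    point-triangle projection then picks the best candidate.  Suitable for
    points on or near the surface (all uses here).
    """
    import scipy.spatial

    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = np.asarray(mesh.triangles)
    centroids = tri.mean(axis=1)
    k = min(k, len(tri))
    _, cand = scipy.spatial.cKDTree(centroids).query(points, k=k)
    cand = np.atleast_2d(cand)
    n, kk = cand.shape
    flat_tri = tri[cand.ravel()]
    flat_pts = np.repeat(points, kk, axis=0)
    proj = trimesh.triangles.closest_point(flat_tri, flat_pts).reshape(n, kk, 3)
    d = np.linalg.norm(proj - points[:, None, :], axis=2)
    best = np.argmin(d, axis=1)
    idx = np.arange(n)
    return proj[idx, best], d[idx, best], cand[idx, best]


def _subdivide_barycentric(depth: int) -> np.ndarray:
    """Barycentric corner coordinates of the 4**depth subtriangles of the
    unit triangle; shape (4**depth, 3, 3)."""
    tris = np.array([np.eye(3)])
    for _ in range(depth):
        out = []
        for t in tris:
            a, b, c = t
            ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
            out += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        tris = np.array(out)
    return tris


_SUB_COARSE = _subdivide_barycentric(2)  # 16 subtriangles
_SUB_FINE = _subdivide_barycentric(3)  # 64 subtriangles


def _near_field_corrections(
    W: np.ndarray,
    verts: np.ndarray,
    tri: np.ndarray,
    faces: np.ndarray,
    omega: np.ndarray,
) -> None:
    """Replace the lumped 1/3-per-vertex rule by subdivided integration of
    the linear shape functions for observers close to a (non-incident)
    triangle, where the solid-angle kernel varies across the element."""
    centroids = tri.mean(axis=1)
    edge = np.median(np.linalg.norm(tri[:, 0] - tri[:, 1], axis=1))
    d = np.linalg.norm(verts[:, None, :] - centroids[None, :, :], axis=2)
    incident = omega == 0.0  # includes own triangles (zeroed earlier)
    for sub, lo, hi in ((_SUB_FINE, 0.0, 2.0), (_SUB_COARSE, 2.0, 4.0)):
        obs_idx, tri_idx = np.where((d >= lo * edge) & (d < hi * edge) & ~incident)
        if len(obs_idx) == 0:
            continue
        corners = tri[tri_idx]  # (p, 3, 3)
        # world-space subtriangle corners: (p, n_sub, 3 corners, 3)
        sub_pts = np.einsum("scb,pbk->psck", sub, corners)
        # solid angle of each subtriangle from its observer
        r = sub_pts - verts[obs_idx][:, None, None, :]
        r1, r2, r3 = r[:, :, 0], r[:, :, 1], r[:, :, 2]
        l1 = np.linalg.norm(r1, axis=-1)
        l2 = np.linalg.norm(r2, axis=-1)
        l3 = np.linalg.norm(r3, axis=-1)
        numer = np.einsum("psk,psk->ps", r1, np.cross(r2, r3))
        denom = (
            l1 * l2 * l3
            + np.einsum("psk,psk->ps", r1, r2) * l3
            + np.einsum("psk,psk->ps", r1, r3) * l2
            + np.einsum("psk,psk->ps", r2, r3) * l1
        )
        om = 2.0 * np.arctan2(numer, denom)  # (p, n_sub)
        bary_centroid = sub.mean(axis=1)  # (n_sub, 3) shape-function values
        integral = np.einsum("ps,sc->pc", om, bary_centroid)  # (p, 3 corners)
        lumped = omega[obs_idx, tri_idx][:, None] / 3.0
        delta = integral - lumped
        for c in range(3):
            np.add.at(W, (obs_idx, faces[tri_idx, c]), delta[:, c])


@dataclasses.dataclass
class BemHeadModel:
    """Assembled dense boundary operator for nested isotropic shells.

    ``meshes`` are ordered innermost to outermost (inner skull, outer skull,
    scalp); ``conductivities`` are the compartment values inside each mesh.
    """

    meshes: list[trimesh.Trimesh]
    conductivities: tuple[float, ...]
    double_layer: np.ndarray  # D, (n_total, n_total); row sums = 1
    _lu: tuple  # LU of deflated (I - D)
    _iso: dict | None  # isolated-skull pieces, or None
    offsets: np.ndarray  # vertex index offset of each surface
    source_sigma: float

    @property
    def n_vertices(self) -> int:
        return self.offsets[-1]

    @property
    def scalp(self) -> trimesh.Trimesh:
        return self.meshes[-1]

    @property
    def scalp_slice(self) -> slice:
        return slice(self.offsets[-2], self.offsets[-1])

    def content_hash(self) -> str:
        """Hash of meshes + conductivities, usable as a cache key."""
        h = hashlib.sha256()
        for mesh in self.meshes:
            h.update(np.ascontiguousarray(mesh.vertices).tobytes())
            h.update(np.ascontiguousarray(mesh.faces).tobytes())
        h.update(np.asarray(self.conductivities).tobytes())
        return h.hexdigest()[:16]

    def solve(self, dipole: CurrentDipole) -> np.ndarray:
        """Vertex potentials on all surfaces for one dipole (volts)."""
        return self.solve_many(dipole.pos[None, :], dipole.mom[None, :])[:, 0]

    def solve_many(self, positions: np.ndarray, moments: np.ndarray) -> np.ndarray:
        """Vertex potentials (n_total, n_dipoles) for a batch of dipoles."""
        g = self._source_term(positions, moments)
        if self._iso is None:
            return scipy.linalg.lu_solve(self._lu, g)
        iso = self._iso
        v_iso = scipy.linalg.lu_solve(iso["lu"], g[: self.offsets[1]] * iso["g_scale"])
        g_mod = g.copy()
        g_mod[: self.offsets[1]] = iso["rhs_inner"] * v_iso
        g_mod[self.offsets[1] :] += iso["couple"] @ v_iso
        v = scipy.linalg.lu_solve(self._lu, g_mod)
        v[: self.offsets[1]] += iso["c"] * v_iso
        return v

    def scalp_potential(self, dipole: CurrentDipole) -> np.ndarray:
        v = self.solve(dipole)
        return v[self.scalp_slice]

    def _source_term(self, positions: np.ndarray, moments: np.ndarray) -> np.ndarray:
        verts = np.vstack([m.vertices for m in self.meshes])
        d = verts[:, None, :] - positions[None, :, :]  # (n_v, n_d, 3)
        dist3 = np.linalg.norm(d, axis=-1) ** 3
        v_inf = np.einsum("vdk,dk->vd", d, moments) / (4.0 * np.pi * self.source_sigma * dist3)
        return v_inf * self._g_row_scale[:, None]


def _surface_index(meshes) -> tuple[np.ndarray, np.ndarray]:
    counts = [len(m.vertices) for m in meshes]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    surf_of = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
    return offsets, surf_of


def assemble_bem(
    meshes: list[trimesh.Trimesh],
    conductivities: tuple[float, ...] = DEFAULT_CONDUCTIVITIES,
    isolated_skull: bool | None = None,
) -> BemHeadModel:
    """Assemble the dense per-vertex collocation double-layer operator.

    Parameters
    ----------
    meshes
        Closed, outward-oriented surfaces ordered innermost to outermost.
    conductivities
        Conductivity of the compartment *inside* each surface (S/m); the
        medium outside the last surface is air.
    isolated_skull
        Apply the isolated-skull reformulation.  Defaults to automatic: on
        when the second compartment is less than 0.1 times as conductive as
        the first (the low-conductivity regime where the plain operator
        loses accuracy to cancellation).
    """
    if len(meshes) != len(conductivities):
        raise ValueError("need one conductivity per surface")
    for mesh in meshes:
        if not mesh.is_watertight:
            raise ValueError("BEM surfaces must be closed meshes")
        if mesh.volume <= 0:
            raise ValueError("BEM surfaces must be oriented outward")

    n_surf = len(meshes)
    sigma_in = np.asarray(conductivities, dtype=float)
    sigma_out = np.concatenate([sigma_in[1:], [0.0]])
    offsets, surf_of = _surface_index(meshes)
    n_total = offsets[-1]
    verts = np.vstack([m.vertices for m in meshes])

    # solid-angle weight matrix W[i, j]: linear shape functions integrated
    # against the solid-angle kernel.  Far triangles use the lumped rule
    # (exact total angle, 1/3 per vertex); near triangles are subdivided and
    # integrated sub-triangle by sub-triangle, which captures the linear
    # variation where the kernel is strong.
    W = np.zeros((n_total, n_total))
    for k, mesh in enumerate(meshes):
        tri = np.asarray(mesh.triangles)
        faces = np.asarray(mesh.faces) + offsets[k]
        omega = solid_angles(verts, tri)  # (n_total, n_tri_k)
        # triangles incident to the observer subtend zero angle from their
        # own plane; zero them explicitly to avoid numerical noise
        own = slice(offsets[k], offsets[k + 1])
        for c in range(3):
            omega[faces[:, c], np.arange(len(faces))] = 0.0
        contrib = omega / 3.0
        for c in range(3):
            np.add.at(W.T, faces[:, c], contrib.T)
        _near_field_corrections(W, verts, tri, faces, omega)
        # closed-surface identity fixes the self weight: total = 2 pi on the
        # surface itself (4 pi / 0 for enclosed / outside observers is exact)
        idx = np.arange(offsets[k], offsets[k + 1])
        W[idx, idx] += 2.0 * np.pi - W[own, offsets[k]:offsets[k + 1]].sum(axis=1)

    sig_sum = sigma_in[surf_of] + sigma_out[surf_of]  # per observer row
    sig_diff = sigma_in[surf_of] - sigma_out[surf_of]  # per source column
    D = (W / (2.0 * np.pi)) * (sig_diff[None, :] / sig_sum[:, None])

    source_sigma = sigma_in[0]
    g_row_scale = 2.0 * source_sigma / sig_sum

    # deflation removes the constant null vector of (I - D)
    M = np.eye(n_total) - D + 1.0 / n_total
    lu = scipy.linalg.lu_factor(M)

    if isolated_skull is None:
        isolated_skull = n_surf >= 2 and sigma_in[1] / sigma_in[0] < 0.1

    iso = None
    if isolated_skull:
        if n_surf < 2:
            raise ValueError("isolated-skull approach needs nested surfaces")
        n1 = offsets[1]
        s_in, s_out = sigma_in[0], sigma_out[0]
        if s_in == s_out:
            raise ValueError("isolated-skull approach undefined for equal conductivities")
        # single-surface (insulated) problem on the innermost surface
        D_iso = W[:n1, :n1] / (2.0 * np.pi)
        M_iso = np.eye(n1) - D_iso + 1.0 / n1
        c = s_in / (s_in - s_out)
        iso = {
            "lu": scipy.linalg.lu_factor(M_iso),
            # isolated source term is (2 sigma0 / sigma_in) v_inf; the full
            # model's g on S1 is (2 sigma0 / (s_in+s_out)) v_inf
            "g_scale": (s_in + s_out) / s_in,
            "rhs_inner": -2.0 * s_in * s_out / (s_in**2 - s_out**2),
            "couple": c * D[n1:, :n1],
            "c": c,
        }

    model = BemHeadModel(
        meshes=list(meshes),
        conductivities=tuple(conductivities),
        double_layer=D,
        _lu=lu,
        _iso=iso,
        offsets=offsets,
        source_sigma=source_sigma,
    )
    model._g_row_scale = g_row_scale
    return model


def bem_potential(
    model: BemHeadModel, dipole: CurrentDipole, points: np.ndarray,
    vertex_potentials: np.ndarray | None = None,
    max_offset: float = 1e-3,
) -> np.ndarray:
    """Scalp potential at arbitrary on-surface points by barycentric
    interpolation of the solved vertex potentials."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.any(dipole.mom) and vertex_potentials is None:
        return np.zeros(len(points))
    if vertex_potentials is None:
        vertex_potentials = model.scalp_potential(dipole)
    scalp = model.scalp
    closest, dist, tri_id = closest_on_surface(scalp, points)
    if np.any(dist > max_offset):
        raise ValueError(
            f"points up to {dist.max() * 1e3:.1f} mm off the scalp surface "
            f"(limit {max_offset * 1e3:.0f} mm)"
        )
    tris = scalp.triangles[tri_id]
    bary = trimesh.triangles.points_to_barycentric(tris, closest)
    face_verts = scalp.faces[tri_id]
    return np.einsum("pc,pc->p", bary, vertex_potentials[face_verts])


def sensor_frames_on_scalp(model: BemHeadModel, positions: np.ndarray) -> list[SensorFrame]:
    """Project sensor positions onto the scalp mesh and attach orthonormal
    tangential frames (azimuthal / inclinational, i.e. local phi / theta)."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    closest, _, tri_id = closest_on_surface(model.scalp, positions)
    normals = model.scalp.face_normals[tri_id]
    z = np.array([0.0, 0.0, 1.0])
    frames = []
    for p, n in zip(closest, normals):
        az = np.cross(z, n)
        if np.linalg.norm(az) < 1e-9:
            az = np.array([0.0, 1.0, 0.0])
        az = az / np.linalg.norm(az)
        incl = np.cross(az, n)
        incl /= np.linalg.norm(incl)
        frames.append(SensorFrame(p, az, incl))
    return frames


def bem_tangential_field(
    model: BemHeadModel,
    dipole: CurrentDipole,
    frames: list[SensorFrame],
    h: float = 1e-3,
    vertex_potentials: np.ndarray | None = None,
) -> np.ndarray:
    """Tangential E components ``(E_theta, E_phi)`` per frame by forward
    differencing of the scalp potential over 1 mm (default) steps.

    Each displaced point is projected back onto the scalp surface before the
    potential is interpolated, mirroring a surface sensor triplet.
    """
    if h <= 0:
        raise ValueError("finite-difference step h must be positive")
    if vertex_potentials is None:
        vertex_potentials = model.scalp_potential(dipole)
    base = np.array([f.position for f in frames])
    incl = np.array([f.inclinational for f in frames])
    azim = np.array([f.azimuthal for f in frames])

    def pot(points):
        proj, _, tri_id = closest_on_surface(model.scalp, points)
        tris = model.scalp.triangles[tri_id]
        bary = trimesh.triangles.points_to_barycentric(tris, proj)
        return np.einsum("pc,pc->p", bary, vertex_potentials[model.scalp.faces[tri_id]])

    v0 = pot(base)
    e_theta = -(pot(base + h * incl) - v0) / h
    e_phi = -(pot(base + h * azim) - v0) / h
    return np.column_stack([e_theta, e_phi])


def _shell_levels(level: int | tuple[int, int, int]) -> tuple[int, int, int]:
    # the innermost (inner skull) surface is meshed one level finer by
    # default, which controls the error amplified by the resistive skull
    return (level + 1, level, level) if isinstance(level, int) else tuple(level)


def spherical_shell_meshes(
    level: int | tuple[int, int, int] = 3,
    radii: tuple[float, float, float] = (0.091, 0.097, 0.102),
) -> list[trimesh.Trimesh]:
    """Concentric icosphere shells (innermost to outermost) for
    cross-validation against the analytic spherical model.  An integer
    ``level`` meshes the inner skull at ``level + 1`` and the outer shells at
    ``level``; pass an explicit (inner, mid, outer) tuple to override."""
    return [icosphere(lv, r) for lv, r in zip(_shell_levels(level), radii)]


def head_shaped_shell_meshes(
    level: int | tuple[int, int, int] = 3,
    radii: tuple[float, float, float] = (0.091, 0.097, 0.102),
    axes: tuple[float, float, float] = (1.0, 0.85, 0.75),
) -> list[trimesh.Trimesh]:
    """Smoothly non-spherical (ellipsoidal) shells standing in for
    MRI-derived head geometry; same nesting as the spherical variant."""
    scale = np.asarray(axes)
    out = []
    for lv, r in zip(_shell_levels(level), radii):
        mesh = icosphere(lv, r)
        mesh = trimesh.Trimesh(vertices=mesh.vertices * scale, faces=mesh.faces, process=False)
        out.append(mesh)
    return out
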