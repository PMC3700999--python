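"""Synthetic-data stage: cortical source patches, sensor montages at chosen
standoffs, the global amplitude calibration, and sensors x observations data
matrices for every measurement type.

A "source patch" is one observation: a contiguous set of 37 normal-oriented
unit dipoles (fewer at the 12 pentagonal mesh vertices) sharing a common
amplitude, centered on a node of the next-coarser icosphere grid so that the
patches tile each hemisphere uniformly.  The single global amplitude is set
so that the strongest patch produces a 10 microvolt maximum scalp potential,
typical of human evoked responses.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse
import trimesh

from . import forward_bem, forward_spherical
from .forward_bem import BemHeadModel
from .forward_spherical import SphericalHeadModel
from .geometry import CorticalSurface, neighborhood

__all__ = [
    "SourcePatch",
    "SensorArray",
    "DataMatrix",
    "make_montage",
    "build_source_space",
    "dipole_gain_matrix",
    "patch_gain",
    "calibrate_amplitude",
    "build_data_matrix",
    "TARGET_SCALP_POTENTIAL",
    "PCA_STANDOFFS",
    "LOCALIZATION_STANDOFFS",
    "FIELD_KINDS",
    "membership_matrix",
]

TARGET_SCALP_POTENTIAL = 10e-6  # V; max scalp potential of the strongest patch
PCA_STANDOFFS = (0.0, 0.001, 0.010, 0.030)  # m, signal-count experiments
LOCALIZATION_STANDOFFS = (0.0, 0.01, 0.03, 0.10)  # m, localization experiments
FIELD_KINDS = ("E_r", "E_theta", "E_phi")
KNOWN_KINDS = ("V",) + FIELD_KINDS


@dataclasses.dataclass(frozen=True)
class SourcePatch:
    """One simulated activation: a patch center with its <= 3rd-ring
    neighborhood, all dipoles along the local cortex normals."""

    patch_id: int
    center: int  # global dipole index
    members: np.ndarray  # global dipole indices
    hemisphere: str  # "rh" | "lh"
    is_tangential: bool  # mean |tangential moment| > mean |radial moment|

    def __post_init__(self):
        object.__setattr__(self, "members", np.asarray(self.members, dtype=np.int64))


@dataclasses.dataclass(frozen=True)
class SensorArray:
    """Sensor sites plus the measurement kind of every channel.

    Channels are ordered kind-major: all sites for the first kind, then all
    sites for the next, so a 128-site montage with the three field kinds has
    384 channels.
    """

    sites: np.ndarray  # (n_sites, 3), positions at the stated standoff
    kinds: tuple[str, ...]
    standoff: float
    scalp_radius: float
    montage_id: str

    def __post_init__(self):
        object.__setattr__(self, "sites", np.asarray(self.sites, dtype=float))
        bad = set(self.kinds) - set(KNOWN_KINDS)
        if bad:
            raise ValueError(f"unknown channel kinds: {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_channels(self) -> int:
        return self.n_sites * len(self.kinds)

    @property
    def channel_kinds(self) -> np.ndarray:
        return np.repeat(self.kinds, self.n_sites)

    @property
    def channel_sites(self) -> np.ndarray:
        return np.tile(np.arange(self.n_sites), len(self.kinds))

    def subset(self, kinds: tuple[str, ...]) -> "SensorArray":
        """Same sites, restricted channel kinds (e.g. tangential-only)."""
        return dataclasses.replace(self, kinds=tuple(kinds))

    def at_standoff(self, standoff: float) -> "SensorArray":
        """Shift every site radially to a new standoff above the scalp."""
        unit = self.sites / np.linalg.norm(self.sites, axis=1, keepdims=True)
        return dataclasses.replace(
            self, sites=unit * (self.scalp_radius + standoff), standoff=standoff
        )

    def to_text(self) -> str:
        """Whitespace-delimited electrode coordinate table (label x y z, m)."""
        lines = [
            f"S{i + 1:03d} {p[0]:+.6f} {p[1]:+.6f} {p[2]:+.6f}"
            for i, p in enumerate(self.sites)
        ]
        return "\n".join(lines) + "\n"


def make_montage(
    n_sensors: int = 128,
    standoff: float = 0.0,
    kinds: tuple[str, ...] = ("V",),
    scalp_radius: float = 0.102,
    cap_angle: float = 2.0 * np.pi / 3.0,
    allow_any_count: bool = False,
) -> SensorArray:
    """Quasi-uniform head-net-like sensor cap.

    Sites follow a Fibonacci spiral over the spherical cap of polar half-angle
    ``cap_angle`` (120 degrees by default: crown coverage without face and
    neck, emulating a 128-channel net), shifted radially to ``standoff``
    meters above the scalp sphere.  Supported counts are 128 and the 485-site
    refinement of the same cap; other counts need ``allow_any_count``.
    """
    if n_sensors not in (128, 485) and not allow_any_count:
        raise ValueError(
            f"montage size {n_sensors} not in (128, 485); "
            "pass allow_any_count=True for arbitrary sizes"
        )
    if standoff < 0:
        raise ValueError("standoff must be >= 0")
    i = np.arange(n_sensors)
    # equal-area polar placement over the cap, golden-angle azimuths
    cos_theta = 1.0 - (1.0 - np.cos(cap_angle)) * (i + 0.5) / n_sensors
    theta = np.arccos(cos_theta)
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = scalp_radius + standoff
    sites = np.column_stack(
        [
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
            r * np.cos(theta),
        ]
    )
    return SensorArray(
        sites=sites,
        kinds=tuple(kinds),
        standoff=standoff,
        scalp_radius=scalp_radius,
        montage_id=f"cap{n_sensors}",
    )


def _hemi_arrays(cortex: CorticalSurface):
    """Global dipole arrays: right hemisphere first, then left."""
    positions = np.vstack([cortex.right.vertices, cortex.left.vertices])
    normals = np.vstack([cortex.right_normals, cortex.left_normals])
    return positions, normals


def build_source_space(cortex: CorticalSurface) -> list[SourcePatch]:
    """One patch per node of the next-coarser icosphere grid per hemisphere.

    For the default subdivision-5 cortex this gives 2,562 centers per
    hemisphere (5,124 patches), each with its 37-dipole third-ring
    neighborhood (32 at the 24 pentagonal centers).  Relies on the nested
    vertex ordering of the icosphere: the first ``10 * 4**(L-1) + 2``
    vertices of the level-L mesh are the level-(L-1) grid.
    """
    level = cortex.subdivision
    n_fine = 10 * 4**level + 2
    n_coarse = 10 * 4 ** (level - 1) + 2
    for hemi, mesh in cortex.hemispheres.items():
        if len(mesh.vertices) != n_fine:
            raise ValueError(
                f"{hemi} mesh has {len(mesh.vertices)} vertices; expected "
                f"{n_fine} for subdivision {level}"
            )
    positions, normals = _hemi_arrays(cortex)
    patches: list[SourcePatch] = []
    for h, (hemi, mesh) in enumerate(cortex.hemispheres.items()):
        offset = h * n_fine
        for center in range(n_coarse):
            members = neighborhood(mesh, center, 3) + offset
            mom = normals[members]
            pos = positions[members]
            rhat = pos / np.linalg.norm(pos, axis=1, keepdims=True)
            radial = np.abs(np.einsum("ik,ik->i", mom, rhat))
            tang = np.linalg.norm(mom - np.einsum("ik,ik->i", mom, rhat)[:, None] * rhat, axis=1)
            patches.append(
                SourcePatch(
                    patch_id=len(patches),
                    center=center + offset,
                    members=members,
                    hemisphere=hemi,
                    is_tangential=bool(np.mean(tang) > np.mean(radial)),
                )
            )
    return patches


def membership_matrix(patches: list[SourcePatch], n_dipoles: int) -> scipy.sparse.csr_matrix:
    """Sparse (n_dipoles x n_patches) patch membership indicator."""
    rows = np.concatenate([p.members for p in patches])
    cols = np.concatenate([np.full(len(p.members), p.patch_id) for p in patches])
    return scipy.sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_dipoles, len(patches))
    )


@dataclasses.dataclass
class DataMatrix:
    """Channels x observations matrix with its metadata."""

    data: np.ndarray
    montage: SensorArray
    patches: list[SourcePatch]
    amplitude: float  # common dipole amplitude, A*m
    model_label: str

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_observations(self) -> int:
        return self.data.shape[1]


def dipole_gain_matrix(
    model: SphericalHeadModel | BemHeadModel,
    cortex: CorticalSurface,
    montage: SensorArray,
) -> np.ndarray:
    """Channels x dipoles lead field for every cortex vertex (unit moments
    along the cortex normals); the matrix the inverse solvers invert."""
    positions, normals = _hemi_arrays(cortex)
    if isinstance(model, SphericalHeadModel):
        gains = forward_spherical.dipole_gain(model, positions, normals, montage.sites)
        return np.vstack([gains[kind] for kind in montage.kinds])
    if isinstance(model, BemHeadModel):
        return _bem_dipole_gain(model, positions, normals, montage)
    raise TypeError(f"unsupported model type: {type(model)!r}")


def patch_gain(
    model: SphericalHeadModel | BemHeadModel,
    cortex: CorticalSurface,
    patches: list[SourcePatch],
    montage: SensorArray,
    dipole_gain: np.ndarray | None = None,
) -> np.ndarray:
    """Channels x patches gain per unit dipole amplitude (columns are the
    forward fields of unit patches: the sum over member dipoles)."""
    if dipole_gain is None:
        dipole_gain = dipole_gain_matrix(model, cortex, montage)
    n_dipoles = dipole_gain.shape[1]
    member = membership_matrix(patches, n_dipoles)
    return np.asarray((member.T.tocsr() @ dipole_gain.T).T)


def _bem_dipole_gain(
    model: BemHeadModel, positions: np.ndarray, moments: np.ndarray, montage: SensorArray
) -> np.ndarray:
    """BEM gain; supports scalp potential and tangential field kinds only."""
    if "E_r" in montage.kinds:
        raise ValueError(
            "the BEM forward solution does not provide the radial field "
            "component (unsupported channel kind 'E_r')"
        )
    if montage.standoff > 1e-9:
        raise ValueError("BEM channels are defined on the scalp surface only")
    v = model.solve_many(positions, moments)[model.scalp_slice]  # (n_scalp_v, n_dip)
    frames = forward_bem.sensor_frames_on_scalp(model, montage.sites)
    base = np.array([f.position for f in frames])
    incl = np.array([f.inclinational for f in frames])
    azim = np.array([f.azimuthal for f in frames])
    h = 1e-3

    interp0 = _interpolator(model.scalp, base)
    interp_t = _interpolator(model.scalp, base + h * incl)
    interp_p = _interpolator(model.scalp, base + h * azim)
    blocks = []
    for kind in montage.kinds:
        if kind == "V":
            blocks.append(interp0 @ v)
        elif kind == "E_theta":
            blocks.append(-((interp_t @ v) - (interp0 @ v)) / h)
        elif kind == "E_phi":
            blocks.append(-((interp_p @ v) - (interp0 @ v)) / h)
    return np.vstack(blocks)


def _interpolator(scalp: trimesh.Trimesh, points: np.ndarray) -> scipy.sparse.csr_matrix:
    """Sparse barycentric interpolation operator from scalp vertices to
    (projected) points."""
    proj, _, tri_id = forward_bem.closest_on_surface(scalp, points)
    bary = trimesh.triangles.points_to_barycentric(scalp.triangles[tri_id], proj)
    faces = scalp.faces[tri_id]
    rows = np.repeat(np.arange(len(points)), 3)
    return scipy.sparse.csr_matrix(
        (bary.ravel(), (rows, faces.ravel())), shape=(len(points), len(scalp.vertices))
    )


def calibrate_amplitude(
    gain: np.ndarray, target: float = TARGET_SCALP_POTENTIAL
) -> float:
    """Global dipole amplitude (A*m) such that the strongest patch reaches
    ``target`` volts peak over the potential channels (scalp, standoff 0)."""
    peak = float(np.max(np.abs(gain)))
    if peak == 0.0:
        raise ValueError("all-zero gain matrix cannot be calibrated")
    return target / peak


def build_data_matrix(
    model: SphericalHeadModel | BemHeadModel,
    cortex: CorticalSurface,
    patches: list[SourcePatch],
    montage: SensorArray,
    amplitude: float,
    gain: np.ndarray | None = None,
) -> DataMatrix:
    """Sensors x observations data matrix: column j is the forward solution
    of patch j (common amplitude times the sum of its member dipoles) at
    every channel of the montage."""
    if gain is None:
        gain = patch_gain(model, cortex, patches, montage)
    label = "spherical" if isinstance(model, SphericalHeadModel) else "bem"
    return DataMatrix(
        data=gain * amplitude,
        montage=montage,
        patches=patches,
        amplitude=amplitude,
        model_label=label,
    )
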