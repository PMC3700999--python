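"""Serialization helpers: HDF5 lead fields and BEM operators, plain-text
electrode coordinate tables."""

from __future__ import annotations

import json
import pathlib

import h5py
import numpy as np

from .experiment_data import SensorArray

__all__ = [
    "save_leadfield",
    "load_leadfield",
    "save_montage_text",
    "load_montage_text",
    "save_bem_operator",
    "load_bem_operator",
]


def save_leadfield(
    path: str | pathlib.Path, gains: dict[str, np.ndarray], metadata: dict | None = None
) -> None:
    """Write sensors x sources gain arrays (V, E_r, E_theta, E_phi, ...) as
    HDF5 datasets with a JSON sidecar of model parameters."""
    path = pathlib.Path(path)
    with h5py.File(path, "w") as f:
        for kind, arr in gains.items():
            f.create_dataset(kind, data=np.asarray(arr))
    if metadata is not None:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(metadata, indent=2))


def load_leadfield(path: str | pathlib.Path) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as f:
        return {k: f[k][()] for k in f.keys()}


def save_montage_text(montage: SensorArray, path: str | pathlib.Path) -> None:
    """Whitespace-delimited electrode coordinate file: label x y z (meters)."""
    pathlib.Path(path).write_text(montage.to_text())


def load_montage_text(path: str | pathlib.Path) -> np.ndarray:
    rows = []
    for line in pathlib.Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) == 4:
            rows.append([float(v) for v in parts[1:]])
    return np.asarray(rows)


def save_bem_operator(model, path: str | pathlib.Path) -> None:
    """Cache an assembled BEM double-layer operator keyed by the content hash
    of its meshes and conductivities."""
    with h5py.File(path, "w") as f:
        f.attrs["content_hash"] = model.content_hash()
        f.attrs["conductivities"] = np.asarray(model.conductivities)
        f.create_dataset("double_layer", data=model.double_layer)
        f.create_dataset("offsets", data=model.offsets)
        for i, mesh in enumerate(model.meshes):
            f.create_dataset(f"vertices_{i}", data=np.asarray(mesh.vertices))
            f.create_dataset(f"faces_{i}", data=np.asarray(mesh.faces))


def load_bem_operator(path: str | pathlib.Path, expected_hash: str | None = None):
    """Rebuild a BEM model from a cached operator; refuses a stale cache when
    ``expected_hash`` does not match."""
    import trimesh

    from .forward_bem import assemble_bem

    with h5py.File(path, "r") as f:
        stored = f.attrs["content_hash"]
        if expected_hash is not None and stored != expected_hash:
            raise ValueError(f"stale BEM cache: stored {stored}, expected {expected_hash}")
        conductivities = tuple(f.attrs["conductivities"])
        n = (len(f.keys()) - 2) // 2
        meshes = [
            trimesh.Trimesh(f[f"vertices_{i}"][()], f[f"faces_{i}"][()], process=False)
            for i in range(n)
        ]
    # reassembling is cheap relative to the solve and revalidates the meshes
    return assemble_bem(meshes, conductivities)
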