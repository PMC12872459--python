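"""File formats: GIFTI surfaces/metrics/labels, HDF5 matrices, text masks.

Vertex indexing is 0-based everywhere; text mask files declare it in a
header comment.  Every HDF5 artifact carries provenance attributes
(package version, seed, config hash, stage) so outputs are traceable to the
configuration that produced them.
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import nibabel as nib
import numpy as np
from nibabel import gifti

from .basis import LaplaceBasis
from .mesh import TriangleMesh
from .preprocess import RunSeries

__all__ = [
    "save_mesh_gifti", "load_mesh_gifti",
    "save_metric_gifti", "load_metric_gifti",
    "load_mask", "save_mask_text",
    "save_series_h5", "load_series_h5",
    "save_basis_h5", "load_basis_h5",
]


def _provenance(**meta) -> Dict[str, str]:
    from . import __version__
    out = {"package_version": __version__}
    out.update({k: str(v) for k, v in meta.items() if v is not None})
    return out


# ---------------------------------------------------------------- GIFTI


def save_mesh_gifti(path: str, mesh: TriangleMesh) -> None:
    """Write a .surf.gii geometry file (pointset + triangle arrays)."""
    coords = gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET")
    tris = gifti.GiftiDataArray(
        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE")
    img = gifti.GiftiImage(darrays=[coords, tris])
    if mesh.hemisphere is not None:
        img.meta["cortexcf_hemisphere"] = ",".join(
            str(int(h)) for h in mesh.hemisphere)
    nib.save(img, path)


def load_mesh_gifti(path: str) -> TriangleMesh:
    img = nib.load(path)
    coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")
    tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")
    if not coords or not tris:
        raise ValueError(f"{path}: not a GIFTI surface (missing arrays)")
    hemi = None
    tag = dict(img.meta).get("cortexcf_hemisphere")
    if tag:
        hemi = np.array([int(t) for t in tag.split(",")])
    return TriangleMesh(np.asarray(coords[0].data, dtype=float),
                        np.asarray(tris[0].data, dtype=np.int64),
                        hemisphere=hemi)


def save_metric_gifti(path: str, values: np.ndarray,
                      names: Optional[Sequence[str]] = None) -> None:
    """Write per-vertex scalar map(s) as a .func.gii metric file."""
    values = np.atleast_2d(np.asarray(values, dtype=np.float32))
    darrays = []
    for i, col in enumerate(values):
        da = gifti.GiftiDataArray(col, intent="NIFTI_INTENT_NONE")
        if names is not None:
            da.meta["Name"] = names[i]
        darrays.append(da)
    nib.save(gifti.GiftiImage(darrays=darrays), path)


def load_metric_gifti(path: str) -> np.ndarray:
    img = nib.load(path)
    data = np.stack([np.asarray(d.data, dtype=float) for d in img.darrays])
    return data[0] if data.shape[0] == 1 else data


def load_mask(path: str, n_vertices: Optional[int] = None) -> np.ndarray:
    """Vertex index mask from a GIFTI label file or a text index list.

    GIFTI label files select vertices with a nonzero label.  Text files list
    one 0-based index per line; ``#`` lines are comments.  Out-of-range
    indices are rejected with the offending value.
    """
    if path.endswith(".gii"):
        img = nib.load(path)
        data = np.asarray(img.darrays[0].data)
        idx = np.flatnonzero(data != 0)
    else:
        idx = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    idx.append(int(line))
        idx = np.asarray(sorted(set(idx)), dtype=np.int64)
    if n_vertices is not None and idx.size and (idx.min() < 0 or idx.max() >= n_vertices):
        bad = idx[(idx < 0) | (idx >= n_vertices)][0]
        raise ValueError(f"{path}: mask index {bad} out of range "
                         f"for {n_vertices} vertices")
    return idx


def save_mask_text(path: str, indices: Sequence[int]) -> None:
    with open(path, "w") as fh:
        fh.write("# cortexcf vertex mask; index-base: 0\n")
        for i in indices:
            fh.write(f"{int(i)}\n")


# ---------------------------------------------------------------- HDF5


def save_series_h5(path: str, runs: Sequence[RunSeries], **meta) -> None:
    """Persist multi-run series as ``run_000``... datasets with provenance."""
    with h5py.File(path, "w") as f:
        for k, v in _provenance(**meta).items():
            f.attrs[k] = v
        for i, run in enumerate(runs):
            d = f.create_dataset(f"run_{i:03d}", data=run.data)
            d.attrs["dt"] = run.dt
            d.attrs["run_id"] = run.run_id or f"run_{i:03d}"


def load_series_h5(path: str) -> List[RunSeries]:
    runs = []
    with h5py.File(path, "r") as f:
        for name in sorted(k for k in f if k.startswith("run_")):
            d = f[name]
            runs.append(RunSeries(d[()], dt=float(d.attrs.get("dt", 1.0)),
                                  run_id=str(d.attrs.get("run_id", name))))
    if not runs:
        raise ValueError(f"{path}: no run_* datasets found")
    return runs


def save_basis_h5(path: str, basis: LaplaceBasis, **meta) -> None:
    with h5py.File(path, "w") as f:
        for k, v in _provenance(**meta).items():
            f.attrs[k] = v
        f.create_dataset("eigenfunctions", data=basis.eigenfunctions)
        f.create_dataset("eigenvalues", data=basis.eigenvalues)
        f.create_dataset("mass", data=basis.mass)
        f.attrs["includes_constant_mode"] = basis.includes_constant_mode


def load_basis_h5(path: str) -> LaplaceBasis:
    with h5py.File(path, "r") as f:
        return LaplaceBasis(
            eigenfunctions=f["eigenfunctions"][()],
            eigenvalues=f["eigenvalues"][()],
            mass=f["mass"][()],
            includes_constant_mode=bool(f.attrs["includes_constant_mode"]),
        )
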