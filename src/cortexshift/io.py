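"""Reading and writing surfaces, metrics and masks.

GIFTI (``.surf.gii`` / ``.func.gii`` / ``.shape.gii``) via nibabel is the
primary format; a plain-text fallback is provided for surfaces
(header line ``"V F"``, then V ``x y z`` lines, then F ``i j k`` lines,
0-based) and a two-column ``vertex,value`` CSV for metrics.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import gifti

from .meshcore import MetricMap, SurfaceMesh

__all__ = [
    "load_surface",
    "save_surface",
    "load_metric",
    "save_metric",
]


def save_surface(mesh: SurfaceMesh, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".gii":
        da_v = gifti.GiftiDataArray(
            mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
        )
        da_f = gifti.GiftiDataArray(mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE")
        img = gifti.GiftiImage(darrays=[da_v, da_f])
        nib.save(img, str(path))
    else:
        with open(path, "w") as fh:
            fh.write(f"{mesh.n_vertices} {mesh.n_faces}\n")
            for x, y, z in mesh.vertices:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
            for i, j, k in mesh.faces:
                fh.write(f"{i} {j} {k}\n")


def load_surface(path: str | Path, name: str | None = None) -> SurfaceMesh:
    path = Path(path)
    if path.suffix == ".gii":
        img = nib.load(str(path))
        verts = faces = None
        for da in img.darrays:
            if da.intent == gifti.gifti.intent_codes["NIFTI_INTENT_POINTSET"]:
                verts = np.asarray(da.data, dtype=np.float64)
            elif da.intent == gifti.gifti.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                faces = np.asarray(da.data, dtype=np.int64)
        if verts is None or faces is None:
            raise ValueError(f"{path} lacks POINTSET/TRIANGLE arrays")
        return SurfaceMesh(verts, faces, name or path.stem)
    with open(path) as fh:
        nv, nf = map(int, fh.readline().split())
        verts = np.loadtxt(fh, max_rows=nv, ndmin=2)
        faces = np.loadtxt(fh, max_rows=nf, dtype=np.int64, ndmin=2)
    return SurfaceMesh(verts, faces, name or path.stem)


def save_metric(metric: MetricMap | np.ndarray, path: str | Path) -> None:
    path = Path(path)
    values = metric.values if isinstance(metric, MetricMap) else np.asarray(metric, dtype=float)
    if path.suffix == ".gii":
        da = gifti.GiftiDataArray(values.astype(np.float32), intent="NIFTI_INTENT_NONE")
        nib.save(gifti.GiftiImage(darrays=[da]), str(path))
    else:
        with open(path, "w") as fh:
            fh.write("vertex,value\n")
            for i, v in enumerate(values):
                fh.write(f"{i},{v:.9g}\n")


def load_metric(path: str | Path, mesh_name: str = "surface", units: str = "") -> MetricMap:
    path = Path(path)
    if path.suffix == ".gii":
        img = nib.load(str(path))
        values = np.asarray(img.darrays[0].data, dtype=np.float64)
        return MetricMap(values, mesh_name, units)
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    order = np.argsort(data[:, 0])
    return MetricMap(data[order, 1], mesh_name, units)
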