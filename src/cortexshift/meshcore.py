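"""Triangulated cortical-surface data structures and geometric primitives.

The midthickness surface at one timepoint is represented as a triangle mesh
(:class:`SurfaceMesh`); every per-vertex quantity (thickness in mm, vertex
area in mm^2, log2 change, test statistics, p-values) is a
:class:`MetricMap`.  This module provides the geometry layer the rest of the
pipeline is built on: face/vertex areas with the one-third-triangle
attribution rule, global summaries over a cortex mask, graph geodesic
distances, truncated-Gaussian geodesic smoothing, and an icosahedron-based
toy parcellation with a designated medial-wall region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra

__all__ = [
    "SurfaceMesh",
    "MetricMap",
    "VertexMask",
    "Parcellation",
    "SmoothingParams",
    "face_areas",
    "vertex_areas",
    "total_area",
    "mean_thickness",
    "estimate_volume",
    "geodesic_distances",
    "smooth_metric",
    "build_parcellation",
    "medial_wall_mask",
    "fwhm_to_sigma",
]

_DEGENERATE_AREA = 1e-12


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full-width-at-half-maximum to its sigma."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SurfaceMesh:
    """A triangulated 2-manifold surface.

    Parameters
    ----------
    vertices
        ``(V, 3)`` float array of coordinates in mm.
    faces
        ``(F, 3)`` integer array of vertex indices with consistent
        (outward) winding.
    name
        Human-readable label, e.g. ``"lh.baseline"``.
    base_face
        Optional ``(F,)`` array mapping each face to one of the 20 faces of
        the base icosahedron it descends from.  Set by the icosphere
        builders; required by :func:`build_parcellation`.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = "surface"
    base_face: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        # each undirected edge may be shared by at most two faces
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        if counts.size and counts.max() > 2:
            raise ValueError("non-manifold mesh: an edge is shared by more than two faces")
        self._cache: dict = {}

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an ``(E, 2)`` index array."""
        if "edges" not in self._cache:
            e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
            self._cache["edges"] = np.unique(e, axis=0)
        return self._cache["edges"]

    def edge_length_graph(self) -> sparse.csr_matrix:
        """Sparse symmetric graph with Euclidean edge lengths as weights."""
        if "graph" not in self._cache:
            e = self.edges()
            w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
            g = sparse.coo_matrix(
                (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
                shape=(self.n_vertices, self.n_vertices),
            )
            self._cache["graph"] = g.tocsr()
        return self._cache["graph"]

    def vertex_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR-style (indptr, face_indices) giving the faces incident to each vertex."""
        if "vf" not in self._cache:
            v = self.faces.ravel()
            f = np.repeat(np.arange(self.n_faces), 3)
            order = np.argsort(v, kind="stable")
            counts = np.bincount(v, minlength=self.n_vertices)
            indptr = np.concatenate([[0], np.cumsum(counts)])
            self._cache["vf"] = (indptr, f[order])
        return self._cache["vf"]


@dataclass
class MetricMap:
    """One scalar per vertex on a named mesh."""

    values: np.ndarray
    mesh_name: str = "surface"
    units: str = ""  # mm | mm^2 | log2-ratio | statistic | p

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("MetricMap values must be 1-D")
        if self.units == "p" and self.values.size:
            v = self.values[np.isfinite(self.values)]
            if v.size and (v.min() <= 0 or v.max() > 1):
                raise ValueError("p-value maps must lie in (0, 1]")


@dataclass
class VertexMask:
    """Boolean per-vertex mask; ``role`` is ``"cortex"`` or ``"medial_wall"``."""

    values: np.ndarray
    role: str = "cortex"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)


@dataclass
class Parcellation:
    """Integer ROI label per vertex plus a label table."""

    roi_label: np.ndarray
    roi_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.roi_label = np.asarray(self.roi_label, dtype=np.int64)


@dataclass
class SmoothingParams:
    """Truncated geodesic Gaussian kernel parameters.

    fwhm is in mm; the kernel is truncated at ``truncation_radius`` multiples
    of sigma (sigma = fwhm / (2 sqrt(2 ln 2))).
    """

    fwhm: float = 20.0
    truncation_radius: float = 3.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")

    @property
    def sigma(self) -> float:
        return fwhm_to_sigma(self.fwhm)


# ---------------------------------------------------------------------------
# areas


def face_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Per-face area in mm^2 (half the cross-product norm of two edges)."""
    v = mesh.vertices
    f = mesh.faces
    a = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    areas = 0.5 * np.linalg.norm(a, axis=1)
    if np.any(areas <= _DEGENERATE_AREA):
        warnings.warn("mesh contains degenerate (zero-area) faces", stacklevel=2)
    return areas


def vertex_areas(mesh: SurfaceMesh) -> MetricMap:
    """Vertex areas: each vertex receives one third of each incident triangle."""
    fa = face_areas(mesh)
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, mesh.faces.ravel(), np.repeat(fa / 3.0, 3))
    if np.any(np.bincount(mesh.faces.ravel(), minlength=mesh.n_vertices) == 0):
        warnings.warn("mesh contains isolated vertices (area 0)", stacklevel=2)
    return MetricMap(out, mesh.name, "mm^2")


def _as_mask(mask, n: int) -> np.ndarray:
    if mask is None:
        return np.ones(n, dtype=bool)
    if isinstance(mask, VertexMask):
        mask = mask.values
    m = np.asarray(mask, dtype=bool)
    if m.shape != (n,):
        raise ValueError("mask length does not match vertex count")
    return m


def total_area(mesh: SurfaceMesh, mask=None) -> float:
    """Sum of vertex areas over the masked (cortex) vertices, in mm^2."""
    m = _as_mask(mask, mesh.n_vertices)
    if not m.any():
        raise ValueError("empty mask")
    return float(vertex_areas(mesh).values[m].sum())


def mean_thickness(thickness: MetricMap, mask=None, *, area_weights: np.ndarray | None = None) -> float:
    """Mean thickness over masked vertices.

    The default is the unweighted vertex mean; pass per-vertex
    ``area_weights`` for an area-weighted alternative.
    """
    m = _as_mask(mask, thickness.values.size)
    if not m.any():
        raise ValueError("empty mask")
    if area_weights is None:
        return float(thickness.values[m].mean())
    w = np.asarray(area_weights, dtype=float)[m]
    return float(np.average(thickness.values[m], weights=w))


def estimate_volume(mesh: SurfaceMesh, thickness: MetricMap, mask=None) -> float:
    """Total cortical volume estimate: mean thickness x total surface area."""
    return mean_thickness(thickness, mask) * total_area(mesh, mask)


# ---------------------------------------------------------------------------
# geodesics and smoothing


def geodesic_distances(
    mesh: SurfaceMesh, source_vertex: int, radius: float = np.inf
) -> dict[int, float]:
    """Graph-geodesic distances (mm) from a source vertex to vertices within radius.

    Shortest paths along mesh edges with Euclidean edge lengths; an
    approximation to the true polyhedral geodesic that is adequate when used
    with smoothing kernels much wider than the edge length.
    """
    d = dijkstra(mesh.edge_length_graph(), indices=source_vertex, limit=radius)
    reached = np.flatnonzero(np.isfinite(d))
    return {int(i): float(d[i]) for i in reached if d[i] <= radius}


def _smoothing_operator(
    mesh: SurfaceMesh, params: SmoothingParams, mask: np.ndarray
) -> sparse.csr_matrix:
    """Row-normalized truncated-Gaussian kernel matrix on masked vertices."""
    sigma = params.sigma
    cutoff = params.truncation_radius * sigma
    graph = mesh.edge_length_graph()
    idx = np.flatnonzero(mask)
    rows, cols, vals = [], [], []
    # chunk the multi-source Dijkstra to bound memory on large meshes
    chunk = max(1, int(2e7) // max(mesh.n_vertices, 1))
    for s in range(0, idx.size, chunk):
        src = idx[s : s + chunk]
        d = dijkstra(graph, indices=src, limit=cutoff)
        r, c = np.nonzero(np.isfinite(d))
        w = np.exp(-0.5 * (d[r, c] / sigma) ** 2)
        keep = mask[c]
        rows.append(src[r[keep]])
        cols.append(c[keep])
        vals.append(w[keep])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    k = sparse.coo_matrix((vals, (rows, cols)), shape=(mesh.n_vertices,) * 2).tocsr()
    norm = np.asarray(k.sum(axis=1)).ravel()
    norm[norm == 0] = 1.0
    return sparse.diags(1.0 / norm) @ k


def smooth_metric(
    metric: MetricMap,
    mesh: SurfaceMesh,
    params: SmoothingParams,
    mask=None,
) -> MetricMap:
    """Geodesic Gaussian smoothing of a metric map.

    The kernel is a Gaussian in graph-geodesic distance, truncated at
    ``truncation_radius`` sigma, with per-vertex weight normalization so that
    constant maps are preserved exactly.  Vertices outside the mask are
    excluded from both the input support and the normalization, and returned
    unchanged.
    """
    m = _as_mask(mask, mesh.n_vertices)
    if metric.values.size != mesh.n_vertices:
        raise ValueError("metric length does not match mesh")
    mean_edge = float(
        np.mean(
            np.linalg.norm(
                mesh.vertices[mesh.edges()[:, 0]] - mesh.vertices[mesh.edges()[:, 1]], axis=1
            )
        )
    )
    if params.fwhm < mean_edge:
        warnings.warn(
            "smoothing FWHM is below the mean edge length; kernel is near-delta",
            stacklevel=2,
        )
    key = ("smooth_op", params.fwhm, params.truncation_radius, m.tobytes())
    if key not in mesh._cache:
        mesh._cache[key] = _smoothing_operator(mesh, params, m)
    op = mesh._cache[key]
    out = metric.values.copy()
    sm = op @ np.where(m, metric.values, 0.0)
    out[m] = sm[m]
    return MetricMap(out, metric.mesh_name, metric.units)


# ---------------------------------------------------------------------------
# parcellation


def build_parcellation(mesh: SurfaceMesh, roi_names: dict[int, str] | None = None) -> Parcellation:
    """Partition an icosphere-derived mesh into the 20 base-icosahedron parcels.

    Each face of the level-0 icosahedron defines one ROI; a vertex is
    assigned the lowest base-face id among its incident faces.  This is a
    structural stand-in for a gyral atlas, giving contiguous patches of
    roughly equal size for ROI-level analyses.
    """
    if mesh.base_face is None:
        raise ValueError("mesh is not subdivision-structured (no base-face lineage)")
    labels = np.full(mesh.n_vertices, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(labels, mesh.faces.ravel(), np.repeat(mesh.base_face, 3))
    if roi_names is None:
        roi_names = {int(i): f"parcel_{int(i):02d}" for i in np.unique(labels)}
    return Parcellation(labels, roi_names)


def medial_wall_mask(parcellation: Parcellation, wall_roi: int = 0) -> tuple[VertexMask, VertexMask]:
    """Split a parcellation into (medial-wall, cortex) masks.

    The designated ``wall_roi`` parcel plays the role of the medial wall and
    is excluded from every downstream computation.
    """
    wall = parcellation.roi_label == wall_roi
    return VertexMask(wall, "medial_wall"), VertexMask(~wall, "cortex")


def parcel_is_contiguous(mesh: SurfaceMesh, parcellation: Parcellation, roi: int) -> bool:
    """True if the given ROI forms a single edge-connected patch."""
    m = parcellation.roi_label == roi
    idx = np.flatnonzero(m)
    if idx.size == 0:
        return True
    e = mesh.edges()
    keep = m[e[:, 0]] & m[e[:, 1]]
    sub = e[keep]
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[idx] = np.arange(idx.size)
    g = sparse.coo_matrix(
        (np.ones(2 * len(sub)), (np.r_[remap[sub[:, 0]], remap[sub[:, 1]]],
                                 np.r_[remap[sub[:, 1]], remap[sub[:, 0]]])),
        shape=(idx.size, idx.size),
    )
    n, _ = connected_components(g.tocsr(), directed=False)
    return n == 1
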