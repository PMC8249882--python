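"""Spherical mesh utilities shared by the generator and the registration.

Provides recursive icosahedron subdivision (with face lineage back to the 20
base faces), fast barycentric point location on spherical triangulations,
and band-limited random scalar fields built from real spherical harmonics.
"""

from __future__ import annotations

import hashlib
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import sph_harm_y

__all__ = [
    "icosphere",
    "SphereLocator",
    "sh_basis",
    "random_band_limited_field",
]

_PHI = (1.0 + np.sqrt(5.0)) / 2.0


def _base_icosahedron() -> tuple[np.ndarray, np.ndarray]:
    v = np.array(
        [
            [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
            [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
            [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
        ],
        dtype=np.float64,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    # enforce outward winding: det[a, b, c] > 0
    det = np.einsum("ij,ij->i", np.cross(v[f[:, 0]], v[f[:, 1]]), v[f[:, 2]])
    flip = det < 0
    f[flip] = f[flip][:, [0, 2, 1]]
    return v, f


@lru_cache(maxsize=16)
def _icosphere_cached(level: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    verts, faces = _base_icosahedron()
    lineage = np.arange(20, dtype=np.int64)
    for _ in range(level):
        edge_mid: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            if key not in edge_mid:
                m = vlist[i] + vlist[j]
                m = m / np.linalg.norm(m)
                edge_mid[key] = len(vlist)
                vlist.append(m)
            return edge_mid[key]

        new_faces = np.empty((4 * len(faces), 3), dtype=np.int64)
        new_lineage = np.repeat(lineage, 4)
        for k, (a, b, c) in enumerate(faces):
            ab = midpoint(a, b)
            bc = midpoint(b, c)
            ca = midpoint(c, a)
            new_faces[4 * k : 4 * k + 4] = [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = new_faces
        lineage = new_lineage
    verts.setflags(write=False)
    faces.setflags(write=False)
    lineage.setflags(write=False)
    return verts, faces, lineage


def icosphere(level: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit icosphere by recursive 4-fold subdivision.

    Returns ``(vertices, faces, base_face)`` where ``base_face`` maps each
    face to the base-icosahedron face it descends from.
    ``V = 10 * 4**level + 2``.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    if level > 7:
        raise ValueError("refusing icosphere level > 7 (memory guard)")
    v, f, l = _icosphere_cached(level)
    return v.copy(), f.copy(), l.copy()


class SphereLocator:
    """Barycentric point location on a spherical triangulation.

    For a query direction q, finds the triangle whose central (gnomonic)
    projection contains q and the convex weights w solving
    ``w0*a + w1*b + w2*c ∝ q``.  Candidate faces come from the nearest
    vertex's incident faces, with a brute-force fallback for the rare
    queries that miss (numerical ties on edges).
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=np.float64)
        self.faces = np.asarray(faces, dtype=np.int64)
        self._tree = cKDTree(self.vertices)
        # per-face inverse of [a b c]^T for solving barycentric systems
        tri = self.vertices[self.faces]  # (F, 3, 3): rows are a, b, c
        self._inv = np.linalg.inv(np.transpose(tri, (0, 2, 1)))  # inverse of column matrix
        # padded incident-face table
        nv = len(self.vertices)
        counts = np.bincount(self.faces.ravel(), minlength=nv)
        maxdeg = int(counts.max())
        table = np.full((nv, maxdeg), -1, dtype=np.int64)
        fill = np.zeros(nv, dtype=np.int64)
        for fi, face in enumerate(self.faces):
            for v in face:
                table[v, fill[v]] = fi
                fill[v] += 1
        self._vf = table

    def locate(self, points: np.ndarray, tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
        """Return (face_index, weights) for each query point (unit vectors)."""
        q = np.asarray(points, dtype=np.float64)
        single = q.ndim == 1
        q = np.atleast_2d(q)
        n = len(q)
        _, nearest = self._tree.query(q, k=1)
        cand = self._vf[nearest]  # (n, maxdeg)
        valid = cand >= 0
        w = np.einsum("nkij,nj->nki", self._inv[np.where(valid, cand, 0)], q)
        minw = np.where(valid, w.min(axis=2), -np.inf)
        best = np.argmax(minw, axis=1)
        rows = np.arange(n)
        face = cand[rows, best]
        weights = w[rows, best]
        ok = minw[rows, best] >= -tol
        if not ok.all():
            # brute force over all faces for the stragglers
            bad = np.flatnonzero(~ok)
            wb = np.einsum("fij,nj->nfi", self._inv, q[bad])
            mb = wb.min(axis=2)
            bf = np.argmax(mb, axis=1)
            face[bad] = bf
            weights[bad] = wb[np.arange(len(bad)), bf]
        s = weights.sum(axis=1, keepdims=True)
        weights = weights / s
        np.clip(weights, 0.0, None, out=weights)
        weights /= weights.sum(axis=1, keepdims=True)
        if single:
            return face[0], weights[0]
        return face, weights

    def interpolate(self, vertex_values: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Barycentric interpolation of per-vertex values at query directions."""
        face, w = self.locate(points)
        vals = np.asarray(vertex_values, dtype=np.float64)
        corner = vals[self.faces[face]]  # (n, 3) or (n, 3, d)
        if corner.ndim == 3:
            return np.einsum("nkd,nk->nd", corner, w)
        return np.einsum("nk,nk->n", corner, w)


# ---------------------------------------------------------------------------
# band-limited random fields

_BASIS_CACHE: dict[tuple[str, int, int], np.ndarray] = {}


def sh_basis(points: np.ndarray, lmin: int, lmax: int) -> np.ndarray:
    """Real spherical-harmonic basis matrix at unit directions.

    Returns an ``(N, K)`` matrix whose columns are the real harmonics
    Y_lm for l in [lmin, lmax], m in [-l, l], orthonormal on the sphere.
    Cached per (points, degree-range).
    """
    pts = np.ascontiguousarray(points, dtype=np.float64)
    key = (hashlib.sha1(pts.tobytes()).hexdigest(), lmin, lmax)
    if key in _BASIS_CACHE:
        return _BASIS_CACHE[key]
    theta = np.arccos(np.clip(pts[:, 2], -1.0, 1.0))
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    cols = []
    for l in range(lmin, lmax + 1):
        for m in range(0, l + 1):
            y = sph_harm_y(l, m, theta, phi)
            if m == 0:
                cols.append(np.real(y))
            else:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * np.real(y))
                cols.append(np.sqrt(2.0) * (-1.0) ** m * np.imag(y))
    basis = np.column_stack(cols)
    if len(_BASIS_CACHE) > 32:
        _BASIS_CACHE.clear()
    _BASIS_CACHE[key] = basis
    return basis


def random_band_limited_field(
    points: np.ndarray,
    rng: np.random.Generator,
    lmin: int = 2,
    lmax: int = 8,
    sd: float = 1.0,
) -> np.ndarray:
    """Smooth Gaussian random field on the sphere with pointwise SD ``sd``.

    Coefficients are i.i.d. normal over the chosen degree band, giving an
    isotropic field; by the addition theorem the pointwise variance is
    ``sum_l (2l+1) / (4 pi)``, which is normalized away.
    """
    basis = sh_basis(points, lmin, lmax)
    coeff = rng.standard_normal(basis.shape[1])
    var = sum((2 * l + 1) for l in range(lmin, lmax + 1)) / (4.0 * np.pi)
    return basis @ coeff * (sd / np.sqrt(var))
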