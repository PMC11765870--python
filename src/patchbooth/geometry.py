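"""Tetrahedral lattice geometry shared by the tabulated color space and
the printer's backward model.

A hexahedral lattice of paired coordinates (a point in a *source* space
plus its image in a *target* space) is cut into tetrahedra — six per
cube, all sharing the cube's main diagonal — giving a piecewise-linear,
invertible map: locate the tetrahedron containing a source-space query,
then carry its barycentric weights over to the target coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["CUBE_TETRAHEDRA", "split_cube", "TetraMesh", "ContainmentError"]


class ContainmentError(ValueError):
    """Raised when a query point lies outside every tetrahedron."""


def _corner_index(i: int, j: int, k: int) -> int:
    return 4 * i + 2 * j + k


def _build_cube_tetrahedra() -> np.ndarray:
    # Six tetrahedra around the main diagonal (0,0,0)-(1,1,1): one per
    # permutation of the axis order, walking edge by edge to the far corner.
    from itertools import permutations

    tets = []
    for perm in permutations(range(3)):
        steps = [np.zeros(3, dtype=int)]
        acc = np.zeros(3, dtype=int)
        for ax in perm[:2]:
            acc = acc.copy()
            acc[ax] = 1
            steps.append(acc)
        steps.append(np.ones(3, dtype=int))
        tets.append([_corner_index(*s) for s in steps])
    return np.asarray(tets, dtype=int)


#: (6, 4) corner indices of the canonical cube split; corner c = 4i+2j+k.
CUBE_TETRAHEDRA = _build_cube_tetrahedra()


def split_cube(corners) -> np.ndarray:
    """Split one cube (8 corner points, indexed c = 4i+2j+k) into the six
    canonical tetrahedra sharing the main diagonal.

    Returns an array of shape (6, 4, 3). Raises on a degenerate cube
    (zero total volume).
    """
    corners = np.asarray(corners, dtype=float)
    if corners.shape != (8, 3):
        raise ValueError("expected 8 corner points of shape (8, 3)")
    tets = corners[CUBE_TETRAHEDRA]
    vols = np.abs(np.linalg.det(tets[:, 1:] - tets[:, :1])) / 6.0
    if np.sum(vols) <= 0:
        raise ValueError("degenerate cube: zero volume")
    return tets


class TetraMesh:
    """Piecewise-linear map between two spaces over a tetrahedralized lattice.

    Parameters
    ----------
    source : ndarray (ni, nj, nk, 3)
        Lattice vertex coordinates in the space queries live in.
    target : ndarray (ni, nj, nk, d)
        Paired coordinates carried by the interpolation.
    """

    def __init__(self, source: np.ndarray, target: np.ndarray):
        source = np.asarray(source, dtype=float)
        target = np.asarray(target, dtype=float)
        if source.ndim != 4 or source.shape[-1] != 3:
            raise ValueError("source must have shape (ni, nj, nk, 3)")
        if target.shape[:3] != source.shape[:3]:
            raise ValueError("target lattice shape must match source")
        ni, nj, nk = source.shape[:3]
        if min(ni, nj, nk) < 2:
            raise ValueError("lattice needs at least 2 nodes per axis")
        self.lattice_shape = (ni, nj, nk)
        verts_src = source.reshape(-1, 3)
        verts_tgt = target.reshape(-1, target.shape[-1])

        # global vertex index of lattice node (i, j, k)
        def gidx(i, j, k):
            return (i * nj + j) * nk + k

        ii, jj, kk = np.meshgrid(
            np.arange(ni - 1), np.arange(nj - 1), np.arange(nk - 1), indexing="ij"
        )
        cells = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        corner_offsets = np.array(
            [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=int
        )
        corners = cells[:, None, :] + corner_offsets[None, :, :]  # (ncell, 8, 3)
        corner_gidx = gidx(corners[..., 0], corners[..., 1], corners[..., 2])
        # (ncell, 6, 4) -> (ntet, 4), cells in C scan order then split order
        self.tetra = corner_gidx[:, CUBE_TETRAHEDRA].reshape(-1, 4)

        self.verts_src = verts_src
        self.verts_tgt = verts_tgt
        v = verts_src[self.tetra]                       # (ntet, 4, 3)
        self._v0 = v[:, 0]
        M = np.swapaxes(v[:, 1:] - v[:, :1], 1, 2)      # columns are edges
        self._det = np.linalg.det(M)
        ok = np.abs(self._det) > 1e-300
        Minv = np.zeros_like(M)
        Minv[ok] = np.linalg.inv(M[ok])
        self._Minv = Minv
        self._centroids = v.mean(axis=1)
        self._tree = cKDTree(self._centroids)
        self._bbox_lo = verts_src.min(axis=0)
        self._bbox_hi = verts_src.max(axis=0)
        scale = float(np.max(self._bbox_hi - self._bbox_lo))
        self._tol = 1e-9 * max(scale, 1.0)

    @property
    def n_tetrahedra(self) -> int:
        return self.tetra.shape[0]

    def volume(self) -> float:
        """Total source-space volume of the mesh."""
        return float(np.sum(np.abs(self._det)) / 6.0)

    def _bary(self, tets: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Barycentric coordinates (t1, t2, t3) of p in each tetra of `tets`."""
        rhs = p[None, :] - self._v0[tets]
        return np.einsum("nij,nj->ni", self._Minv[tets], rhs)

    def _locate_one(self, p: np.ndarray, tol: float):
        lo, hi = self._bbox_lo, self._bbox_hi
        if np.any(p < lo - tol) or np.any(p > hi + tol):
            return None
        n = self.n_tetrahedra
        for k in (8, 64, 512):
            k = min(k, n)
            _, cand = self._tree.query(p, k=k)
            cand = np.atleast_1d(cand)
            t = self._bary(cand, p)
            inside = np.all(t >= -tol, axis=1) & (t.sum(axis=1) <= 1.0 + tol)
            if np.any(inside):
                # boundary ties: first containing tetra in cell-scan order
                hits = cand[inside]
                best = int(hits[np.argmin(hits)])
                return best, self._bary(np.array([best]), p)[0]
            if k == n:
                break
        # exhaustive fallback for rare KD-tree misses
        t = self._bary(np.arange(n), p)
        inside = np.all(t >= -tol, axis=1) & (t.sum(axis=1) <= 1.0 + tol)
        if np.any(inside):
            best = int(np.flatnonzero(inside)[0])
            return best, t[best]
        return None

    def locate(self, points, tol: float | None = None):
        """Locate each point; returns (tetra_index, bary4) with index -1 and
        NaN weights for points outside the mesh."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        tol = self._tol if tol is None else tol
        idx = np.full(len(pts), -1, dtype=int)
        bary = np.full((len(pts), 4), np.nan)
        for m, p in enumerate(pts):
            hit = self._locate_one(p, tol)
            if hit is not None:
                idx[m] = hit[0]
                t = hit[1]
                bary[m] = np.concatenate([[1.0 - t.sum()], t])
        return idx, bary

    def contains(self, points, tol: float = 1e-8) -> np.ndarray:
        """Membership test; boundary points count as inside."""
        idx, _ = self.locate(points, tol=tol)
        out = idx >= 0
        return out if np.ndim(points) > 1 else bool(out[0])

    def interpolate(self, points) -> np.ndarray:
        """Map source-space points to target space (barycentric transfer).

        Raises :class:`ContainmentError` if any point is outside.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx, bary = self.locate(pts)
        if np.any(idx < 0):
            bad = pts[idx < 0][0]
            raise ContainmentError(f"point {bad} outside tetrahedral mesh")
        tgt = self.verts_tgt[self.tetra[idx]]           # (m, 4, d)
        out = np.einsum("mi,mid->md", bary, tgt)
        return out if np.ndim(points) > 1 else out[0]

    def boundary_faces(self) -> np.ndarray:
        """Outward shell of the lattice as triangles (n_faces, 3) of vertex ids."""
        ni, nj, nk = self.lattice_shape

        def gidx(i, j, k):
            return (i * nj + j) * nk + k

        quads = []
        grids = {
            0: [(0, "lo"), (ni - 1, "hi")],
            1: [(0, "lo"), (nj - 1, "hi")],
            2: [(0, "lo"), (nk - 1, "hi")],
        }
        dims = {0: (nj, nk), 1: (ni, nk), 2: (ni, nj)}
        for ax, faces in grids.items():
            d1, d2 = dims[ax]
            for fixed, _ in faces:
                for a in range(d1 - 1):
                    for b in range(d2 - 1):
                        c = []
                        for da, db in ((0, 0), (1, 0), (1, 1), (0, 1)):
                            if ax == 0:
                                c.append(gidx(fixed, a + da, b + db))
                            elif ax == 1:
                                c.append(gidx(a + da, fixed, b + db))
                            else:
                                c.append(gidx(a + da, b + db, fixed))
                        quads.append(c)
        quads = np.asarray(quads, dtype=int)
        return np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]], axis=0)
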