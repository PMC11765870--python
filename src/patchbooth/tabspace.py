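"""A CIEDE2000-uniform tabulated color space ("tab space").

CIEDE2000 is not Euclidean, which makes equidistant sampling of CIELAB
awkward. The remedy used here is a lattice of Lab nodes, centered on
Lab (50, 0, 0), constructed so that the CIEDE2000 distance between any
two axis neighbors equals a fixed ``step_de`` (0.5 by default). In the
continuous index coordinates of that lattice — "tab coordinates" —
Euclidean distance multiplied by ``step_de`` approximates CIEDE2000
locally, so geometric constructions (close packings, isotropic random
offsets) can be done with plain Euclidean geometry.

Construction: nodes are seeded from a separable marching initialization
(1-D CIEDE2000 marching along the lightness axis, radial marching in
the chroma plane) and then relaxed by gradient descent on weighted
squared distance residuals with the center node pinned. The primary
constraints put every axis neighbor at ``step_de``; softly weighted
face-diagonal constraints at ``sqrt(2) * step_de`` suppress the shear
modes that the axis contract alone leaves free (see DIAGONAL_WEIGHT).
The system remains under-determined enough for the axis residuals to be
driven essentially to zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import brentq

from .colorimetry import delta_e00
from .geometry import ContainmentError, TetraMesh

__all__ = [
    "TabGrid",
    "CoverageError",
    "build_tab_grid",
    "save_tab_grid",
    "load_tab_grid",
    "tab_to_lab",
    "lab_to_tab",
]


class CoverageError(ValueError):
    """A Lab color (or tab coordinate) lies outside the grid's coverage."""


@dataclass
class TabGrid:
    """Lattice of Lab nodes with fixed CIEDE2000 neighbor spacing.

    ``nodes[i - lo[0], j - lo[1], k - lo[2]]`` is the Lab triple of the
    node at integer offset (i, j, k); offset (0, 0, 0) is the center.
    """

    step_de: float
    center: np.ndarray
    lo: np.ndarray            # minimal integer offsets per axis
    nodes: np.ndarray         # (ni, nj, nk, 3) Lab
    _mesh: TetraMesh | None = field(default=None, repr=False, compare=False)

    @property
    def hi(self) -> np.ndarray:
        return self.lo + np.array(self.nodes.shape[:3]) - 1

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) inclusive integer offset ranges per axis."""
        return self.lo.copy(), self.hi

    def node(self, i: int, j: int, k: int) -> np.ndarray:
        idx = np.array([i, j, k]) - self.lo
        if np.any(idx < 0) or np.any(idx >= self.nodes.shape[:3]):
            raise CoverageError(f"offset ({i},{j},{k}) outside extent")
        return self.nodes[tuple(idx)]

    def in_extent(self, coords) -> np.ndarray:
        c = np.atleast_2d(np.asarray(coords, dtype=float))
        ok = np.all((c >= self.lo - 1e-9) & (c <= self.hi + 1e-9), axis=1)
        return ok if np.ndim(coords) > 1 else bool(ok[0])

    def to_de_units(self, tab_distance) -> np.ndarray:
        """Convert a tab-space Euclidean distance to CIEDE2000 units."""
        return np.asarray(tab_distance, dtype=float) * self.step_de

    def mesh(self) -> TetraMesh:
        """Lab -> tab tetrahedral mesh (built lazily, cached)."""
        if self._mesh is None:
            ni, nj, nk = self.nodes.shape[:3]
            ii, jj, kk = np.meshgrid(
                np.arange(ni) + self.lo[0],
                np.arange(nj) + self.lo[1],
                np.arange(nk) + self.lo[2],
                indexing="ij",
            )
            tab = np.stack([ii, jj, kk], axis=-1).astype(float)
            self._mesh = TetraMesh(self.nodes, tab)
        return self._mesh

    def neighbor_deltas(self) -> np.ndarray:
        """CIEDE2000 of every axis-adjacent node pair (all axes pooled)."""
        out = []
        for ax in range(3):
            a = np.moveaxis(self.nodes, ax, 0)
            out.append(delta_e00(a[:-1], a[1:]).ravel())
        return np.concatenate(out)


# ---------------------------------------------------------------------------
# Construction

def _march(start_lab, direction, n_steps, step_de, metric):
    """March n_steps from start_lab along a Lab axis direction so each
    consecutive pair is metric-distance step_de apart."""
    pts = [np.asarray(start_lab, dtype=float)]
    d = np.asarray(direction, dtype=float)
    for _ in range(n_steps):
        p = pts[-1]

        def f(t):
            return float(metric(p, p + t * d)) - step_de

        hi = 3.0 * step_de
        while f(hi) < 0:
            hi *= 2.0
        t = brentq(f, 1e-12, hi, xtol=1e-12)
        pts.append(p + t * d)
    return np.asarray(pts)


#: Weight of the face-diagonal constraints relative to the axis-neighbor
#: constraints during relaxation. The axis contract alone is under-
#: determined: lattice *shear* changes diagonal distances while leaving
#: all six neighbor distances intact, which silently destroys the
#: Euclidean <-> CIEDE2000 equivalence for oblique pairs. Softly pinning
#: face diagonals at sqrt(2) x step removes the shear modes.
DIAGONAL_WEIGHT = 0.3


def _edge_index_arrays(shape):
    """(edges, targets_in_steps, weights): axis neighbors at distance 1
    (weight 1) plus face diagonals at sqrt(2) (weight DIAGONAL_WEIGHT)."""
    ni, nj, nk = shape
    idx = np.arange(ni * nj * nk).reshape(ni, nj, nk)
    pairs, targets, weights = [], [], []
    for ax in range(3):
        a = np.moveaxis(idx, ax, 0)
        e = np.stack([a[:-1].ravel(), a[1:].ravel()], axis=1)
        pairs.append(e)
        targets.append(np.ones(len(e)))
        weights.append(np.ones(len(e)))
    sqrt2 = np.sqrt(2.0)
    for d1 in range(3):
        for d2 in range(d1 + 1, 3):
            for s in (1, -1):
                off = np.zeros(3, dtype=int)
                off[d1] = 1
                off[d2] = s
                sl_a = [slice(None)] * 3
                sl_b = [slice(None)] * 3
                for ax, o in enumerate(off):
                    if o == 1:
                        sl_a[ax] = slice(0, -1)
                        sl_b[ax] = slice(1, None)
                    elif o == -1:
                        sl_a[ax] = slice(1, None)
                        sl_b[ax] = slice(0, -1)
                e = np.stack([idx[tuple(sl_a)].ravel(),
                              idx[tuple(sl_b)].ravel()], axis=1)
                pairs.append(e)
                targets.append(np.full(len(e), sqrt2))
                weights.append(np.full(len(e), DIAGONAL_WEIGHT))
    return (np.concatenate(pairs, axis=0), np.concatenate(targets),
            np.concatenate(weights))


def _relax(nodes_flat, edges, targets, weights, step_de, pinned, max_sweeps,
           tol_move, metric=delta_e00, lr=0.05):
    """Adam gradient descent on sum(w (metric(edge) - target)^2), center
    pinned. ``metric`` must be vectorized over (n, 3) Lab arrays."""
    x = nodes_flat.copy()
    ia, ib = edges[:, 0], edges[:, 1]
    tgt = targets * step_de
    m = np.zeros_like(x)
    v = np.zeros_like(x)
    b1, b2, eps = 0.9, 0.999, 1e-12
    h = 1e-4
    for sweep in range(1, max_sweeps + 1):
        A, B = x[ia], x[ib]
        r = metric(A, B) - tgt
        grad = np.zeros_like(x)
        for c in range(3):
            e = np.zeros(3)
            e[c] = h
            dA = (metric(A + e, B) - metric(A - e, B)) / (2 * h)
            dB = (metric(A, B + e) - metric(A, B - e)) / (2 * h)
            np.add.at(grad[:, c], ia, 2.0 * weights * r * dA)
            np.add.at(grad[:, c], ib, 2.0 * weights * r * dB)
        grad[pinned] = 0.0
        m = b1 * m + (1 - b1) * grad
        v = b2 * v + (1 - b2) * grad * grad
        mh = m / (1 - b1 ** sweep)
        vh = v / (1 - b2 ** sweep)
        move = lr * mh / (np.sqrt(vh) + eps)
        # cosine learning-rate decay sharpens the final residuals
        move *= 0.5 * (1.0 + np.cos(np.pi * min(sweep / max_sweeps, 1.0))) + 1e-3
        x -= move
        if np.max(np.abs(move)) < tol_move:
            break
    return x


def build_tab_grid(
    center=(50.0, 0.0, 0.0),
    step_de: float = 0.5,
    radius_nodes=(10, 10, 10),
    metric=None,
    max_sweeps: int = 500,
    tol_move: float = 1e-4,
) -> TabGrid:
    """Build the tabulated grid around ``center``.

    ``radius_nodes`` gives the node count on each side of the center per
    axis (lightness, a-like, b-like). If the lightness extent would leave
    L* in [0, 100], the lightness axis is truncated with a warning.
    ``metric`` is a hook for tests (defaults to CIEDE2000).
    """
    if step_de <= 0:
        raise ValueError("step_de must be positive")
    radius_nodes = np.broadcast_to(np.asarray(radius_nodes, dtype=int), (3,)).copy()
    if np.any(radius_nodes < 1):
        raise ValueError("radius_nodes must be >= 1 on every axis")
    center = np.asarray(center, dtype=float)
    # metric must be vectorized over (n, 3) Lab arrays; CIEDE2000 default
    metric = metric if metric is not None else delta_e00

    # lightness axis marching, truncated at the Lab validity bounds
    up, down = [], []
    p = center.copy()
    for _ in range(radius_nodes[0]):
        nxt = _march(p, [1.0, 0.0, 0.0], 1, step_de, metric)[1]
        if nxt[0] > 100.0 + 1e-9:
            break
        up.append(nxt)
        p = nxt
    p = center.copy()
    for _ in range(radius_nodes[0]):
        nxt = _march(p, [-1.0, 0.0, 0.0], 1, step_de, metric)[1]
        if nxt[0] < 0.0 - 1e-9:
            break
        down.append(nxt)
        p = nxt
    if len(up) < radius_nodes[0] or len(down) < radius_nodes[0]:
        warnings.warn(
            "lightness extent truncated to keep L* within [0, 100]",
            stacklevel=2,
        )
    L_axis = np.array([q[0] for q in down[::-1]] + [center[0]] + [q[0] for q in up])
    lo = np.array([-len(down), -radius_nodes[1], -radius_nodes[2]])

    # radial chroma marching along +a gives the index->radius profile
    rmax = int(np.ceil(np.hypot(radius_nodes[1], radius_nodes[2]))) + 1
    radial = _march(center, [0.0, 1.0, 0.0], rmax, step_de, metric)
    radial_dist = radial[:, 1] - center[1]

    ni = len(L_axis)
    nj = 2 * radius_nodes[1] + 1
    nk = 2 * radius_nodes[2] + 1
    jj, kk = np.meshgrid(
        np.arange(nj) + lo[1], np.arange(nk) + lo[2], indexing="ij"
    )
    rho = np.hypot(jj, kk)
    C = np.interp(rho, np.arange(rmax + 1), radial_dist)
    with np.errstate(invalid="ignore", divide="ignore"):
        ca = np.where(rho > 0, C * jj / rho, 0.0)
        cb = np.where(rho > 0, C * kk / rho, 0.0)
    nodes = np.empty((ni, nj, nk, 3))
    nodes[..., 0] = L_axis[:, None, None]
    nodes[..., 1] = center[1] + ca[None, :, :]
    nodes[..., 2] = center[2] + cb[None, :, :]

    flat = nodes.reshape(-1, 3)
    edges, targets, weights = _edge_index_arrays((ni, nj, nk))
    pinned = int(((0 - lo[0]) * nj + (0 - lo[1])) * nk + (0 - lo[2]))
    if max_sweeps > 0:
        flat = _relax(flat, edges, targets, weights, step_de, pinned,
                      max_sweeps, tol_move, metric=metric)
    flat[pinned] = center
    return TabGrid(step_de=float(step_de), center=center, lo=lo,
                   nodes=flat.reshape(ni, nj, nk, 3))


def euclidean_metric(a, b):
    """Plain Lab Euclidean distance (vectorized); the test hook under which
    the construction degenerates to an exact cubic lattice."""
    return np.linalg.norm(np.asarray(a, dtype=float) - np.asarray(b, dtype=float),
                          axis=-1)


# ---------------------------------------------------------------------------
# Conversion operations

def tab_to_lab(coords, grid: TabGrid) -> np.ndarray:
    """Trilinear interpolation of tab coordinates to Lab."""
    c = np.atleast_2d(np.asarray(coords, dtype=float))
    if not np.all(grid.in_extent(c)):
        bad = c[~np.atleast_1d(grid.in_extent(c))][0]
        raise CoverageError(f"tab coordinate {bad} outside grid extent")
    fidx = (c - grid.lo).T  # fractional lattice indices, shape (3, m)
    out = np.stack(
        [map_coordinates(grid.nodes[..., d], fidx, order=1, mode="nearest")
         for d in range(3)],
        axis=-1,
    )
    return out if np.ndim(coords) > 1 else out[0]


def lab_to_tab(lab, grid: TabGrid, refine: bool = True) -> np.ndarray:
    """Invert the grid: Lab -> continuous tab coordinates.

    The containing tetrahedron is located in the grid's 6-per-cube
    tetrahedral structure and its barycentric weights give the tab
    coordinate. Because the forward map interpolates trilinearly (not
    tetra-linearly), that coordinate is then polished by a few Newton
    steps against :func:`tab_to_lab` so the round trip closes to well
    below 1e-6 Lab units (``refine=False`` returns the raw tetrahedral
    estimate).
    """
    single = np.ndim(lab) == 1
    pts = np.atleast_2d(np.asarray(lab, dtype=float))
    try:
        coords = np.atleast_2d(grid.mesh().interpolate(pts))
    except ContainmentError as exc:
        raise CoverageError(str(exc)) from exc
    if refine:
        lo, hi = grid.extent
        h = 1e-6
        for _ in range(8):
            f = tab_to_lab(coords, grid) - pts
            err = np.max(np.abs(f))
            if err < 1e-10:
                break
            # finite-difference Jacobian of the trilinear forward map
            J = np.empty((len(coords), 3, 3))
            for d in range(3):
                e = np.zeros(3)
                e[d] = h
                up = np.clip(coords + e, lo, hi)
                dn = np.clip(coords - e, lo, hi)
                J[:, :, d] = (tab_to_lab(up, grid) - tab_to_lab(dn, grid)) / (
                    up[:, d] - dn[:, d])[:, None]
            step = np.linalg.solve(J, f[..., None])[..., 0]
            coords = np.clip(coords - step, lo, hi)
    return coords[0] if single else coords


# ---------------------------------------------------------------------------
# Persistence: CSV node dump + JSON sidecar

def save_tab_grid(grid: TabGrid, csv_path, sidecar_path=None) -> None:
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    ni, nj, nk = grid.nodes.shape[:3]
    with open(csv_path, "w", encoding="utf-8") as fh:
        fh.write("i,j,k,L,a,b\n")
        for i in range(ni):
            for j in range(nj):
                for k in range(nk):
                    L, a, b = (float(v) for v in grid.nodes[i, j, k])
                    fh.write(
                        f"{i + grid.lo[0]},{j + grid.lo[1]},{k + grid.lo[2]},"
                        f"{L!r},{a!r},{b!r}\n"
                    )
    meta = {
        "step_de": grid.step_de,
        "center": list(map(float, grid.center)),
        "lo": list(map(int, grid.lo)),
        "shape": [ni, nj, nk],
    }
    sidecar_path.write_text(json.dumps(meta, indent=1), encoding="utf-8")


def load_tab_grid(csv_path, sidecar_path=None) -> TabGrid:
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text(encoding="utf-8"))
    lo = np.asarray(meta["lo"], dtype=int)
    shape = tuple(meta["shape"])
    nodes = np.full(shape + (3,), np.nan)
    seen = np.zeros(shape, dtype=bool)
    with open(csv_path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.lower().startswith("i,j,k"):
            raise ValueError("bad grid dump header")
        for line in fh:
            parts = line.strip().split(",")
            if len(parts) != 6:
                raise ValueError(f"malformed grid row: {line!r}")
            i, j, k = (int(parts[d]) - lo[d] for d in range(3))
            nodes[i, j, k] = [float(parts[3]), float(parts[4]), float(parts[5])]
            seen[i, j, k] = True
    if not seen.all():
        raise ValueError("grid dump incomplete: missing nodes")
    return TabGrid(step_de=float(meta["step_de"]),
                   center=np.asarray(meta["center"], dtype=float),
                   lo=lo, nodes=nodes)
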