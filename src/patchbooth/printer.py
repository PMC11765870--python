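"""Printer characterization: polyharmonic-spline forward model, tetrahedral
backward model, model selection, gamut meshes and profile I/O.

The forward model is a scattered-data interpolant from device RGB (the
printer's native control space, treated as continuous [0,1]^3) to a
colorimetric target space (CIEXYZ or CIELAB under D65). It is a
polyharmonic radial basis expansion with an affine polynomial tail:

    f(x) = sum_i w_i phi(|x - x_i|) + c0 + c . x

with phi in {r, r^3, r^2 log r} and side conditions sum w_i = 0,
sum w_i x_i = 0. A scalar smoothing factor s relaxes exact interpolation
by adding s*n to the kernel-matrix diagonal (standard thin-plate
regularization). The backward direction and the gamut membership test
both ride on one fine RGB lattice pushed through the forward model and
cut into tetrahedra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solve
from sklearn.base import BaseEstimator, RegressorMixin

from .colorimetry import Observer, delta_e00, delta_e76, lab_to_xyz, xyz_to_lab
from .geometry import ContainmentError, TetraMesh

__all__ = [
    "Chart",
    "make_charts",
    "PolyharmonicSpline",
    "PrinterForwardModel",
    "fit_forward",
    "select_model",
    "BackwardModel",
    "build_backward",
    "GamutMesh",
    "compute_gamut",
    "in_gamut",
    "OutOfGamutError",
    "PrinterProfile",
    "write_profile",
    "read_profile",
]

KERNELS = ("linear", "cubic", "thin-plate")
TARGET_SPACES = ("CIEXYZ", "CIELAB")

#: Default smoothing grid for model selection; brackets the useful range.
DEFAULT_SMOOTHING_GRID = (0.0, 1e-4, 2.5e-4, 1e-3, 2.5e-3, 1e-2, 2.5e-2, 1e-1)


class OutOfGamutError(ValueError):
    """A requested color lies outside the printer's gamut."""


# ---------------------------------------------------------------------------
# Charts

@dataclass(frozen=True)
class Chart:
    """A set of device-RGB patches with a role tag."""

    patches: np.ndarray       # (n, 3) in [0, 1]
    role: str = "training"

    def __post_init__(self):
        p = np.asarray(self.patches, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError("patches must have shape (n, 3)")
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError("RGB components must lie in [0, 1]")
        object.__setattr__(self, "patches", p)

    def __len__(self):
        return len(self.patches)


def make_charts(train_n: int = 6, test_n: int = 5) -> tuple[Chart, Chart]:
    """Regular RGB lattices: train_n^3 training and test_n^3 test patches
    (defaults give the 216 + 125 scheme)."""

    def lattice(n):
        if n < 2:
            raise ValueError("lattice needs n >= 2 per axis")
        ax = np.linspace(0.0, 1.0, n)
        return np.array(list(product(ax, ax, ax)))

    return Chart(lattice(train_n), "training"), Chart(lattice(test_n), "test")


# ---------------------------------------------------------------------------
# Polyharmonic spline

def _phi(r: np.ndarray, kernel: str) -> np.ndarray:
    if kernel == "linear":
        return r
    if kernel == "cubic":
        return r ** 3
    if kernel == "thin-plate":
        out = np.zeros_like(r)
        nz = r > 0
        out[nz] = r[nz] ** 2 * np.log(r[nz])   # phi(0) = 0 (limit value)
        return out
    raise ValueError(f"unknown kernel {kernel!r}; expected one of {KERNELS}")


class PolyharmonicSpline(BaseEstimator, RegressorMixin):
    """Polyharmonic RBF interpolant with affine tail and scalar smoothing.

    Parameters
    ----------
    kernel : {"linear", "cubic", "thin-plate"}
    smoothing : float >= 0
        Added to the kernel-matrix diagonal as ``smoothing * n``.

    Attributes
    ----------
    centers_ : (n, 3) training sites
    weights_ : (n, d) RBF weights (satisfy the polynomial side conditions)
    poly_ : (4, d) affine coefficients [c0; c]
    """

    def __init__(self, kernel: str = "cubic", smoothing: float = 0.0):
        self.kernel = kernel
        self.smoothing = smoothing

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        n = len(X)
        if self.smoothing < 0:
            raise ValueError("smoothing must be nonnegative")
        d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
        if self.smoothing == 0.0 and np.any(d2[~np.eye(n, dtype=bool)] < 1e-24):
            raise ValueError("duplicate centers make the system singular")
        K = _phi(np.sqrt(d2), self.kernel) + self.smoothing * n * np.eye(n)
        P = np.hstack([np.ones((n, 1)), X])
        A = np.zeros((n + 4, n + 4))
        A[:n, :n] = K
        A[:n, n:] = P
        A[n:, :n] = P.T
        rhs = np.zeros((n + 4, y.shape[1]))
        rhs[:n] = y
        sol = solve(A, rhs)
        self.centers_ = X
        self.weights_ = sol[:n]
        self.poly_ = sol[n:]
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        r = np.sqrt(np.sum((X[:, None, :] - self.centers_[None, :, :]) ** 2, axis=-1))
        out = _phi(r, self.kernel) @ self.weights_
        out += np.hstack([np.ones((len(X), 1)), X]) @ self.poly_
        return out


class PrinterForwardModel(BaseEstimator, RegressorMixin):
    """Device RGB -> colorimetry. Fits a :class:`PolyharmonicSpline` in the
    chosen target space; predictions are returned in both CIELAB and CIEXYZ
    (converted under the observer's reference illuminant, default D65).
    """

    def __init__(self, kernel: str = "cubic", target_space: str = "CIEXYZ",
                 smoothing: float = 0.0, observer: Observer | None = None):
        self.kernel = kernel
        self.target_space = target_space
        self.smoothing = smoothing
        self.observer = observer

    def _obs(self) -> Observer:
        return self.observer if self.observer is not None else Observer.default()

    def fit(self, X, xyz):
        """Fit from RGB patches and their *measured XYZ* (Y of white = 100)."""
        if self.target_space not in TARGET_SPACES:
            raise ValueError(f"target_space must be one of {TARGET_SPACES}")
        X = np.asarray(X, dtype=float)
        xyz = np.asarray(xyz, dtype=float)
        self.white_ = self._obs().white_xyz()
        y = xyz if self.target_space == "CIEXYZ" else xyz_to_lab(xyz, self.white_)
        self.spline_ = PolyharmonicSpline(self.kernel, self.smoothing).fit(X, y)
        return self

    def _check_rgb(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if np.any(X < -1e-9) or np.any(X > 1 + 1e-9):
            raise ValueError("RGB inputs must lie in the unit cube")
        return X

    def predict_xyz(self, X):
        single = np.ndim(X) == 1
        X = self._check_rgb(X)
        raw = self.spline_.predict(X)
        xyz = raw if self.target_space == "CIEXYZ" else lab_to_xyz(raw, self.white_)
        return xyz[0] if single else xyz

    def predict(self, X):
        """Predict CIELAB."""
        single = np.ndim(X) == 1
        X = self._check_rgb(X)
        raw = self.spline_.predict(X)
        lab = xyz_to_lab(raw, self.white_) if self.target_space == "CIEXYZ" else raw
        return lab[0] if single else lab


def fit_forward(train: Chart, measured_xyz, kernel: str = "cubic",
                target_space: str = "CIEXYZ", smoothing: float = 0.0,
                observer: Observer | None = None) -> PrinterForwardModel:
    measured_xyz = np.asarray(measured_xyz, dtype=float)
    if len(measured_xyz) != len(train):
        raise ValueError("measurement count must match the chart")
    return PrinterForwardModel(kernel, target_space, smoothing, observer).fit(
        train.patches, measured_xyz
    )


def select_model(train: Chart, train_xyz, test: Chart, test_xyz,
                 smoothing_grid=DEFAULT_SMOOTHING_GRID,
                 observer: Observer | None = None):
    """Exhaustive search over kernels x target spaces x smoothing values.

    Scores every configuration by the mean CIEDE2000 on the test chart and
    returns ``(best_model, score_table)``; the table also carries max and
    95th-percentile statistics for both CIEDE76 and CIEDE2000.
    """
    smoothing_grid = tuple(smoothing_grid)
    if not smoothing_grid:
        raise ValueError("smoothing grid must not be empty")
    obs = observer if observer is not None else Observer.default()
    white = obs.white_xyz()
    test_lab = xyz_to_lab(np.asarray(test_xyz, dtype=float), white)
    rows = []
    best = None
    for kernel in KERNELS:
        for space in TARGET_SPACES:
            for s in smoothing_grid:
                model = fit_forward(train, train_xyz, kernel, space, s, obs)
                pred = model.predict(test.patches)
                de00 = delta_e00(pred, test_lab)
                de76 = delta_e76(pred, test_lab)
                rows.append({
                    "kernel": kernel, "target_space": space, "smoothing": s,
                    "mean_de00": de00.mean(), "max_de00": de00.max(),
                    "p95_de00": np.percentile(de00, 95),
                    "mean_de76": de76.mean(), "max_de76": de76.max(),
                    "p95_de76": np.percentile(de76, 95),
                })
                if best is None or rows[-1]["mean_de00"] < best[0]:
                    best = (rows[-1]["mean_de00"], model)
    table = pd.DataFrame(rows).sort_values("mean_de00", ignore_index=True)
    return best[1], table


# ---------------------------------------------------------------------------
# Backward model and gamut

def _rgb_lattice(sampling_n: int, rgb_bounds) -> np.ndarray:
    lo, hi = rgb_bounds
    ax = np.linspace(lo, hi, sampling_n)
    g = np.meshgrid(ax, ax, ax, indexing="ij")
    return np.stack(g, axis=-1)  # (n, n, n, 3)


def _forward_lattice_colors(model: PrinterForwardModel, lattice, space, grid):
    flat = lattice.reshape(-1, 3)
    lab = model.predict(flat)
    if space == "CIELAB":
        return lab.reshape(lattice.shape)
    if space == "tab":
        if grid is None:
            raise ValueError("tab-space operations need a TabGrid")
        from .tabspace import lab_to_tab

        tab = lab_to_tab(lab, grid)
        return tab.reshape(lattice.shape)
    raise ValueError(f"unknown space {space!r}")


@dataclass
class BackwardModel:
    """Inverse map color -> device RGB over a fine forward-mapped lattice."""

    space: str                 # "CIELAB" or "tab"
    sampling_n: int
    mesh: TetraMesh            # source: color space, target: RGB

    def invert(self, color) -> np.ndarray:
        """Return RGB in [0,1]^3 for an in-gamut color; raises
        :class:`OutOfGamutError` outside the mesh."""
        try:
            rgb = self.mesh.interpolate(color)
        except ContainmentError as exc:
            raise OutOfGamutError(str(exc)) from exc
        return np.clip(rgb, 0.0, 1.0)


def build_backward(model: PrinterForwardModel, sampling_n: int = 33,
                   space: str = "CIELAB", grid=None,
                   rgb_bounds=(0.0, 1.0)) -> BackwardModel:
    """Push a ``sampling_n``^3 RGB lattice through the forward model and cut
    it into tetrahedra keyed by the predicted colors."""
    if sampling_n < 4:
        raise ValueError("sampling_n must be >= 4")
    lattice = _rgb_lattice(sampling_n, rgb_bounds)
    colors = _forward_lattice_colors(model, lattice, space, grid)
    return BackwardModel(space=space, sampling_n=sampling_n,
                         mesh=TetraMesh(colors, lattice))


@dataclass
class GamutMesh:
    """Printer gamut in a color space: tetra interior + boundary shell."""

    space: str
    mesh: TetraMesh
    volume: float
    boundary: np.ndarray       # (n_tris, 3) vertex indices into mesh.verts_src

    def __contains__(self, color) -> bool:
        return bool(self.mesh.contains(color))


def compute_gamut(model: PrinterForwardModel, sampling_n: int = 33,
                  space: str = "CIELAB", grid=None,
                  rgb_bounds=(0.0, 1.0)) -> GamutMesh:
    """Gamut mesh from the same fine RGB lattice as the backward model."""
    if sampling_n < 4:
        raise ValueError("sampling_n must be >= 4")
    lattice = _rgb_lattice(sampling_n, rgb_bounds)
    colors = _forward_lattice_colors(model, lattice, space, grid)
    mesh = TetraMesh(colors, lattice)
    return GamutMesh(space=space, mesh=mesh, volume=mesh.volume(),
                     boundary=mesh.boundary_faces())


def in_gamut(gamut: GamutMesh, color) -> np.ndarray | bool:
    """Tetrahedral membership test (boundary counts as inside)."""
    return gamut.mesh.contains(color)


# ---------------------------------------------------------------------------
# Profile I/O

@dataclass
class PrinterProfile:
    """Characterization record set: one (RGB, XYZ, Lab) row per chart patch
    plus the selected model hyperparameters."""

    rgb: np.ndarray
    xyz: np.ndarray
    lab: np.ndarray
    kernel: str
    target_space: str
    smoothing: float

    def __post_init__(self):
        n = len(self.rgb)
        if not (len(self.xyz) == len(self.lab) == n):
            raise ValueError("record arrays must have equal length")

    def __len__(self):
        return len(self.rgb)


def make_profile(train: Chart, train_xyz, test: Chart, test_xyz,
                 kernel: str, target_space: str, smoothing: float,
                 observer: Observer | None = None) -> PrinterProfile:
    obs = observer if observer is not None else Observer.default()
    rgb = np.vstack([train.patches, test.patches])
    xyz = np.vstack([np.asarray(train_xyz, float), np.asarray(test_xyz, float)])
    lab = xyz_to_lab(xyz, obs.white_xyz())
    return PrinterProfile(rgb, xyz, lab, kernel, target_space, float(smoothing))


def write_profile(profile: PrinterProfile, path) -> None:
    payload = {
        "format": "patchbooth-profile-v1",
        "kernel": profile.kernel,
        "target_space": profile.target_space,
        "smoothing": profile.smoothing,
        "records": [
            {"rgb": list(map(float, r)), "xyz": list(map(float, x)),
             "lab": list(map(float, l))}
            for r, x, l in zip(profile.rgb, profile.xyz, profile.lab)
        ],
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_profile(path, observer: Observer | None = None,
                 check_consistency: bool = True) -> PrinterProfile:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        records = payload["records"]
        rgb = np.array([r["rgb"] for r in records], dtype=float)
        xyz = np.array([r["xyz"] for r in records], dtype=float)
        lab = np.array([r["lab"] for r in records], dtype=float)
        prof = PrinterProfile(rgb, xyz, lab, payload["kernel"],
                              payload["target_space"], float(payload["smoothing"]))
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed profile file {path}: {exc}") from exc
    if check_consistency:
        obs = observer if observer is not None else Observer.default()
        recomputed = xyz_to_lab(prof.xyz, obs.white_xyz())
        if not np.allclose(recomputed, prof.lab, atol=1e-6):
            raise ValueError("profile XYZ and Lab records are inconsistent")
    return prof
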