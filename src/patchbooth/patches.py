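"""Reference-patch selection and near-threshold pair generation.

Reference colors are spread through the printer's gamut with the densest
possible uniform arrangement — the face-centered-cubic ("Kepler") sphere
packing, in which every interior point has exactly 12 equidistant
nearest neighbors. A bisection on the packing distance D finds the
largest spacing at which N stack points still fit inside the gamut.

Around each reference, closely related colors are drawn in the tabulated
space (where Euclidean distance approximates CIEDE2000): the lightness
coordinate is held fixed and a chromatic-plane offset of magnitude
rho ~ N(mu, sigma^2) (redrawn while rho <= 0) in a uniformly random
direction theta is applied, so the nominal pair difference follows a
positive-truncated normal around mu.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .colorimetry import delta_e00
from .printer import BackwardModel, GamutMesh, OutOfGamutError
from .spectral import SpectralDistribution
from .tabspace import TabGrid, tab_to_lab

__all__ = [
    "KeplerStack",
    "generate_stack",
    "max_spacing",
    "select_references",
    "PairSamplingSpec",
    "ColorPair",
    "sample_pair_color",
    "generate_pair_set",
    "aggregate_measurements",
    "band_and_filter",
    "truncated_normal_mean",
    "patch_side_for_angle",
    "write_pair_manifest",
    "read_pair_manifest",
]

BANDS = ("<1", "1-1.5", "1.5-2", ">2")


# ---------------------------------------------------------------------------
# Kepler (FCC) stacking

@dataclass(frozen=True)
class KeplerStack:
    """FCC lattice points around a center with nearest-neighbor spacing D."""

    center: np.ndarray
    spacing: float
    points: np.ndarray         # (n, 3), includes the center
    shells: np.ndarray         # (n,) shell radius index of each point


def generate_stack(center, D: float, n_shells: int) -> KeplerStack:
    """All FCC lattice points within ``n_shells * D`` of the center.

    The FCC lattice is realized as the even-parity integer lattice
    scaled by D / sqrt(2); its minimum pairwise distance is exactly D
    and each interior point touches 12 neighbors at distance D.
    """
    if D <= 0:
        raise ValueError("spacing D must be positive")
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    center = np.asarray(center, dtype=float)
    # even integer lattice within radius n_shells * sqrt(2)
    m = int(math.floor(n_shells * math.sqrt(2.0))) + 1
    r = np.arange(-m, m + 1)
    ii, jj, kk = np.meshgrid(r, r, r, indexing="ij")
    pts = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    pts = pts[(pts.sum(axis=1) % 2) == 0]
    d2 = np.sum(pts * pts, axis=1)
    keep = d2 <= 2.0 * n_shells ** 2 + 1e-9
    pts = pts[keep]
    d2 = d2[keep]
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], d2))
    pts = pts[order]
    d2 = d2[order]
    coords = center + pts * (D / math.sqrt(2.0))
    shells = np.rint(np.sqrt(d2 / 2.0) * 1e9) / 1e9
    return KeplerStack(center=center, spacing=float(D), points=coords,
                       shells=shells)


def _membership(gamut) -> callable:
    """Accept a GamutMesh or a boolean predicate over (n, 3) points."""
    if isinstance(gamut, GamutMesh):
        return lambda pts: np.atleast_1d(gamut.mesh.contains(pts))
    if callable(gamut):
        return lambda pts: np.atleast_1d(gamut(pts))
    raise TypeError("gamut must be a GamutMesh or a predicate")


def max_spacing(gamut, center, N: int, tol: float = 1e-3,
                ceiling: float | None = None) -> float:
    """Largest packing distance D (within ``tol``) at which at least N
    Kepler-stack points around ``center`` remain inside the gamut.

    Exploits monotonicity of the in-gamut count in D via bisection. The
    search ceiling defaults to the gamut bounding-box diagonal.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    inside = _membership(gamut)
    center = np.asarray(center, dtype=float)
    if not inside(center[None])[0]:
        raise ValueError("stack center lies outside the gamut")
    if N == 1:
        return float(ceiling) if ceiling else _default_ceiling(gamut, center)
    hi = float(ceiling) if ceiling else _default_ceiling(gamut, center)

    def feasible(D):
        # shells need only out-reach the gamut; the count is capped at N
        # so small D never explodes the stack
        n_shells = max(1, min(int(math.ceil(hi / D)) + 1, 60))
        stack = generate_stack(center, D, n_shells)
        return int(np.sum(inside(stack.points))) >= N

    # halve down from the ceiling to the first feasible spacing
    lo = hi
    while not feasible(lo):
        lo *= 0.5
        if lo < max(tol, hi * 2 ** -24):
            raise ValueError(f"cannot fit {N} stack points inside the gamut")
    if lo == hi:
        return hi
    hi2 = lo * 2.0
    while hi2 - lo > tol:
        mid = 0.5 * (lo + hi2)
        if feasible(mid):
            lo = mid
        else:
            hi2 = mid
    return lo


def _default_ceiling(gamut, center) -> float:
    if isinstance(gamut, GamutMesh):
        span = gamut.mesh.verts_src.max(axis=0) - gamut.mesh.verts_src.min(axis=0)
        return float(np.linalg.norm(span))
    return 1e3


def select_references(gamut, center, N: int, tol: float = 1e-3,
                      ceiling: float | None = None):
    """The N in-gamut stack points nearest the center at the max spacing.

    Ties broken deterministically by (distance to center, lexicographic
    coordinates). Returns ``(points (N, 3), D)``.
    """
    D = max_spacing(gamut, center, N, tol=tol, ceiling=ceiling)
    inside = _membership(gamut)
    center = np.asarray(center, dtype=float)
    hi = float(ceiling) if ceiling else _default_ceiling(gamut, center)
    stack = generate_stack(center, D, max(1, int(math.ceil(hi / D)) + 1))
    pts = stack.points[inside(stack.points)]
    dist = np.linalg.norm(pts - center, axis=1)
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], np.round(dist, 9)))
    pts = pts[order]
    if len(pts) < N:
        raise ValueError(f"only {len(pts)} in-gamut stack points at D={D}")
    return pts[:N], D


# ---------------------------------------------------------------------------
# Pair generation

@dataclass(frozen=True)
class PairSamplingSpec:
    """Offset-magnitude distribution for related colors.

    ``mu`` and ``sigma`` are in CIEDE2000 units (defaults 0.6 and 0.4);
    ``per_ref`` related colors are drawn per reference.
    """

    mu: float = 0.6
    sigma: float = 0.4
    per_ref: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.mu <= 0 or self.sigma < 0 or self.per_ref < 1:
            raise ValueError("require mu > 0, sigma >= 0, per_ref >= 1")


def truncated_normal_mean(mu: float, sigma: float) -> float:
    """Mean of N(mu, sigma^2) truncated to (0, inf).

    Rejecting nonpositive draws biases the offset mean upward by
    sigma * phi(alpha) / (1 - Phi(alpha)) with alpha = -mu / sigma.
    """
    if sigma == 0:
        return mu
    alpha = -mu / sigma
    phi = math.exp(-0.5 * alpha * alpha) / math.sqrt(2.0 * math.pi)
    Phi = 0.5 * (1.0 + math.erf(alpha / math.sqrt(2.0)))
    return mu + sigma * phi / (1.0 - Phi)


def sample_pair_offset(spec: PairSamplingSpec, rng: np.random.Generator):
    """Draw (rho, theta): rho ~ N(mu, sigma^2) redrawn until positive,
    theta ~ U(0, 2 pi)."""
    rho = rng.normal(spec.mu, spec.sigma)
    while rho <= 0.0:
        rho = rng.normal(spec.mu, spec.sigma)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return rho, theta


def sample_pair_color(ref_tab, spec: PairSamplingSpec, rng: np.random.Generator,
                      grid: TabGrid, in_gamut=None, max_retries: int = 100):
    """Draw one related color around a reference, in tab coordinates.

    The lightness (first) coordinate is kept equal to the reference's;
    the chromatic offset has Euclidean tab magnitude ``rho / step_de``
    so its nominal CIEDE2000 is rho. Draws falling outside the gamut (if
    a membership predicate is given) are redrawn up to ``max_retries``.

    Returns ``(related_tab, rho, theta)``.
    """
    ref_tab = np.asarray(ref_tab, dtype=float)
    if not grid.in_extent(ref_tab):
        raise ValueError("reference tab coordinate outside grid extent")
    for _ in range(max_retries):
        rho, theta = sample_pair_offset(spec, rng)
        off = np.array([0.0, math.sin(theta), math.cos(theta)]) * (rho / grid.step_de)
        cand = ref_tab + off
        if not grid.in_extent(cand):
            continue
        if in_gamut is not None and not np.atleast_1d(in_gamut(cand[None]))[0]:
            continue
        return cand, rho, theta
    raise OutOfGamutError("could not draw an in-gamut related color "
                          f"after {max_retries} retries")


@dataclass
class ColorPair:
    """A reference/related patch pair with its bookkeeping."""

    pair_id: int
    ref_tab: np.ndarray
    ref_lab: np.ndarray
    ref_rgb: np.ndarray
    rel_tab: np.ndarray
    rel_lab: np.ndarray
    rel_rgb: np.ndarray
    nominal_de00: float
    measured_de00: float | None = None
    band: str | None = None
    status: str = "retained"
    marker_id: int | None = None
    rho: float = field(default=np.nan, repr=False)
    theta: float = field(default=np.nan, repr=False)


def generate_pair_set(refs_tab, spec: PairSamplingSpec, backward: BackwardModel,
                      grid: TabGrid, in_gamut=None, rng=None) -> list[ColorPair]:
    """Generate ``per_ref`` related colors for each reference and resolve
    every member to printable device RGB through the backward model."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    refs_tab = np.atleast_2d(np.asarray(refs_tab, dtype=float))
    pairs = []
    pid = 0
    for ref in refs_tab:
        ref_lab = tab_to_lab(ref, grid)
        ref_rgb = backward.invert(ref_lab if backward.space == "CIELAB" else ref)
        for _ in range(spec.per_ref):
            rel, rho, theta = sample_pair_color(ref, spec, rng, grid, in_gamut)
            rel_lab = tab_to_lab(rel, grid)
            rel_rgb = backward.invert(rel_lab if backward.space == "CIELAB" else rel)
            pairs.append(ColorPair(
                pair_id=pid, marker_id=pid,
                ref_tab=ref, ref_lab=ref_lab, ref_rgb=ref_rgb,
                rel_tab=rel, rel_lab=rel_lab, rel_rgb=rel_rgb,
                nominal_de00=float(rho), rho=float(rho), theta=float(theta),
            ))
            pid += 1
    return pairs


# ---------------------------------------------------------------------------
# Measurement aggregation and banding

def aggregate_measurements(readings) -> SpectralDistribution:
    """Mean spectrum over a measurement scheme.

    ``readings`` is either a flat sequence of spectra or a nested
    sequence (locations of consecutive repeats, e.g. 5 x 3). For a
    balanced nested design the mean of location means equals the grand
    mean, so everything reduces to one unweighted average.
    """
    flat = []
    for item in readings:
        if isinstance(item, SpectralDistribution):
            flat.append(item)
        else:
            flat.extend(item)
    if not flat:
        raise ValueError("no readings")
    wl = flat[0].wavelengths
    for s in flat[1:]:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("readings on mismatched wavelength grids")
    vals = np.mean([s.values for s in flat], axis=0)
    return SpectralDistribution(wl, vals, name="aggregate")


def band_of(de: float) -> str:
    if de < 1.0:
        return "<1"
    if de < 1.5:
        return "1-1.5"
    if de < 2.0:
        return "1.5-2"
    return ">2"


def band_and_filter(pairs: list[ColorPair], outlier_threshold: float = 2.0):
    """Assign quality bands from measured CIEDE2000 and drop outliers.

    Pairs whose measured difference exceeds ``outlier_threshold`` are too
    far from their reference to serve in a discrimination experiment.
    Returns ``(retained, outliers, summary)`` where the summary maps each
    band to its fraction of the full set.
    """
    retained, outliers = [], []
    counts = dict.fromkeys(BANDS, 0)
    for p in pairs:
        if p.measured_de00 is None:
            raise ValueError(f"pair {p.pair_id} has no measured difference")
        p.band = band_of(p.measured_de00)
        counts[p.band] += 1
        if p.measured_de00 > outlier_threshold:
            p.status = "outlier"
            outliers.append(p)
        else:
            p.status = "retained"
            retained.append(p)
    n = max(len(pairs), 1)
    summary = {f"frac_{band}": counts[band] / n for band in BANDS}
    summary["n_total"] = len(pairs)
    summary["n_retained"] = len(retained)
    summary["n_outliers"] = len(outliers)
    return retained, outliers, summary


# ---------------------------------------------------------------------------
# Stimulus geometry

def patch_side_for_angle(angle_deg: float, distance_cm: float,
                         rounded: bool = False) -> float:
    """Side of a square patch subtending ``angle_deg`` at ``distance_cm``:
    2 d tan(angle / 2). ``rounded`` snaps to 0.1 cm for presentation."""
    if angle_deg < 0 or distance_cm <= 0:
        raise ValueError("need angle >= 0 and distance > 0")
    side = 2.0 * distance_cm * math.tan(math.radians(angle_deg) / 2.0)
    return round(side, 1) if rounded else side


# ---------------------------------------------------------------------------
# Pair manifest I/O

def _rgb8(rgb) -> list[int]:
    return [int(round(c * 255)) for c in np.clip(rgb, 0, 1)]


def write_pair_manifest(pairs: list[ColorPair], path, fmt: str | None = None):
    """Write the pair manifest (JSON or CSV by extension)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    records = [{
        "pair_id": p.pair_id,
        "marker_id": p.marker_id,
        "ref_rgb": [float(x) for x in p.ref_rgb],
        "ref_rgb8": _rgb8(p.ref_rgb),
        "rel_rgb": [float(x) for x in p.rel_rgb],
        "rel_rgb8": _rgb8(p.rel_rgb),
        "ref_lab": [float(x) for x in p.ref_lab],
        "rel_lab": [float(x) for x in p.rel_lab],
        "nominal_de00": p.nominal_de00,
        "measured_de00": p.measured_de00,
        "band": p.band,
        "status": p.status,
    } for p in pairs]
    if fmt == "json":
        path.write_text(json.dumps({"pairs": records}, indent=1), encoding="utf-8")
    elif fmt == "csv":
        cols = ["pair_id", "marker_id",
                "ref_r", "ref_g", "ref_b", "rel_r", "rel_g", "rel_b",
                "ref_r8", "ref_g8", "ref_b8", "rel_r8", "rel_g8", "rel_b8",
                "nominal_de00", "measured_de00", "band", "status"]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for r in records:
                w.writerow([r["pair_id"], r["marker_id"], *r["ref_rgb"],
                            *r["rel_rgb"], *r["ref_rgb8"], *r["rel_rgb8"],
                            r["nominal_de00"], r["measured_de00"],
                            r["band"], r["status"]])
    else:
        raise ValueError(f"unknown manifest format {fmt!r}")


def read_pair_manifest(path) -> list[dict]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return payload["pairs"]
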