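"""Foundational colorimetry: tristimulus integration, CIELAB, color
differences and photometry.

Colors are plain float arrays: XYZ and Lab triples have shape ``(..., 3)``
so every operation vectorizes. The reference white is scaled to Y = 100.

Color-matching functions
------------------------
The CIE 1931 2-degree color-matching functions are evaluated from the
multi-lobe (piecewise) Gaussian analytic fit of Wyman, Sloan & Shirley
(J. Computer Graphics Techniques, 2013). The fit deviates from the CIE
table by well under 1% of peak on each function, which is ample for the
purposes here: every quantity of interest compares two stimuli *through
the same observer*. The luminous-efficiency function V(lambda) is the
ybar lobe of the same fit; illuminant A comes from its exact Planckian
formula, and D65 from the standard 10 nm relative-SPD table packaged
with the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .spectral import VIS_GRID, SpectralDistribution, read_spectrum_csv

__all__ = [
    "cmf_1931",
    "d65_spd",
    "illuminant_a_spd",
    "equal_energy_spd",
    "vlambda",
    "Observer",
    "spd_to_xyz",
    "xyz_to_lab",
    "lab_to_xyz",
    "delta_e76",
    "delta_e00",
    "illuminance",
]

_EPS = (6.0 / 29.0) ** 3          # CIELAB linear-segment break
_KAPPA = (29.0 / 6.0) ** 2 / 3.0  # slope of the linear segment (= 841/108)


def _lobe(x, mu, s1, s2):
    s = np.where(x < mu, s1, s2)
    t = (x - mu) / s
    return np.exp(-0.5 * t * t)


def cmf_1931(wavelengths=None) -> np.ndarray:
    """CIE 1931 2-deg color-matching functions, shape (n, 3).

    Analytic multi-lobe Gaussian fit (Wyman-Sloan-Shirley 2013).
    """
    wl = VIS_GRID if wavelengths is None else np.asarray(wavelengths, dtype=float)
    xbar = (
        1.056 * _lobe(wl, 599.8, 37.9, 31.0)
        + 0.362 * _lobe(wl, 442.0, 16.0, 26.7)
        - 0.065 * _lobe(wl, 501.1, 20.4, 26.2)
    )
    ybar = 0.821 * _lobe(wl, 568.8, 46.9, 40.5) + 0.286 * _lobe(wl, 530.9, 16.3, 31.1)
    zbar = 1.217 * _lobe(wl, 437.0, 11.8, 36.0) + 0.681 * _lobe(wl, 459.0, 26.0, 13.8)
    return np.clip(np.stack([xbar, ybar, zbar], axis=-1), 0.0, None)


def vlambda(wavelengths=None) -> SpectralDistribution:
    """Photopic luminous efficiency V(lambda) (the ybar function)."""
    wl = VIS_GRID if wavelengths is None else np.asarray(wavelengths, dtype=float)
    return SpectralDistribution(wl, cmf_1931(wl)[:, 1], name="V(lambda)")


def d65_spd(grid=None) -> SpectralDistribution:
    """CIE illuminant D65 relative SPD, resampled to ``grid`` (default 1 nm)."""
    with resources.files("patchbooth.data").joinpath("cie_d65_10nm.csv").open("r") as fh:
        raw = read_spectrum_csv(fh, name="D65")
    return raw.to_grid(VIS_GRID if grid is None else grid, method="linear")


def illuminant_a_spd(grid=None) -> SpectralDistribution:
    """CIE illuminant A from its exact Planckian formula (T = 2848 K, c2 old)."""
    wl = VIS_GRID if grid is None else np.asarray(grid, dtype=float)
    c2 = 1.435e7  # nm K, historical value fixed by the CIE definition
    num = np.expm1(c2 / (2848.0 * 560.0))
    den = np.expm1(c2 / (2848.0 * wl))
    vals = 100.0 * (560.0 / wl) ** 5 * num / den
    return SpectralDistribution(wl, vals, name="A")


def equal_energy_spd(grid=None) -> SpectralDistribution:
    wl = VIS_GRID if grid is None else np.asarray(grid, dtype=float)
    return SpectralDistribution(wl, np.ones_like(wl), name="E")


@dataclass(frozen=True)
class Observer:
    """Bundle of CMFs, reference illuminant and V(lambda) on one grid.

    ``k`` is the emissive normalization constant fixed so the session's
    reference SPD maps to Y = 100; it is computed lazily on first use if
    not supplied.
    """

    wavelengths: np.ndarray
    cmfs: np.ndarray                    # (n, 3)
    illuminant: SpectralDistribution    # reference illuminant (default D65)
    k_emissive: float | None = None

    @classmethod
    def default(cls, illuminant: SpectralDistribution | None = None) -> "Observer":
        ill = illuminant if illuminant is not None else d65_spd()
        wl = VIS_GRID
        if not np.array_equal(ill.wavelengths, wl):
            ill = ill.to_grid(wl)
        return cls(wavelengths=wl, cmfs=cmf_1931(wl), illuminant=ill)

    @property
    def pitch(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def white_xyz(self) -> np.ndarray:
        """XYZ of the reference illuminant, Y scaled to 100."""
        return spd_to_xyz(self.illuminant, self, mode="emissive")


def _aligned_values(spd: SpectralDistribution, obs: Observer) -> np.ndarray:
    if np.array_equal(spd.wavelengths, obs.wavelengths):
        return spd.values
    lo = max(spd.wavelengths[0], obs.wavelengths[0])
    hi = min(spd.wavelengths[-1], obs.wavelengths[-1])
    if lo >= hi:
        raise ValueError("spectrum and observer have disjoint wavelength support")
    # auto-resample; missing tails integrate as zero
    out = np.interp(obs.wavelengths, spd.wavelengths, spd.values, left=0.0, right=0.0)
    return out


def spd_to_xyz(
    spd: SpectralDistribution,
    obs: Observer | None = None,
    mode: str = "emissive",
) -> np.ndarray:
    """Integrate a spectrum against the observer's CMFs.

    ``mode="emissive"`` scales with k = 100 / integral(S_ref ybar) so the
    observer's reference illuminant maps to Y = 100. With
    ``mode="reflective"`` the spectrum is a reflectance factor weighted
    by the reference illuminant (perfect diffuser -> Y = 100).
    Integration is rectangle (bin-width) summation on the observer grid.
    """
    obs = obs or Observer.default()
    vals = _aligned_values(spd, obs)
    dl = obs.pitch
    if mode == "emissive":
        k = obs.k_emissive
        if k is None:
            k = 100.0 / (np.sum(obs.illuminant.values * obs.cmfs[:, 1]) * dl)
        return k * (vals @ obs.cmfs) * dl
    if mode in ("reflective", "reflective-with-illuminant"):
        ill = obs.illuminant.values
        k = 100.0 / (np.sum(ill * obs.cmfs[:, 1]) * dl)
        return k * ((vals * ill) @ obs.cmfs) * dl
    raise ValueError(f"unknown mode {mode!r}")


def _f(t):
    t = np.asarray(t, dtype=float)
    return np.where(t > _EPS, np.cbrt(t), _KAPPA * t + 4.0 / 29.0)


def _finv(u):
    u = np.asarray(u, dtype=float)
    return np.where(u > 6.0 / 29.0, u ** 3, (u - 4.0 / 29.0) / _KAPPA)


def xyz_to_lab(xyz, white) -> np.ndarray:
    """CIE 1976 L*a*b* from XYZ (both with Y of white = 100)."""
    xyz = np.asarray(xyz, dtype=float)
    white = np.asarray(white, dtype=float)
    if np.any(white <= 0):
        raise ValueError("white point components must be positive")
    fx, fy, fz = (_f(xyz[..., i] / white[..., i]) for i in range(3))
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


def lab_to_xyz(lab, white) -> np.ndarray:
    """Inverse of :func:`xyz_to_lab`."""
    lab = np.asarray(lab, dtype=float)
    white = np.asarray(white, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    return np.stack(
        [white[..., 0] * _finv(fx), white[..., 1] * _finv(fy), white[..., 2] * _finv(fz)],
        axis=-1,
    )


def delta_e76(lab1, lab2) -> np.ndarray:
    """CIE 1976 color difference: Euclidean distance in Lab."""
    d = np.asarray(lab1, dtype=float) - np.asarray(lab2, dtype=float)
    return np.sqrt(np.sum(d * d, axis=-1))


def delta_e00(lab1, lab2, kL=1.0, kC=1.0, kH=1.0) -> np.ndarray:
    """CIEDE2000 color difference (CIE 142; parametric factors default 1).

    Vectorized over leading dimensions; symmetric in its arguments.
    """
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    c7 = Cbar ** 7
    G = 0.5 * (1.0 - np.sqrt(c7 / (c7 + 25.0 ** 7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where(C1p == 0.0, 0.0, h1p)
    h2p = np.where(C2p == 0.0, 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p
    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0.0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(habs <= 180.0, 0.5 * hsum,
                   np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)))
    hbp = np.where(C1p * C2p == 0.0, hsum, hbp)

    T = (1.0
         - 0.17 * np.cos(np.radians(hbp - 30.0))
         + 0.24 * np.cos(np.radians(2.0 * hbp))
         + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
         - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0)))

    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    cb7 = Cbp ** 7
    RC = 2.0 * np.sqrt(cb7 / (cb7 + 25.0 ** 7))
    lb2 = (Lbp - 50.0) ** 2
    SL = 1.0 + 0.015 * lb2 / np.sqrt(20.0 + lb2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    tL = dLp / (kL * SL)
    tC = dCp / (kC * SC)
    tH = dHp / (kH * SH)
    return np.sqrt(np.maximum(tL * tL + tC * tC + tH * tH + RT * tC * tH, 0.0))


def illuminance(spd: SpectralDistribution, obs: Observer | None = None) -> float:
    """Photometric integral 683 * integral(S V) in lux-equivalent units."""
    obs = obs or Observer.default()
    vals = _aligned_values(spd, obs)
    return float(683.0 * np.sum(vals * obs.cmfs[:, 1]) * obs.pitch)
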