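"""Synthetic ground-truth devices ("rigs") for exercising every pipeline
stage without hardware.

Three rigs are provided:

* :class:`VirtualPrinter` — a smooth subtractive ink-mixing model. It is
  deliberately *not* a physical ink model: it only needs to be a smooth,
  monotone, printer-like RGB -> reflectance map with known ground truth,
  so that characterization error measures model fidelity, not rig
  quirks.
* :class:`VirtualPanel` — a 19-channel LED luminaire whose per-channel
  peak wavelengths, amplitude attenuations between 30 and 45 degC, and
  peak-shift behavior follow the measured characterization of a real
  multi-channel panel. Channel SPDs are Gaussian surrogates (the real
  shapes are not tabulated): FWHM 22 nm for narrow emitters, 70 nm for
  the broad ones. Drive response is exactly linear.
* :class:`VirtualSpectroradiometer` — resamples to a 5 nm instrument
  pitch and applies seeded multiplicative/additive noise.

A single seed fixes every synthetic output bit-exactly (for a fixed call
sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import VIS_GRID, SpectralDistribution, resample

__all__ = [
    "PANEL_THERMAL_TABLE",
    "VirtualPrinter",
    "VirtualPanel",
    "VirtualSpectroradiometer",
    "VirtualPanelSession",
    "run_characterization",
    "rigs_from_scenario",
]

# Measured thermal characterization of the 19 retained panel channels:
# (label, peak wavelength at 30 degC [nm], amplitude attenuation at 45 degC,
#  peak-shift category). Categories: "no" shift, "<10" nm, or "grad"ual.
PANEL_THERMAL_TABLE = [
    ("V1", 406, 0.07, "no"), ("V2", 421, 0.06, "no"), ("RB1", 441, 0.04, "no"),
    ("RB2", 454, 0.03, "no"), ("B1", 468, 0.04, "no"), ("B2", 478, 0.05, "<10"),
    ("C", 500, 0.16, "<10"), ("G1", 517, 0.01, "<10"), ("G2", 528, 0.15, "<10"),
    ("L", 544, 0.02, "grad"), ("PC-A", 594, 0.08, "grad"), ("OR", 624, 0.27, "grad"),
    ("R1", 636, 0.30, "grad"), ("R2", 654, 0.28, "grad"), ("DR1", 686, 0.06, "grad"),
    ("DR2", 708, 0.21, "grad"), ("FR1", 732, 0.28, "grad"), ("FR2", 765, 0.10, "grad"),
    ("FR3", 777, 0.07, "grad"),
]

#: Peak-shift magnitude at 45 degC assigned to each category (nm). The
#: categories are qualitative; these numbers are a modeling choice.
SHIFT_NM = {"no": 0.0, "<10": 3.0, "grad": 5.0}

#: Channels with broad (phosphor-like) emission get the wide surrogate.
BROAD_CHANNELS = {"C", "L", "PC-A"}

_T_RANGE = (30.0, 45.0)


# ---------------------------------------------------------------------------
# Virtual printer

def _gauss(wl, mu, fwhm):
    s = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((wl - mu) / s) ** 2)


@dataclass
class VirtualPrinter:
    """Smooth subtractive ink-mixing printer with seeded measurement noise.

    Reflectance model: paper white times, per subtractive primary c,
    ``(1 - amount_c(rgb) * absorb_c(lambda)) ** gamma`` with
    ``amount = 1 - rgb_channel``. Output is clipped to [0, 1].
    """

    noise_sigma: float = 0.002          # multiplicative measurement noise
    gamma: float = 1.8
    seed: int = 0
    grid: np.ndarray = field(default_factory=lambda: VIS_GRID.copy())

    def __post_init__(self):
        wl = self.grid
        # paper white: high, flat-ish, slightly blue-absorbing (matte stock)
        self._paper = 0.88 - 0.04 * _gauss(wl, 400.0, 90.0)
        # absorption bands of the cyan / magenta / yellow-like primaries
        self._absorb = np.stack([
            0.93 * _gauss(wl, 620.0, 110.0),   # cyan ink absorbs long wl
            0.93 * _gauss(wl, 530.0, 90.0),    # magenta absorbs mid wl
            0.93 * _gauss(wl, 445.0, 80.0),    # yellow absorbs short wl
        ])
        self._rng = np.random.default_rng(self.seed)

    def reflectance(self, rgb) -> np.ndarray:
        """Noise-free ground-truth reflectance, shape (..., n_wl)."""
        rgb = np.asarray(rgb, dtype=float)
        amounts = 1.0 - rgb                          # (..., 3)
        layers = 1.0 - amounts[..., :, None] * self._absorb  # (..., 3, n_wl)
        refl = self._paper * np.prod(layers, axis=-2) ** self.gamma
        return np.clip(refl, 0.0, 1.0)

    def print_and_measure(self, rgb) -> SpectralDistribution | list:
        """Print patch(es) and return measured reflectance spectra."""
        rgb = np.asarray(rgb, dtype=float)
        if np.any(rgb < -1e-9) or np.any(rgb > 1 + 1e-9):
            raise ValueError("RGB must lie in the unit cube")
        refl = self.reflectance(rgb)
        if self.noise_sigma > 0:
            refl = refl * (1.0 + self._rng.normal(0.0, self.noise_sigma, refl.shape))
        refl = np.clip(refl, 0.0, 1.0)
        if rgb.ndim == 1:
            return SpectralDistribution(self.grid, refl)
        return [SpectralDistribution(self.grid, r) for r in refl]


# ---------------------------------------------------------------------------
# Virtual LED panel

@dataclass(frozen=True)
class ChannelThermalModel:
    label: str
    peak_nm: float           # peak wavelength at 30 degC
    fwhm_nm: float
    amplitude: float         # peak spectral amplitude at full drive, 30 degC
    attenuation: float       # fractional amplitude loss at 45 degC
    shift_nm: float          # peak shift at 45 degC (toward longer wl)

    def spd_values(self, wl: np.ndarray, T: float) -> np.ndarray:
        """Full-drive channel SPD at heatsink temperature T (degC)."""
        frac = (T - _T_RANGE[0]) / (_T_RANGE[1] - _T_RANGE[0])
        amp = self.amplitude * (1.0 - self.attenuation * frac)
        return amp * _gauss(wl, self.peak_nm + self.shift_nm * frac, self.fwhm_nm)


@dataclass
class VirtualPanel:
    """Thermally drifting multi-channel LED panel (linear drive response)."""

    channels: list[ChannelThermalModel] = field(default_factory=list)
    grid: np.ndarray = field(default_factory=lambda: VIS_GRID.copy())

    @classmethod
    def from_thermal_table(cls, overrides: dict | None = None,
                    grid: np.ndarray | None = None) -> "VirtualPanel":
        """Build the 19-channel panel from the measured thermal table.

        ``overrides`` may remap ``{label: {"attenuation": ..., "shift_nm":
        ..., "fwhm_nm": ..., "amplitude": ...}}``.
        """
        chans = []
        for label, peak, att, cat in PANEL_THERMAL_TABLE:
            kw = {
                "label": label, "peak_nm": float(peak),
                "fwhm_nm": 70.0 if label in BROAD_CHANNELS else 22.0,
                "amplitude": 1.0, "attenuation": float(att),
                "shift_nm": SHIFT_NM[cat],
            }
            if overrides and label in overrides:
                kw.update(overrides[label])
            chans.append(ChannelThermalModel(**kw))
        return cls(channels=chans, grid=VIS_GRID.copy() if grid is None else grid)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_spd(self, i: int, T: float = 30.0) -> SpectralDistribution:
        self._check_T(T)
        return SpectralDistribution(self.grid, self.channels[i].spd_values(self.grid, T),
                                    name=self.channels[i].label)

    def _check_T(self, T: float):
        if not (_T_RANGE[0] - 1e-9 <= T <= _T_RANGE[1] + 1e-9):
            raise ValueError(f"temperature {T} degC outside {_T_RANGE}")

    def output(self, drives, T: float = 30.0) -> SpectralDistribution:
        """Panel SPD: linear superposition of per-channel contributions."""
        self._check_T(T)
        drives = np.asarray(drives, dtype=float)
        if drives.shape != (self.n_channels,):
            raise ValueError(f"expected {self.n_channels} drive levels")
        if np.any(drives < -1e-12) or np.any(drives > 1 + 1e-12):
            raise ValueError("drive levels must lie in [0, 1]")
        vals = np.zeros_like(self.grid)
        for d, ch in zip(drives, self.channels):
            if d > 0:
                vals += d * ch.spd_values(self.grid, T)
        return SpectralDistribution(self.grid, vals, name=f"panel@{T:.3g}C")


# ---------------------------------------------------------------------------
# Virtual spectroradiometer

@dataclass
class VirtualSpectroradiometer:
    """5 nm-pitch instrument with multiplicative and additive noise.

    A *reading* averages ``n_avg`` consecutive noisy captures (the same
    3-consecutive-measurements convention used when reading printed
    patches); ``sigma_mult``/``sigma_add`` apply per capture.
    """

    wl_start: float = 380.0
    wl_end: float = 780.0
    pitch: float = 5.0
    sigma_mult: float = 0.003
    sigma_add: float = 0.0
    n_avg: int = 3
    seed: int = 0

    def __post_init__(self):
        self.grid = np.arange(self.wl_start, self.wl_end + self.pitch / 2, self.pitch)
        self._rng = np.random.default_rng(self.seed)

    @classmethod
    def ideal(cls, **kw) -> "VirtualSpectroradiometer":
        kw.setdefault("sigma_mult", 0.0)
        kw.setdefault("sigma_add", 0.0)
        return cls(**kw)

    def measure(self, spd: SpectralDistribution) -> SpectralDistribution:
        lo = max(self.grid[0], spd.wavelengths[0])
        hi = min(self.grid[-1], spd.wavelengths[-1])
        sub = self.grid[(self.grid >= lo - 1e-9) & (self.grid <= hi + 1e-9)]
        out = resample(spd, sub, method="linear")
        clean = out.values
        if self.sigma_mult == 0.0 and self.sigma_add == 0.0:
            return SpectralDistribution(sub, clean, name=spd.name)
        caps = np.repeat(clean[None, :], max(self.n_avg, 1), axis=0)
        if self.sigma_mult > 0:
            caps = caps * (1.0 + self._rng.normal(0.0, self.sigma_mult, caps.shape))
        if self.sigma_add > 0:
            caps = caps + self._rng.normal(0.0, self.sigma_add, caps.shape)
        return SpectralDistribution(sub, np.clip(caps.mean(axis=0), 0.0, None),
                                    name=spd.name)


# ---------------------------------------------------------------------------
# Characterization procedure (simulated execution)

def run_characterization(panel: VirtualPanel, drive_levels: int = 100,
                         temperatures: int = 15,
                         spectro: VirtualSpectroradiometer | None = None):
    """Measure every channel separately over a drive-level x temperature
    sweep and summarize its thermal behavior.

    Returns ``(tensor, summary)``: the SPD tensor has shape
    ``(n_channels, drive_levels, temperatures, n_wl)`` on the instrument
    grid, and the summary DataFrame reports per-channel amplitude
    attenuation and peak shift recomputed *from the tensor*.

    The instrument defaults to a noiseless spectroradiometer over its
    full 350-1000 nm range so broad red-edge channels are not clipped
    when thermally shifted.
    """
    if drive_levels < 2 or temperatures < 2:
        raise ValueError("need at least 2 drive levels and 2 temperatures")
    if spectro is None:
        spectro = VirtualSpectroradiometer.ideal(wl_start=350.0, wl_end=1000.0)
    drives = np.linspace(1.0 / drive_levels, 1.0, drive_levels)
    temps = np.linspace(_T_RANGE[0], _T_RANGE[1], temperatures)

    full_grid = np.arange(350.0, 1000.0 + 0.5, panel.grid[1] - panel.grid[0])
    tensor = np.zeros((panel.n_channels, drive_levels, temperatures,
                       len(spectro.grid)))
    for ci, ch in enumerate(panel.channels):
        for di, d in enumerate(drives):
            for ti, T in enumerate(temps):
                vals = d * ch.spd_values(full_grid, T)
                spd = SpectralDistribution(full_grid, vals, name=ch.label)
                tensor[ci, di, ti] = spectro.measure(spd).values

    rows = []
    fine = np.arange(spectro.grid[0], spectro.grid[-1] + 0.5, 1.0)
    for ci, ch in enumerate(panel.channels):
        first = tensor[ci, -1, 0]
        last = tensor[ci, -1, -1]
        p30 = np.sum(first)
        p45 = np.sum(last)
        att = 1.0 - p45 / p30 if p30 > 0 else np.nan
        pk30 = fine[np.argmax(np.interp(fine, spectro.grid, first))]
        pk45 = fine[np.argmax(np.interp(fine, spectro.grid, last))]
        rows.append({"channel": ch.label, "peak_nm": pk30,
                     "attenuation": att, "peak_shift_nm": pk45 - pk30})
    return tensor, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Panel session: the measure()/set_drives() contract used by the
# stabilization loop, with a temperature trajectory.

class VirtualPanelSession:
    """Drives a :class:`VirtualPanel` along a temperature schedule.

    Each ``measure()`` call reads the output at the next scheduled
    temperature (the schedule saturates at its last entry), emulating a
    run during which the luminaire heats up between control iterations.
    """

    def __init__(self, panel: VirtualPanel, schedule=None,
                 spectro: VirtualSpectroradiometer | None = None,
                 drives=None):
        self.panel = panel
        self.schedule = (np.asarray(schedule, dtype=float) if schedule is not None
                         else np.linspace(*_T_RANGE, 10))
        self.spectro = spectro if spectro is not None else VirtualSpectroradiometer()
        self.drives = (np.zeros(panel.n_channels) if drives is None
                       else np.asarray(drives, dtype=float))
        self._step = 0

    @property
    def temperature(self) -> float:
        return float(self.schedule[min(self._step, len(self.schedule) - 1)])

    def set_drives(self, drives) -> None:
        drives = np.asarray(drives, dtype=float)
        if drives.shape != (self.panel.n_channels,):
            raise ValueError("drive vector length mismatch")
        self.drives = np.clip(drives, 0.0, 1.0)

    def measure(self) -> SpectralDistribution:
        out = self.spectro.measure(self.panel.output(self.drives, self.temperature))
        self._step += 1
        return out


# ---------------------------------------------------------------------------
# Scenario construction

def rigs_from_scenario(scenario: dict):
    """Build (printer, panel, spectro) from a scenario mapping.

    Recognized keys: ``seed``, ``printer`` (noise_sigma, gamma), ``panel``
    (thermal-table overrides under ``channels``), ``spectro`` (sigma_mult,
    sigma_add, wl_start, wl_end, pitch).
    """
    seed = int(scenario.get("seed", 0))
    pr = scenario.get("printer", {}) or {}
    printer = VirtualPrinter(noise_sigma=float(pr.get("noise_sigma", 0.002)),
                             gamma=float(pr.get("gamma", 1.8)), seed=seed)
    pa = scenario.get("panel", {}) or {}
    panel = VirtualPanel.from_thermal_table(overrides=pa.get("channels"))
    sp = scenario.get("spectro", {}) or {}
    spectro = VirtualSpectroradiometer(
        wl_start=float(sp.get("wl_start", 380.0)),
        wl_end=float(sp.get("wl_end", 780.0)),
        pitch=float(sp.get("pitch", 5.0)),
        sigma_mult=float(sp.get("sigma_mult", 0.003)),
        sigma_add=float(sp.get("sigma_add", 0.0)),
        seed=seed + 1,
    )
    return printer, panel, spectro
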