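"""Spectral distributions on uniform wavelength grids.

The package works internally on the visible band 380-780 nm sampled at
1 nm; instruments deliver coarser pitches (typically 5 or 10 nm) and are
resampled on ingestion. A :class:`SpectralDistribution` carries either
relative radiant power (emissive data) or a reflectance factor.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import Akima1DInterpolator

__all__ = [
    "SpectralDistribution",
    "VIS_GRID",
    "resample",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_cgats",
]

#: Internal working grid: 380-780 nm at 1 nm pitch.
VIS_GRID = np.arange(380.0, 781.0, 1.0)

_VALID_RANGE = (350.0, 1000.0)


@dataclass(frozen=True)
class SpectralDistribution:
    """A sampled spectrum on a strictly increasing uniform wavelength grid.

    Parameters
    ----------
    wavelengths : array of float, nm
        Uniformly pitched, strictly increasing, within [350, 1000] nm.
    values : array of float
        Nonnegative sample values (relative power or reflectance factor),
        one per wavelength.
    name : str, optional
        Free-form label carried through operations.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vv = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vv.ndim != 1 or wl.size != vv.size:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("need at least two samples")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("wavelength grid must be uniform")
        if wl[0] < _VALID_RANGE[0] - 1e-9 or wl[-1] > _VALID_RANGE[1] + 1e-9:
            raise ValueError(f"grid must lie within {_VALID_RANGE} nm")
        if np.any(vv < -1e-9):
            raise ValueError("spectral values must be nonnegative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", np.clip(vv, 0.0, None))

    @property
    def pitch(self) -> float:
        """Grid pitch in nm."""
        return float(self.wavelengths[1] - self.wavelengths[0])

    def __mul__(self, k: float) -> "SpectralDistribution":
        return SpectralDistribution(self.wavelengths, self.values * float(k), self.name)

    __rmul__ = __mul__

    def __add__(self, other: "SpectralDistribution") -> "SpectralDistribution":
        if not np.array_equal(self.wavelengths, other.wavelengths):
            raise ValueError("cannot add spectra on different grids")
        return SpectralDistribution(self.wavelengths, self.values + other.values, self.name)

    def to_grid(self, grid: np.ndarray, method: str = "linear") -> "SpectralDistribution":
        """Resample onto ``grid`` (see :func:`resample`)."""
        return resample(self, grid, method=method)


def resample(
    spd: SpectralDistribution,
    target_grid: np.ndarray,
    method: str = "linear",
) -> SpectralDistribution:
    """Resample a spectrum onto a new uniform grid.

    ``method`` is ``"linear"`` or ``"akima"``. Extrapolation outside the
    source span is refused; tiny negative overshoots of the Akima spline
    are clipped to zero.
    """
    grid = np.asarray(target_grid, dtype=float)
    wl, vv = spd.wavelengths, spd.values
    if grid[0] < wl[0] - 1e-9 or grid[-1] > wl[-1] + 1e-9:
        raise ValueError(
            f"target grid [{grid[0]}, {grid[-1]}] outside source span [{wl[0]}, {wl[-1]}]"
        )
    if np.array_equal(grid, wl):
        return SpectralDistribution(grid, vv.copy(), spd.name)
    if method == "linear":
        out = np.interp(grid, wl, vv)
    elif method == "akima":
        out = Akima1DInterpolator(wl, vv)(grid)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return SpectralDistribution(grid, np.clip(out, 0.0, None), spd.name)


# ---------------------------------------------------------------------------
# File I/O: two-column CSV and a minimal CGATS.17 dialect (i1Pro ecosystem).

def read_spectrum_csv(path_or_buf, name: str = "") -> SpectralDistribution:
    """Read a two-column (wavelength_nm, value) CSV; '#' comments allowed."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf, "r", encoding="utf-8") as fh:
            text = fh.read()
    rows = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line or line.lower().startswith("wavelength"):
            continue
        parts = re.split(r"[,;\s]+", line)
        if len(parts) < 2:
            raise ValueError(f"malformed spectrum line: {line!r}")
        rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValueError("no spectral samples found")
    arr = np.asarray(rows)
    return SpectralDistribution(arr[:, 0], arr[:, 1], name=name)


def write_spectrum_csv(spd: SpectralDistribution, path_or_buf) -> None:
    """Write a spectrum as two-column CSV with a header line."""
    buf = io.StringIO()
    buf.write("wavelength_nm,value\n")
    for w, v in zip(spd.wavelengths, spd.values):
        buf.write(f"{w:.6g},{v:.10g}\n")
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(buf.getvalue())
    else:
        with open(path_or_buf, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())


def read_cgats(path_or_buf) -> "pd.DataFrame":
    """Parse a CGATS.17-style measurement block into a DataFrame.

    Supports the subset emitted by i1Pro-class instruments: a
    ``BEGIN_DATA_FORMAT``/``END_DATA_FORMAT`` field list followed by a
    ``BEGIN_DATA``/``END_DATA`` table. Spectral fields named
    ``SPECTRAL_NM_<wl>`` (or ``nm<wl>``) become float columns like any
    other field; the caller assembles spectra from them.
    """
    import pandas as pd

    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf, "r", encoding="utf-8") as fh:
            text = fh.read()
    fmt = re.search(r"BEGIN_DATA_FORMAT\s*(.*?)\s*END_DATA_FORMAT", text, re.S)
    dat = re.search(r"BEGIN_DATA(?!_FORMAT)\s*(.*?)\s*END_DATA(?!_FORMAT)",
                    text, re.S)
    if fmt is None or dat is None:
        raise ValueError("not a CGATS block: missing DATA_FORMAT or DATA section")
    fields = fmt.group(1).split()
    rows = []
    for line in dat.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != len(fields):
            raise ValueError(
                f"CGATS row has {len(parts)} fields, expected {len(fields)}: {line!r}"
            )
        rows.append(parts)
    df = pd.DataFrame(rows, columns=fields)
    for col in df.columns:
        try:
            df[col] = df[col].astype(float)
        except ValueError:
            pass
    return df


def spectral_columns(df, prefix: str = "SPECTRAL_NM_"):
    """Extract (wavelengths, matrix) from CGATS spectral columns."""
    cols = [c for c in df.columns if c.startswith(prefix) or re.fullmatch(r"nm\d+", c)]
    if not cols:
        raise ValueError("no spectral columns found")
    wls = np.array([float(re.search(r"(\d+\.?\d*)$", c).group(1)) for c in cols])
    order = np.argsort(wls)
    return wls[order], df[[cols[i] for i in order]].to_numpy(dtype=float)
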