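"""Spectral stabilization of a multi-channel LED panel under thermal drift.

Model: the panel output is the linear superposition of its channels,
``S(lambda) = sum_i I_i S_i(lambda)``, with ``S_i`` the full-drive
channel SPD at the reference temperature and ``I_i`` in [0, 1] the drive
levels. Heat-up attenuates channel output and shifts peaks toward longer
wavelengths. Rather than requiring a full thermal characterization, the
drift is summarized per channel by an intensity offset ``dI_i`` and a
wavelength offset ``dlam_i``:

    S_drifted(lambda) ~= sum_i (I_i + dI_i) S_i(lambda + dlam_i)

estimated from a *single* measurement M of the panel output by
minimizing the squared spectral mismatch over (dI, dlam). The corrected
drives then minimize the mismatch of the deviated model to the target
spectrum, subject to the box constraint I in [0, 1]. Iterating
measure -> estimate -> re-solve -> apply forms the closed loop.

All integrals run over the visible band 380-780 nm on a 1 nm grid; the
squared-mismatch objective (MSE) is the default, with a mean-absolute
alternative behind a flag (solved by iteratively reweighted least
squares).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .colorimetry import Observer, delta_e00, delta_e76, illuminance, xyz_to_lab
from .spectral import VIS_GRID, SpectralDistribution

__all__ = [
    "ChannelBasis",
    "ThermalDeviation",
    "StabilizationTrace",
    "predict_output",
    "solve_drives",
    "estimate_deviation",
    "update_drives",
    "stabilize",
    "spd_metrics",
]

DLAM_MAX = 10.0   # nm; search range for per-channel wavelength offsets
DLAM_STEP = 0.1   # nm; scan resolution


@dataclass(frozen=True)
class ChannelBasis:
    """Per-channel full-drive SPDs at the reference temperature, one grid."""

    wavelengths: np.ndarray     # (n_wl,), uniform
    spds: np.ndarray            # (L, n_wl), nonnegative
    labels: tuple = ()

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        S = np.asarray(self.spds, dtype=float)
        if S.ndim != 2 or S.shape[1] != wl.size:
            raise ValueError("spds must have shape (n_channels, n_wl)")
        if np.any(S < -1e-9):
            raise ValueError("channel SPDs must be nonnegative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "spds", np.clip(S, 0.0, None))
        if not self.labels:
            object.__setattr__(self, "labels",
                               tuple(f"ch{i}" for i in range(len(S))))

    @property
    def n_channels(self) -> int:
        return self.spds.shape[0]

    @classmethod
    def measure_from_panel(cls, panel, spectro=None, T: float = 30.0,
                           grid=None) -> "ChannelBasis":
        """Characterize a panel-like rig channel by channel at full drive."""
        grid = VIS_GRID if grid is None else np.asarray(grid, dtype=float)
        rows = []
        labels = []
        for i in range(panel.n_channels):
            drives = np.zeros(panel.n_channels)
            drives[i] = 1.0
            spd = panel.output(drives, T)
            if spectro is not None:
                spd = spectro.measure(spd)
            rows.append(np.interp(grid, spd.wavelengths, spd.values,
                                  left=0.0, right=0.0))
            labels.append(getattr(panel.channels[i], "label", f"ch{i}"))
        return cls(grid, np.asarray(rows), tuple(labels))

    def shifted(self, dlam) -> np.ndarray:
        """Channel matrix with each base SPD evaluated at lambda + dlam_i
        (linear interpolation, zero beyond the band edges)."""
        dlam = np.asarray(dlam, dtype=float)
        out = np.empty_like(self.spds)
        for i, d in enumerate(dlam):
            if d == 0.0:
                out[i] = self.spds[i]
            else:
                out[i] = np.interp(self.wavelengths + d, self.wavelengths,
                                   self.spds[i], left=0.0, right=0.0)
        return out


@dataclass(frozen=True)
class ThermalDeviation:
    """Per-channel intensity and wavelength offsets summarizing drift."""

    dI: np.ndarray
    dlam: np.ndarray           # nm

    def __post_init__(self):
        dI = np.asarray(self.dI, dtype=float)
        dlam = np.asarray(self.dlam, dtype=float)
        if dI.shape != dlam.shape:
            raise ValueError("dI and dlam must have matching shapes")
        if np.any(np.abs(dlam) > DLAM_MAX + 1e-9):
            raise ValueError(f"|dlam| must not exceed {DLAM_MAX} nm")
        object.__setattr__(self, "dI", dI)
        object.__setattr__(self, "dlam", dlam)

    @classmethod
    def zero(cls, n: int) -> "ThermalDeviation":
        return cls(np.zeros(n), np.zeros(n))


def _as_values(spd, basis: ChannelBasis) -> np.ndarray:
    if isinstance(spd, SpectralDistribution):
        if np.array_equal(spd.wavelengths, basis.wavelengths):
            return spd.values
        if spd.pitch > 1.5 * (basis.wavelengths[1] - basis.wavelengths[0]):
            # instrument-pitch readings are upsampled with an Akima spline,
            # which restores peak curvature far better than linear segments
            from scipy.interpolate import Akima1DInterpolator

            lo, hi = spd.wavelengths[0], spd.wavelengths[-1]
            out = Akima1DInterpolator(spd.wavelengths, spd.values)(
                np.clip(basis.wavelengths, lo, hi))
            out[(basis.wavelengths < lo) | (basis.wavelengths > hi)] = 0.0
            return np.clip(out, 0.0, None)
        return np.interp(basis.wavelengths, spd.wavelengths, spd.values,
                         left=0.0, right=0.0)
    return np.asarray(spd, dtype=float)


def predict_output(basis: ChannelBasis, drives,
                   deviation: ThermalDeviation | None = None) -> SpectralDistribution:
    """Superposition of (I_i + dI_i) S_i(lambda + dlam_i); effective drives
    are clipped at zero from below."""
    drives = np.asarray(drives, dtype=float)
    if np.any(drives < -1e-12) or np.any(drives > 1 + 1e-12):
        raise ValueError("drive levels must lie in [0, 1]")
    if deviation is None:
        vals = drives @ basis.spds
    else:
        eff = np.clip(drives + deviation.dI, 0.0, None)
        vals = eff @ basis.shifted(deviation.dlam)
    return SpectralDistribution(basis.wavelengths, np.clip(vals, 0.0, None))


def _solve_box(A, b, lo, hi, objective="mse"):
    if objective == "mse":
        return lsq_linear(A, b, bounds=(lo, hi), method="bvls").x
    if objective == "mae":
        # exact L1 fit as a linear program: min sum(t), -t <= Ax - b <= t
        from scipy.optimize import linprog

        m, n = A.shape
        c = np.concatenate([np.zeros(n), np.ones(m)])
        A_ub = np.block([[A, -np.eye(m)], [-A, -np.eye(m)]])
        b_ub = np.concatenate([b, -b])
        bounds = [(l, h) for l, h in zip(np.atleast_1d(lo) * np.ones(n),
                                         np.atleast_1d(hi) * np.ones(n))]
        bounds += [(0, None)] * m
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
        if not res.success:
            raise RuntimeError(f"L1 drive solve failed: {res.message}")
        return res.x[:n]
    raise ValueError(f"unknown objective {objective!r}")


def solve_drives(target, basis: ChannelBasis, objective: str = "mse") -> np.ndarray:
    """Box-constrained least-squares drive levels matching a target SPD.

    Minimizes the integrated squared mismatch between the target and the
    channel superposition with I in [0, 1]^L.
    """
    b = _as_values(target, basis)
    A = basis.spds.T
    x = _solve_box(A, b, np.zeros(basis.n_channels), np.ones(basis.n_channels),
                   objective)
    return np.clip(x, 0.0, 1.0)


def _residual(A, coef, b):
    return float(np.mean((A @ coef - b) ** 2))


def estimate_deviation(measured, drives, basis: ChannelBasis,
                       dlam_max: float = DLAM_MAX, dlam_step: float = DLAM_STEP,
                       sweeps: int = 2,
                       warm_start: ThermalDeviation | None = None) -> ThermalDeviation:
    """Estimate (dI, dlam) from a single output measurement.

    The squared-mismatch objective is nonconvex in dlam and riddled with
    local minima when neighboring channels overlap (one channel's shift
    can be absorbed by its neighbors' amplitudes). The search therefore
    runs in two stages:

    1. *Common-mode stage*: thermal shift moves every affected channel
       the same way, so a single shared shift offset applied to all
       active channels is scanned first — this steps over the
       misattribution minima that trap purely per-channel searches.
    2. *Per-channel refinement*: block-coordinate descent over each
       active channel's shift (coarse 1 nm scan within +-dlam_max, or a
       +-2 nm trust region around ``warm_start`` when tracking a slowly
       drifting run, then dlam_step resolution around the winner). Every
       candidate is scored by a joint nonnegative least-squares refit of
       all channel amplitudes, so each accepted move lowers the true
       residual and the scheme cannot diverge.

    The final nonnegative amplitudes J give dI = J - I. Channels at zero
    drive emit nothing: they are excluded from the fit, their dI is
    reported as zero and their shift is carried over from ``warm_start``.
    """
    from scipy.optimize import nnls

    drives = np.asarray(drives, dtype=float)
    M = _as_values(measured, basis)
    L = basis.n_channels
    active = np.flatnonzero(drives > 0)
    if active.size == 0:
        warnings.warn("all drives are zero; returning zero deviation",
                      stacklevel=2)
        return ThermalDeviation.zero(L)

    wl = basis.wavelengths

    def col(c, s):
        if s == 0.0:
            return basis.spds[c]
        return np.interp(wl + s, wl, basis.spds[c], left=0.0, right=0.0)

    dlam = np.zeros(L)
    if warm_start is not None:
        dlam = np.clip(np.asarray(warm_start.dlam, dtype=float).copy(),
                       -dlam_max, dlam_max)

    def rss_at(dl):
        A = np.stack([col(a, dl[a]) for a in active], axis=1)
        return nnls(A, M)[1]

    # stage 1: shared shift offset over the active channels
    best_d, best_r = 0.0, rss_at(dlam)
    for d in np.arange(-5.0, 5.0 + 0.25, 0.5):
        trial = dlam.copy()
        trial[active] = np.clip(dlam[active] + d, -dlam_max, dlam_max)
        r = rss_at(trial)
        if r < best_r - 1e-15:
            best_d, best_r = d, r
    dlam[active] = np.clip(dlam[active] + best_d, -dlam_max, dlam_max)

    cols = {c: col(c, dlam[c]) for c in active}

    def joint_rss(c, s):
        """Residual with channel c at shift s, all amplitudes refit >= 0."""
        A = np.stack([cols[a] if a != c else col(c, s) for a in active], axis=1)
        _, r = nnls(A, M)
        return r

    # stage 2: per-channel refinement
    full_coarse = np.arange(-dlam_max, dlam_max + 0.5, 1.0)
    for _ in range(sweeps):
        for c in active:
            if warm_start is None:
                coarse = full_coarse
            else:
                coarse = np.clip(np.arange(dlam[c] - 2.0, dlam[c] + 2.01, 0.5),
                                 -dlam_max, dlam_max)
            best_s = dlam[c]
            best_r = joint_rss(c, best_s)
            for s in coarse:
                r = joint_rss(c, s)
                # epsilon bias toward zero shift keeps degenerate channels tame
                if r + 1e-12 * s * s < best_r + 1e-12 * best_s * best_s:
                    best_s, best_r = s, r
            fine = np.arange(best_s - 1.0, best_s + 1.0 + dlam_step / 2, dlam_step)
            fine = fine[np.abs(fine) <= dlam_max + 1e-9]
            for s in fine:
                r = joint_rss(c, s)
                if r + 1e-12 * s * s < best_r + 1e-12 * best_s * best_s:
                    best_s, best_r = s, r
            dlam[c] = round(best_s, 10)
            cols[c] = col(c, dlam[c])

    A = np.stack([cols[a] for a in active], axis=1)
    J_act, _ = nnls(A, M)
    dI = np.zeros(L)
    dI[active] = J_act - drives[active]
    return ThermalDeviation(dI, dlam)


def update_drives(target, basis: ChannelBasis, deviation: ThermalDeviation,
                  objective: str = "mse") -> np.ndarray:
    """Re-solve drives against the deviated channel model.

    With J = I + dI the mismatch is linear in I, so this is the same
    box-constrained solve as :func:`solve_drives` on the shifted basis
    with the target pre-compensated for dI. Zero deviation reduces it to
    :func:`solve_drives` exactly.
    """
    b = _as_values(target, basis)
    A = basis.shifted(deviation.dlam).T
    b_eff = b - A @ deviation.dI
    x = _solve_box(A, b_eff, np.zeros(basis.n_channels),
                   np.ones(basis.n_channels), objective)
    return np.clip(x, 0.0, 1.0)


@dataclass
class StabilizationTrace:
    """Per-iteration record of the closed loop."""

    drives: list = field(default_factory=list)
    measured: list = field(default_factory=list)
    de00: list = field(default_factory=list)
    de76: list = field(default_factory=list)
    illuminance_ratio: list = field(default_factory=list)
    mse: list = field(default_factory=list)
    deviations: list = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.de00)

    def final_metrics(self) -> dict:
        return {"de00": self.de00[-1], "de76": self.de76[-1],
                "illuminance_ratio": self.illuminance_ratio[-1],
                "mse": self.mse[-1]}


def stabilize(panel, target, n_iter: int, basis: ChannelBasis,
              initial_drives=None, objective: str = "mse",
              observer: Observer | None = None) -> StabilizationTrace:
    """Run the closed loop: measure, estimate drift, re-solve, apply.

    ``panel`` implements the two-method contract ``measure() ->
    SpectralDistribution`` and ``set_drives(array)``. The trace records,
    for each iteration, the metrics of the *measured* output before the
    corrective update, plus one final post-correction measurement.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    target_vals = _as_values(target, basis)
    target_spd = SpectralDistribution(basis.wavelengths, target_vals)
    if initial_drives is None:
        initial_drives = solve_drives(target_spd, basis, objective)
        panel.set_drives(initial_drives)
    drives = np.asarray(initial_drives, dtype=float)
    trace = StabilizationTrace()

    def record(meas_spd, dev):
        m = spd_metrics(meas_spd, target_spd, observer=observer)
        trace.drives.append(drives.copy())
        trace.measured.append(meas_spd)
        trace.de00.append(m["de00"])
        trace.de76.append(m["de76"])
        trace.illuminance_ratio.append(m["illuminance_ratio"])
        trace.mse.append(m["mse"])
        trace.deviations.append(dev)

    prev_dev = None
    for it in range(n_iter):
        try:
            measured = panel.measure()
        except Exception as exc:
            raise RuntimeError(f"panel measurement failed at iteration {it}") from exc
        dev = estimate_deviation(measured, drives, basis, warm_start=prev_dev)
        prev_dev = dev
        drives = update_drives(target_spd, basis, dev, objective)
        try:
            panel.set_drives(drives)
        except Exception as exc:
            raise RuntimeError(f"drive update failed at iteration {it}") from exc
        record(SpectralDistribution(
            basis.wavelengths, _as_values(measured, basis)), dev)
    # post-correction measurement closes the books on the run
    final = panel.measure()
    record(SpectralDistribution(basis.wavelengths, _as_values(final, basis)),
           trace.deviations[-1])
    return trace


def spd_metrics(measured, target, observer: Observer | None = None) -> dict:
    """Colorimetric and photometric mismatch between two SPDs.

    Both spectra are converted to XYZ with one normalization constant
    anchored to the target (target Y = 100), so intensity loss shows up
    as a lightness difference; CIEDE2000/CIEDE76 are computed on the
    resulting Lab pairs with the target as the adapted white. Also
    reports the illuminance ratio and the mean squared spectral error.
    """
    obs = observer if observer is not None else Observer.default()
    if isinstance(measured, SpectralDistribution) and isinstance(
            target, SpectralDistribution):
        grid = target.wavelengths
        mv = np.interp(grid, measured.wavelengths, measured.values,
                       left=0.0, right=0.0)
        tv = target.values
    else:
        raise TypeError("spd_metrics expects SpectralDistribution inputs")
    if not np.any(tv > 0):
        raise ValueError("target SPD is identically zero")
    cmfs = np.stack([np.interp(grid, obs.wavelengths, obs.cmfs[:, i],
                               left=0.0, right=0.0) for i in range(3)], axis=-1)
    dl = grid[1] - grid[0]
    k = 100.0 / (np.sum(tv * cmfs[:, 1]) * dl)
    xyz_t = k * (tv @ cmfs) * dl
    xyz_m = k * (mv @ cmfs) * dl
    lab_t = xyz_to_lab(xyz_t, xyz_t)       # (100, 0, 0) by construction
    lab_m = xyz_to_lab(xyz_m, xyz_t)
    mspd = SpectralDistribution(grid, np.clip(mv, 0.0, None))
    tspd = SpectralDistribution(grid, tv)
    return {
        "de00": float(delta_e00(lab_m, lab_t)),
        "de76": float(delta_e76(lab_m, lab_t)),
        "illuminance_ratio": illuminance(mspd, obs) / illuminance(tspd, obs),
        "mse": float(np.mean((mv - tv) ** 2)),
    }
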