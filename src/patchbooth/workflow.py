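"""End-to-end pipeline stages on the synthetic rigs.

These functions glue the library modules together the way an
experimenter would: characterize the printer from charts, build the
tabulated space, spread reference patches through the joint coverage,
generate pairs, "print" and "measure" them, and run the LED
stabilization scenario. The command-line interface and the acceptance
checks are thin wrappers over these.
"""

from __future__ import annotations

import numpy as np

from . import colorimetry as cm
from . import ledpanel, patches, printer, rigs, tabspace
from .config import RunConfig

__all__ = [
    "measure_chart_xyz",
    "characterize_printer",
    "build_design_space",
    "select_reference_patches",
    "generate_and_measure_pairs",
    "stabilization_scenario",
]


def measure_chart_xyz(vp: rigs.VirtualPrinter, chart: printer.Chart,
                      obs: cm.Observer) -> np.ndarray:
    """Print a chart on the virtual printer and integrate each measured
    reflectance to XYZ under the observer's reference illuminant."""
    spds = vp.print_and_measure(chart.patches)
    return np.array([cm.spd_to_xyz(s, obs, mode="reflective") for s in spds])


def characterize_printer(cfg: RunConfig, vp: rigs.VirtualPrinter | None = None,
                         obs: cm.Observer | None = None, select: bool = False):
    """Charts -> virtual print/measure -> forward model (+ profile).

    Returns ``(model, profile, score_table)``; the score table is None
    unless ``select`` runs the full model selection.
    """
    obs = obs or cm.Observer.default()
    vp = vp or rigs.VirtualPrinter(noise_sigma=cfg.printer_rig.noise_sigma,
                                   gamma=cfg.printer_rig.gamma, seed=cfg.seed)
    train, test = printer.make_charts(cfg.charts.train_n, cfg.charts.test_n)
    train_xyz = measure_chart_xyz(vp, train, obs)
    test_xyz = measure_chart_xyz(vp, test, obs)
    table = None
    if select:
        model, table = printer.select_model(train, train_xyz, test, test_xyz,
                                            cfg.model.smoothing_grid, obs)
        kernel = model.kernel
        space = model.target_space
        smoothing = model.smoothing
    else:
        kernel, space, smoothing = (cfg.model.kernel, cfg.model.target_space,
                                    cfg.model.smoothing)
        model = printer.fit_forward(train, train_xyz, kernel, space, smoothing, obs)
    profile = printer.make_profile(train, train_xyz, test, test_xyz,
                                   kernel, space, smoothing, obs)
    return model, profile, table


def build_design_space(cfg: RunConfig, model: printer.PrinterForwardModel):
    """Tabulated grid + Lab gamut + joint tab-space membership predicate."""
    grid = tabspace.build_tab_grid(center=cfg.tab_grid.center,
                                   step_de=cfg.tab_grid.step_de,
                                   radius_nodes=cfg.tab_grid.radius,
                                   max_sweeps=cfg.tab_grid.max_sweeps)
    gamut = printer.compute_gamut(model, cfg.model.backward_sampling, "CIELAB")

    def in_design_space(tab_pts) -> np.ndarray:
        """A tab point is usable if the grid covers it and its Lab image
        prints (lies inside the printer gamut)."""
        tab_pts = np.atleast_2d(np.asarray(tab_pts, dtype=float))
        ok = np.atleast_1d(grid.in_extent(tab_pts)).copy()
        if np.any(ok):
            labs = tabspace.tab_to_lab(tab_pts[ok], grid)
            ok[np.flatnonzero(ok)] = np.atleast_1d(gamut.mesh.contains(labs))
        return ok

    return grid, gamut, in_design_space


def select_reference_patches(cfg: RunConfig, grid, in_design_space):
    """N reference colors by Kepler stacking at the max spacing."""
    if cfg.stack.center == "gamut-centroid":
        # centroid of the usable region, located by rejection sampling on
        # the grid extent (deterministic)
        lo, hi = grid.extent
        rng = np.random.default_rng(cfg.seed + 101)
        pts = rng.uniform(lo, hi, size=(4096, 3))
        ok = in_design_space(pts)
        center = pts[ok].mean(axis=0) if np.any(ok) else np.zeros(3)
    else:
        center = np.asarray(cfg.stack.center, dtype=float)
    if not in_design_space(center[None])[0]:
        center = np.zeros(3)   # the tab origin is in coverage by construction
    lo, hi = grid.extent
    ceiling = float(np.linalg.norm(hi - lo))
    refs, D = patches.select_references(in_design_space, center,
                                        cfg.stack.n_refs,
                                        tol=cfg.stack.spacing_tol,
                                        ceiling=ceiling)
    return refs, D, center


def generate_and_measure_pairs(cfg: RunConfig, refs_tab, grid, in_design_space,
                               model: printer.PrinterForwardModel,
                               backward: printer.BackwardModel,
                               vp: rigs.VirtualPrinter,
                               obs: cm.Observer | None = None):
    """Pairs -> virtual print -> measured CIEDE2000 -> banding/filtering.

    Measurement emulates the 3-consecutive x 5-location scheme per patch.
    Returns ``(pairs, retained, outliers, summary)``.
    """
    obs = obs or cm.Observer.default()
    spec = patches.PairSamplingSpec(mu=cfg.pairs.mu, sigma=cfg.pairs.sigma,
                                    per_ref=cfg.pairs.per_ref, seed=cfg.seed)
    pairs = patches.generate_pair_set(refs_tab, spec, backward, grid,
                                      in_gamut=in_design_space)
    white = obs.white_xyz()

    def measure_patch(rgb):
        readings = [[vp.print_and_measure(rgb) for _ in range(3)]
                    for _ in range(5)]
        agg = patches.aggregate_measurements(readings)
        return cm.xyz_to_lab(cm.spd_to_xyz(agg, obs, mode="reflective"), white)

    for p in pairs:
        lab_ref = measure_patch(p.ref_rgb)
        lab_rel = measure_patch(p.rel_rgb)
        p.measured_de00 = float(cm.delta_e00(lab_ref, lab_rel))
    retained, outliers, summary = patches.band_and_filter(
        pairs, cfg.pairs.outlier_threshold)
    return pairs, retained, outliers, summary


def stabilization_scenario(cfg: RunConfig, corrected: bool = True):
    """The thermal-drift scenario: characterize the panel at the start
    temperature, solve a metamer of the target illuminant, ramp the
    temperature, and either run the closed loop or hold drives fixed.

    Returns a dict with the basis, target, drives, the trace (if
    corrected) and the uncorrected end-temperature metrics.
    """
    panel = rigs.VirtualPanel.from_thermal_table()
    basis = ledpanel.ChannelBasis.measure_from_panel(panel, T=cfg.panel.t_start)
    ill = (cm.d65_spd() if cfg.panel.target == "D65" else cm.illuminant_a_spd())
    target_shape = ill * (1.0 / ill.values.max())
    drives0 = ledpanel.solve_drives(target_shape, basis)
    target = ledpanel.predict_output(basis, drives0)

    uncorrected = ledpanel.spd_metrics(
        panel.output(drives0, cfg.panel.t_end), target)
    out = {"panel": panel, "basis": basis, "target": target,
           "initial_drives": drives0, "uncorrected": uncorrected}
    if corrected:
        schedule = np.linspace(cfg.panel.t_start, cfg.panel.t_end,
                               cfg.panel.n_steps)
        spectro = rigs.VirtualSpectroradiometer(
            sigma_mult=cfg.panel.spectro_sigma_mult, seed=cfg.seed + 7)
        session = rigs.VirtualPanelSession(panel, schedule=schedule,
                                           spectro=spectro, drives=drives0)
        trace = ledpanel.stabilize(session, target, cfg.panel.n_steps,
                                   basis, initial_drives=drives0)
        out["trace"] = trace
        out["stabilized"] = trace.final_metrics()
    return out
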