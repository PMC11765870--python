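"""Shared fixtures: a small tabulated grid and a characterized virtual
printer, built once per session (construction dominates test runtime)."""

import numpy as np
import pytest

from patchbooth import colorimetry as cm
from patchbooth import printer as pr
from patchbooth import rigs
from patchbooth.tabspace import build_tab_grid


@pytest.fixture(scope="session")
def observer():
    return cm.Observer.default()


@pytest.fixture(scope="session")
def small_grid():
    """Radius-5 tabulated grid at the standard 0.5 step."""
    return build_tab_grid(center=(50.0, 0.0, 0.0), step_de=0.5,
                          radius_nodes=(5, 5, 5), max_sweeps=300)


@pytest.fixture(scope="session")
def noiseless_printer():
    return rigs.VirtualPrinter(noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def chart_measurements(noiseless_printer, observer):
    train, test = pr.make_charts()
    def meas(chart):
        spds = noiseless_printer.print_and_measure(chart.patches)
        return np.array([cm.spd_to_xyz(s, observer, mode="reflective")
                         for s in spds])
    return train, meas(train), test, meas(test)


@pytest.fixture(scope="session")
def forward_model(chart_measurements, observer):
    train, train_xyz, _, _ = chart_measurements
    return pr.fit_forward(train, train_xyz, "cubic", "CIEXYZ", 0.0, observer)


@pytest.fixture(scope="session")
def backward_model(forward_model):
    return pr.build_backward(forward_model, sampling_n=17, space="CIELAB")


@pytest.fixture(scope="session")
def lab_gamut(forward_model):
    return pr.compute_gamut(forward_model, sampling_n=17, space="CIELAB")


@pytest.fixture(scope="session")
def panel():
    return rigs.VirtualPanel.from_thermal_table()


@pytest.fixture(scope="session")
def channel_basis(panel):
    from patchbooth.ledpanel import ChannelBasis

    return ChannelBasis.measure_from_panel(panel, T=30.0)
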