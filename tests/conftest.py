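"""Shared fixtures: one medium-scale synthetic recording reused across
the decoder, neural-image, information and characterization tests."""

from __future__ import annotations

import numpy as np
import pytest

from retinotrack.decoding import LinearDecoder
from retinotrack.retina import (
    PopulationConfig,
    encode,
    make_population,
    salamander_like_trajectory_params,
)
from retinotrack.trajectory import BarGeometry, simulate_spring_ou

BIN = 1.0 / 60.0


@pytest.fixture(scope="session")
def medium_run():
    """60-cell, 15-minute synthetic recording with its fitted decoder."""
    params = salamander_like_trajectory_params(duration=900.0, seed=11)
    traj = simulate_spring_ou(params).resample(BIN)
    cells = make_population(PopulationConfig(n_cells=60, seed=5))
    spikes = encode(traj, BarGeometry(), cells, seed=7)
    model = LinearDecoder(spikes, traj)
    return dict(traj=traj, cells=cells, spikes=spikes, model=model,
                geometry=BarGeometry())


@pytest.fixture(scope="session")
def medium_fit(medium_run):
    return medium_run["model"].fit()


@pytest.fixture(scope="session")
def small_run():
    """20-cell, 5-minute recording for cheap structural tests."""
    params = salamander_like_trajectory_params(duration=300.0, seed=21)
    traj = simulate_spring_ou(params).resample(BIN)
    cells = make_population(PopulationConfig(n_cells=20, span=1000.0, seed=3))
    spikes = encode(traj, BarGeometry(), cells, seed=4)
    return dict(traj=traj, cells=cells, spikes=spikes,
                geometry=BarGeometry())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
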