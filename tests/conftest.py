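"""Shared fixtures: small deterministic paths and the (expensive) simulated
validation batteries, computed once per session and shared across tests."""

from __future__ import annotations

import numpy as np
import pytest

import arscape as a

#: seeds of the 30-run validation batteries
BATTERY_SEEDS = tuple(range(30))


@pytest.fixture
def straight_path():
    """Unit-speed straight line along x, 101 fixes."""
    t = np.arange(101, dtype=float)
    return a.Trajectory(t, t.copy(), np.zeros_like(t))


@pytest.fixture
def random_walk():
    """Gaussian random walk, 200 fixes, irregular time steps."""
    rng = np.random.default_rng(42)
    steps = rng.normal(0.0, 1.0, (200, 2)).cumsum(axis=0)
    t = np.cumsum(rng.uniform(0.5, 1.5, 200))
    return a.Trajectory(t, steps[:, 0], steps[:, 1])


def _battery(name):
    return [a.scenario_analysis(name, s) for s in BATTERY_SEEDS]


@pytest.fixture(scope="session")
def battery_search_scattered():
    return _battery("simple_search_scattered")


@pytest.fixture(scope="session")
def battery_ars_patchy():
    return _battery("simple_ars_patchy")


@pytest.fixture(scope="session")
def battery_ars_hierarchical():
    return _battery("simple_ars_hierarchical")


@pytest.fixture(scope="session")
def battery_hier_hier():
    return _battery("hierarchical_ars_hierarchical")
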