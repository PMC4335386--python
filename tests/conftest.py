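"""Shared fixtures; the expensive default-configuration runs are session-scoped."""

from __future__ import annotations

import pytest

from spinefem.geometry import build_base_geometry
from spinefem.morphogenesis import (
    PROCESS_NAMES,
    ProcessSchedule,
    poisson_sweep,
    run_ablation,
    run_simulation,
)

#: default production resolution (um) used by the acceptance-level fixtures
MESH_SIZE = 3.5
#: coarse settings for fast unit tests of the simulation loop
COARSE = dict(mesh_size=4.0, n_steps=8)


@pytest.fixture(scope="session")
def default_geometry():
    return build_base_geometry()


@pytest.fixture(scope="session")
def default_schedule():
    return ProcessSchedule()


@pytest.fixture(scope="session")
def full_trajectory(default_geometry, default_schedule):
    """The default full three-process simulation (50 increments)."""
    return run_simulation(default_geometry, default_schedule, mesh_size=MESH_SIZE)


@pytest.fixture(scope="session")
def ablation_trajectories(default_geometry, default_schedule):
    """One default-resolution run per disabled process."""
    return {
        which: run_ablation(
            default_geometry, default_schedule, which, mesh_size=MESH_SIZE
        )
        for which in PROCESS_NAMES
    }


@pytest.fixture(scope="session")
def poisson_frame(default_geometry, default_schedule):
    return poisson_sweep(
        default_geometry, [0.2, 0.3, 0.4], default_schedule, mesh_size=MESH_SIZE
    )


@pytest.fixture(scope="session")
def coarse_trajectory(default_geometry, default_schedule):
    return run_simulation(default_geometry, default_schedule, **COARSE)
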