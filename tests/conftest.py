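"""Shared fixtures: small simulation specs and session-scoped trajectories.

Everything is generated at test time; nothing binary ships with the repo.
The "small" LJ system (N=76 in a 12 Å box with 4.5/5.5 Å switching) is the
work-horse: same solvent density and temperature as the reference neon
system, shrunk so a Metropolis sweep costs microseconds.
"""

from __future__ import annotations

import numpy as np
import pytest

from solventropy.engine import (
    NEON,
    SimulationSpec,
    Species,
    mc_nvt_independent_frames,
    mc_nvt_sample,
)
from solventropy.trajectory import Trajectory

SMALL_BOX = 12.0
SMALL_N = 76  # matches the reference solvent density 0.0438 / Å^3
TEMPERATURE = 25.0


def small_spec(
    eps_solute: float | None = None,
    n: int = SMALL_N,
    burn_in: int = 500,
    box: float = SMALL_BOX,
) -> SimulationSpec:
    solute = Species(eps_solute, 3.06) if eps_solute is not None else None
    return SimulationSpec(
        box_edge=box,
        temperature=TEMPERATURE,
        solvent=NEON,
        solvent_count=n,
        solute=solute,
        cutoff_on=4.5,
        cutoff_off=5.5,
        burn_in_sweeps=burn_in,
    )


@pytest.fixture(scope="session")
def sol1_small_traj() -> Trajectory:
    """Decorrelated frames of the weakest-solute small system (F=120)."""
    return mc_nvt_independent_frames(small_spec(0.215), 120, seed=901)


@pytest.fixture(scope="session")
def bulk_small_traj() -> Trajectory:
    """Decorrelated frames of the bulk small system (F=120)."""
    return mc_nvt_independent_frames(small_spec(None), 120, seed=902)


@pytest.fixture(scope="session")
def ideal_gas_traj() -> Trajectory:
    """Uniform ideal-gas frames (exactly independent, drawn directly)."""
    rng = np.random.default_rng(903)
    coords = rng.uniform(0.0, SMALL_BOX, size=(400, SMALL_N, 3))
    return Trajectory(coords, SMALL_BOX)
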