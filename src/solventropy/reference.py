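"""Published benchmark inputs for the fixed-LJ-solute-in-neon system.

Four solute strengths (2.5x to 10x the neon well depth) around a common
solvent.  ``SYSTEMS`` carries the force-field / cell parameters; ``BENCHMARK``
carries the published per-solute free-energy table (kcal/mol) used by the
table-replay mode, which exercises the assembly and comparison arithmetic
without any simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SoluteSystem", "BenchmarkRow", "SYSTEMS", "BENCHMARK", "NEON_EPSILON", "NEON_RMIN"]

#: bulk-neon LJ well depth (kcal/mol); the SOL1 solute is 2.5x this value
NEON_EPSILON = 0.086
#: LJ radius of minimum energy shared by solvent and all solutes (Å)
NEON_RMIN = 3.06
#: simulation temperature (K)
TEMPERATURE = 25.0
#: equilibration pressure (atm)
PRESSURE = 1.0


@dataclass(frozen=True)
class SoluteSystem:
    """Cell parameters for one solute strength."""

    name: str
    epsilon_s: float  # kcal/mol
    r_min: float  # Å
    box_edge: float  # Å (NpT-equilibrated edge)
    density: float  # solvent atoms / Å^3


@dataclass(frozen=True)
class BenchmarkRow:
    """Published mean free-energy results for one solute (kcal/mol).

    ``t_ds2_correction_bound`` is an upper bound on the magnitude of the
    pair-correlation correction (reported only as below threshold).
    """

    name: str
    da_fep: float
    du: float
    t_ds1: float
    t_ds2_correction_bound: float
    da1: float
    da2: float


SYSTEMS = {
    "SOL1": SoluteSystem("SOL1", 0.215, NEON_RMIN, 27.3760, 0.04382),
    "SOL2": SoluteSystem("SOL2", 0.430, NEON_RMIN, 27.3710, 0.04384),
    "SOL3": SoluteSystem("SOL3", 0.645, NEON_RMIN, 27.3707, 0.04384),
    "SOL4": SoluteSystem("SOL4", 0.860, NEON_RMIN, 27.3685, 0.04385),
}

BENCHMARK = {
    "SOL1": BenchmarkRow("SOL1", 1.036, -1.717, -0.541, 1e-4, 1.176, 1.176),
    "SOL2": BenchmarkRow("SOL2", 1.820, -2.561, -0.589, 1e-4, 1.972, 1.972),
    "SOL3": BenchmarkRow("SOL3", 2.438, -3.257, -0.694, 1e-4, 2.563, 2.563),
    "SOL4": BenchmarkRow("SOL4", 2.975, -3.839, -0.773, 1e-4, 3.067, 3.067),
}
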