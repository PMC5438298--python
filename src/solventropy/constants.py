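"""Physical constants, unit conversions, and reduced-unit transforms.

Only one unit system is supported throughout the package: energies in
kcal/mol, lengths in Å, temperatures in K, and pressures in atm.  The
Boltzmann constant is expressed in molar units so that ``KB`` and the gas
constant ``R`` coincide numerically; entropies returned anywhere in the
package are therefore molar quantities and must not be rescaled again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "R_GAS",
    "KB",
    "ATM_TO_KCAL_PER_MOL_A3",
    "PhysicalConstants",
    "ReducedState",
    "CONSTANTS",
    "sigma_from_rmin",
    "rmin_from_sigma",
    "reduced_temperature",
    "reduced_pressure",
    "reduced_length",
    "reduced_density",
    "reduced_state",
]

#: Gas constant in kcal/(mol K).
R_GAS: float = 0.0019872

#: Boltzmann constant in molar units, numerically identical to ``R_GAS``.
KB: float = R_GAS

#: 1 atm expressed in kcal/(mol Å^3):  101325 Pa * N_A * 1e-30 m^3/Å^3 / 4184 J/kcal.
ATM_TO_KCAL_PER_MOL_A3: float = 101325.0 * 6.02214076e23 * 1e-30 / 4184.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Registry of the physical constants used across the package."""

    gas_constant_R: float = R_GAS
    boltzmann_kB: float = KB
    atm_to_kcal_per_mol_A3: float = ATM_TO_KCAL_PER_MOL_A3


#: Singleton constant registry, importable by config and CLI layers.
CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class ReducedState:
    """Dimensionless (corresponding-states) description of an LJ state point."""

    t_star: float
    p_star: float
    l_star: float
    rho_star: float


def sigma_from_rmin(r_min: float) -> float:
    """Convert the LJ radius of minimum energy R_min to the zero-crossing sigma.

    R_min = 2**(1/6) * sigma, so sigma = R_min / 2**(1/6).
    """
    if r_min <= 0:
        raise ValueError(f"r_min must be positive, got {r_min}")
    return r_min / 2.0 ** (1.0 / 6.0)


def rmin_from_sigma(sigma: float) -> float:
    """Inverse of :func:`sigma_from_rmin`."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return sigma * 2.0 ** (1.0 / 6.0)


def reduced_temperature(temperature: float, epsilon: float) -> float:
    """T* = kB T / epsilon for a well depth ``epsilon`` in kcal/mol."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if temperature < 0:
        raise ValueError(f"temperature must be nonnegative, got {temperature}")
    return KB * temperature / epsilon

def reduced_pressure(pressure_atm: float, sigma: float, epsilon: float) -> float:
    """p* = p sigma^3 / epsilon with the pressure given in atm."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    return pressure_atm * ATM_TO_KCAL_PER_MOL_A3 * sigma**3 / epsilon


def reduced_length(length: float, sigma: float) -> float:
    """L* = L / sigma."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return length / sigma


def reduced_density(number_density: float, sigma: float) -> float:
    """rho* = rho sigma^3 for a number density in Å^-3."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return number_density * sigma**3


def reduced_state(
    temperature: float,
    pressure_atm: float,
    box_edge: float,
    n_atoms: int,
    sigma: float,
    epsilon: float,
) -> ReducedState:
    """Bundle all four reduced quantities for one simulation state point."""
    rho = n_atoms / box_edge**3
    return ReducedState(
        t_star=reduced_temperature(temperature, epsilon),
        p_star=reduced_pressure(pressure_atm, sigma, epsilon),
        l_star=reduced_length(box_edge, sigma),
        rho_star=reduced_density(rho, sigma),
    )
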