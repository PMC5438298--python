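"""Assembly of solvation/annihilation free energies from energies and entropies.

Sign conventions (fixed here, once):

* Published annihilation free energies are positive for attractive solutes,
  while the literal "dU - T dS" of the tabulated values is their negative.
  The annihilation free energy is therefore defined as

      dA_annihilation = T dS - dU,

  and the solvation (insertion) free energy is its negative.

* The KNN one-particle estimator H1 converges to  -(1/V) \\int g ln g dr,
  so the temperature-weighted one-particle entropy is

      T dS1 = T R N H1            (negative for structured fluids),

  calibrated against the RDF quadrature oracle (:func:`solventropy.rdf.s1_from_rdf`).

* The two-particle truncation adds a pair-correlation correction.  In terms
  of the raw estimator asymptotes H1, H2_solute, H2_liquid,

      T dS2_correction = -T R N (N-1) [ H1 + (H2_liquid - H2_solute)/2 ],

  which is the conditional-two-particle entropy minus the one-particle part
  (the published per-solute table reports this correction column separately;
  the full two-particle entropy is T dS1 + correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import R_GAS
from .extrapolation import EntropySeries

__all__ = [
    "SolvationResult",
    "replicate_statistics",
    "mean_energy_difference",
    "t_delta_s1_from_h1",
    "assemble_c1pe",
    "assemble_c2pe",
]


@dataclass(frozen=True)
class SolvationResult:
    """Assembled free-energy components for one solute (all kcal/mol)."""

    delta_u: float
    t_delta_s1: float
    t_delta_s2_correction: float
    delta_a1: float
    delta_a2: float
    replicate_count: int = 1
    sigma_delta_u: float = float("nan")
    sigma_delta_a1: float = float("nan")
    sigma_delta_a2: float = float("nan")


def replicate_statistics(values: Sequence[float]) -> tuple[float, float]:
    """Sample mean and sample (n-1 denominator) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"need at least 2 replicate values, got {v.size}")
    return float(np.mean(v)), float(np.std(v, ddof=1))


def mean_energy_difference(
    solute_energies: Sequence[float], bulk_energies: Sequence[float]
) -> tuple[float, float]:
    """dU = mean(solute) - mean(bulk) with a propagated naive standard error.

    The standard error treats samples as independent; correlated MC frames
    should be thinned first (or the caller should use replicate spreads).
    """
    a = np.asarray(solute_energies, dtype=float)
    b = np.asarray(bulk_energies, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("energy lists must be non-empty")
    du = float(np.mean(a) - np.mean(b))
    var = 0.0
    if a.size > 1:
        var += np.var(a, ddof=1) / a.size
    if b.size > 1:
        var += np.var(b, ddof=1) / b.size
    return du, float(math.sqrt(var))


def t_delta_s1_from_h1(h1_infinity: float, n_atoms: int, temperature: float) -> float:
    """Calibrated one-particle entropy term T dS1 = T R N H1 (kcal/mol)."""
    return temperature * R_GAS * n_atoms * h1_infinity


def assemble_c1pe(delta_u: float, t_delta_s1: float) -> float:
    """One-particle-truncation annihilation free energy: T dS1 - dU."""
    if not (math.isfinite(delta_u) and math.isfinite(t_delta_s1)):
        raise ValueError("inputs must be finite")
    return t_delta_s1 - delta_u


def pair_correction(
    h1_infinity: float,
    h2_solute_infinity: float,
    h2_liquid_infinity: float,
    n_atoms: int,
    temperature: float,
) -> float:
    """T-weighted pair-correlation correction to the one-particle entropy."""
    return (
        -temperature
        * R_GAS
        * n_atoms
        * (n_atoms - 1)
        * (h1_infinity + 0.5 * (h2_liquid_infinity - h2_solute_infinity))
    )


def _require_asymptote(series: EntropySeries, name: str) -> float:
    if series.h_infinity is None:
        raise ValueError(f"{name} series carries no extrapolated asymptote; fit it first")
    return series.h_infinity


def assemble_c2pe(
    h1: EntropySeries,
    h2_solute: EntropySeries,
    h2_liquid: EntropySeries,
    n_atoms: int,
    temperature: float,
    delta_u: float = 0.0,
    replicate_count: int = 1,
    sigma_delta_u: float = float("nan"),
    sigma_delta_a1: float = float("nan"),
    sigma_delta_a2: float = float("nan"),
) -> SolvationResult:
    """Assemble both truncation levels from extrapolated estimator series."""
    h1_inf = _require_asymptote(h1, "H1")
    h2s_inf = _require_asymptote(h2_solute, "H2(solute)")
    h2l_inf = _require_asymptote(h2_liquid, "H2(liquid)")
    t_ds1 = t_delta_s1_from_h1(h1_inf, n_atoms, temperature)
    corr = pair_correction(h1_inf, h2s_inf, h2l_inf, n_atoms, temperature)
    da1 = assemble_c1pe(delta_u, t_ds1)
    da2 = assemble_c1pe(delta_u, t_ds1 + corr)
    return SolvationResult(
        delta_u=delta_u,
        t_delta_s1=t_ds1,
        t_delta_s2_correction=corr,
        delta_a1=da1,
        delta_a2=da2,
        replicate_count=replicate_count,
        sigma_delta_u=sigma_delta_u,
        sigma_delta_a1=sigma_delta_a1,
        sigma_delta_a2=sigma_delta_a2,
    )
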