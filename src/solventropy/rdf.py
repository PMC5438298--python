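"""Radial distribution functions and the quadrature route to the one-particle entropy.

For a spherically symmetric solute fixed at the box centre, the one-particle
conditional density reduces to rho g(r) with g the solute-solvent RDF.  The
temperature-weighted one-particle solvation entropy then has the closed
quadrature form

    T dS1 = -T R rho \\int g(r) ln g(r) 4 pi r^2 dr            (0 ln 0 := 0)

evaluated by the trapezoid rule over histogram bins.  This is the package's
independent brute-force oracle for the KNN one-particle estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import R_GAS
from .trajectory import Trajectory

__all__ = ["RadialDistribution", "compute_rdf", "s1_from_rdf"]


@dataclass(frozen=True)
class RadialDistribution:
    """Histogram estimate of g(r) with its binning and reference density."""

    bin_edges: np.ndarray  # Å, len nbins+1
    g_values: np.ndarray  # dimensionless, len nbins
    kind: str  # "solute-solvent" | "solvent-solvent"
    density: float  # Å^-3 reference number density
    pair_count: int = 0  # total distances histogrammed before r_max truncation

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_mid": self.r_mid, "g": self.g_values})


def compute_rdf(
    traj: Trajectory,
    kind: str = "solute-solvent",
    bin_width: float = 0.05,
    r_max: float | None = None,
) -> RadialDistribution:
    """Minimum-image distance histogram normalised by ideal-shell counts.

    ``solute-solvent`` measures distances from the (implicit, centre-fixed)
    solute to every solvent atom; ``solvent-solvent`` measures all unordered
    solvent pairs.  Normalisation per frame divides the bin count by
    rho_pairs * (4/3) pi (r+^3 - r-^3) with the appropriate pair density.
    """
    box = traj.box_edge
    if r_max is None:
        r_max = box / 2.0
    if r_max > box / 2.0 + 1e-12:
        raise ValueError(f"r_max {r_max} exceeds half the box edge {box / 2.0}")
    if kind not in ("solute-solvent", "solvent-solvent"):
        raise ValueError(f"unknown RDF kind {kind!r}")

    f, n = traj.n_frames, traj.n_atoms
    v = box**3
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    counts = np.zeros(len(edges) - 1)

    total = 0
    if kind == "solute-solvent":
        centre = np.full(3, box / 2.0)
        for j in range(f):
            d = traj.coordinates[j] - centre
            d -= box * np.rint(d / box)
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            total += len(r)
            counts += np.histogram(r, bins=edges)[0]
        # ideal count per shell for one central reference: rho * Vshell
        per_frame_ideal = traj.n_atoms / v
    else:
        iu1, iu2 = np.triu_indices(n, 1)
        for j in range(f):
            d = traj.coordinates[j, iu1] - traj.coordinates[j, iu2]
            d -= box * np.rint(d / box)
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            total += len(r)
            counts += np.histogram(r, bins=edges)[0]
        # N(N-1)/2 unordered pairs against shell volume fraction Vshell/V
        per_frame_ideal = (n * (n - 1) / 2.0) / v

    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (f * per_frame_ideal * shell)
    return RadialDistribution(
        bin_edges=edges,
        g_values=g,
        kind=kind,
        density=traj.n_atoms / v,
        pair_count=total,
    )


def s1_from_rdf(
    rdf: RadialDistribution, density: float, temperature: float
) -> float:
    """Temperature-weighted one-particle entropy T dS1 (kcal/mol) by quadrature.

    Integrates -T R rho g ln g 4 pi r^2 over the binned range with the
    trapezoid rule on bin midpoints; g is assumed to be exactly 1 beyond the
    last bin (zero integrand).  Bins with g = 0 contribute 0 (the 0 ln 0
    limit).  Negative g values are rejected.
    """
    g = np.asarray(rdf.g_values, dtype=float)
    if np.any(g < 0):
        raise ValueError("negative g(r) values")
    r = rdf.r_mid
    integrand = np.zeros_like(g)
    pos = g > 0
    integrand[pos] = g[pos] * np.log(g[pos])
    integrand *= 4.0 * np.pi * r**2
    s1 = -R_GAS * density * np.trapezoid(integrand, r)
    return float(temperature * s1)
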