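"""Lennard-Jones energetics and Metropolis Monte Carlo sampling.

The model system is a monatomic LJ solvent in a cubic periodic box, with an
optional LJ solute pinned at the box centre.  Pair interactions use the
form  sqrt(eps_i eps_j) [ (Rbar/r)^12 - 2 (Rbar/r)^6 ]  with
Rbar = (R_i + R_j)/2  the combined radius of minimum energy, truncated by
the CHARMM cubic switching function between r_on and r_off.  Alchemical
annihilation of the solute uses a separation-shifted soft core.

Sampling is plain Metropolis MC: single-particle displacements (NVT), plus
ln-V volume moves (NpT).  MC replaces molecular dynamics deliberately — the
downstream estimators consume equilibrium configurations only, and a
"frames are decorrelated" stride contract (in sweeps) replaces an MD
frame-saving interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import _kernels as K
from .constants import KB
from .trajectory import Frame, Trajectory

__all__ = [
    "Species",
    "SimulationSpec",
    "LambdaState",
    "lj_pair_energy",
    "switched_pair_energy",
    "softcore_pair_energy",
    "total_energy",
    "initial_configuration",
    "mc_nvt_sample",
    "mc_npt_equilibrate",
    "NEON",
]


@dataclass(frozen=True)
class Species:
    """LJ parameters of one atomic species (mass is metadata only)."""

    epsilon: float  # kcal/mol, well depth
    r_min: float  # Å, radius of minimum potential energy
    mass: float = 20.18  # amu

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.r_min <= 0:
            raise ValueError(f"r_min must be > 0, got {self.r_min}")


#: Bulk neon solvent parameters used by the reference system.
NEON = Species(epsilon=0.086, r_min=3.06)


@dataclass(frozen=True)
class LambdaState:
    """Degree of solute annihilation: 0 = fully present, 1 = fully annihilated."""

    lam: float = 0.0
    softcore_delta: float = 5.0  # Å^2

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if self.softcore_delta < 0:
            raise ValueError(f"softcore_delta must be >= 0, got {self.softcore_delta}")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one simulation cell and its sampler settings."""

    box_edge: float  # Å, cubic periodic cell
    temperature: float  # K
    solvent: Species
    solvent_count: int
    solute: Optional[Species] = None
    cutoff_on: float = 9.5  # Å, switching starts
    cutoff_off: float = 10.5  # Å, interactions removed beyond
    max_displacement: float = 0.5  # Å, initial MC step size (auto-tuned in burn-in)
    burn_in_sweeps: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_edge < 2.0 * self.cutoff_off:
            raise ValueError(
                f"box_edge {self.box_edge} < 2 * cutoff_off {self.cutoff_off}: "
                "minimum-image convention invalid"
            )
        if not self.cutoff_on < self.cutoff_off:
            raise ValueError("cutoff_on must be < cutoff_off")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.solvent_count < 1:
            raise ValueError("solvent_count must be >= 1")

    @property
    def volume(self) -> float:
        return self.box_edge**3

    @property
    def density(self) -> float:
        """Solvent number density N/V in Å^-3."""
        return self.solvent_count / self.volume

    def with_box_edge(self, edge: float) -> "SimulationSpec":
        return replace(self, box_edge=edge)

    def to_dict(self) -> dict:
        d = {
            "box_edge_A": self.box_edge,
            "temperature_K": self.temperature,
            "solvent": {
                "epsilon": self.solvent.epsilon,
                "r_min": self.solvent.r_min,
                "count": self.solvent_count,
            },
            "cutoff_on": self.cutoff_on,
            "cutoff_off": self.cutoff_off,
            "max_displacement": self.max_displacement,
            "burn_in_sweeps": self.burn_in_sweeps,
            "seed": self.seed,
        }
        if self.solute is not None:
            d["solute"] = {"epsilon": self.solute.epsilon, "r_min": self.solute.r_min}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        solv = d["solvent"]
        solute = None
        if d.get("solute") is not None:
            solute = Species(epsilon=d["solute"]["epsilon"], r_min=d["solute"]["r_min"])
        return cls(
            box_edge=d["box_edge_A"],
            temperature=d["temperature_K"],
            solvent=Species(epsilon=solv["epsilon"], r_min=solv["r_min"]),
            solvent_count=int(solv["count"]),
            solute=solute,
            cutoff_on=d.get("cutoff_on", 9.5),
            cutoff_off=d.get("cutoff_off", 10.5),
            max_displacement=d.get("max_displacement", 0.5),
            burn_in_sweeps=int(d.get("burn_in_sweeps", 500)),
            seed=int(d.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# pair energetics


def _combine(a: Species, b: Species) -> tuple[float, float]:
    return math.sqrt(a.epsilon * b.epsilon), 0.5 * (a.r_min + b.r_min)


def lj_pair_energy(r: float, a: Species, b: Species) -> float:
    """Plain (unswitched) LJ pair energy at separation r."""
    if r <= 0:
        raise ValueError(f"separation must be positive, got {r}")
    eps, rbar = _combine(a, b)
    if eps == 0.0:
        return 0.0
    s6 = (rbar / r) ** 6
    return eps * (s6 * s6 - 2.0 * s6)


def switched_pair_energy(
    r: float, a: Species, b: Species, r_on: float = 9.5, r_off: float = 10.5
) -> float:
    """LJ pair energy multiplied by the CHARMM cubic switch S(r).

    S(r) = (r_off^2 - r^2)^2 (r_off^2 + 2 r^2 - 3 r_on^2) / (r_off^2 - r_on^2)^3
    on [r_on, r_off]; 1 below, 0 above, with continuous first derivative.
    """
    if r <= 0:
        raise ValueError(f"separation must be positive, got {r}")
    if not r_on < r_off:
        raise ValueError(f"invalid switch window [{r_on}, {r_off}]")
    eps, rbar = _combine(a, b)
    return float(K.pair_energy_r2(r * r, eps, rbar, r_on * r_on, r_off * r_off))


def switching_function(r: float, r_on: float, r_off: float) -> float:
    """The switch factor S(r) on its own (for testing/diagnostics)."""
    if not r_on < r_off:
        raise ValueError(f"invalid switch window [{r_on}, {r_off}]")
    return float(K.switch_factor(r * r, r_on * r_on, r_off * r_off))


def softcore_pair_energy(
    r: float,
    solute: Species,
    solvent: Species,
    state: LambdaState,
    r_on: float = 9.5,
    r_off: float = 10.5,
) -> float:
    """Soft-core solute-solvent energy: r_eff^2 = r^2 + delta*lam, scaled by (1-lam).

    Finite at r = 0 for lam > 0; equals the switched pair energy at lam = 0
    and vanishes identically at lam = 1.
    """
    if r < 0:
        raise ValueError(f"separation must be nonnegative, got {r}")
    eps, rbar = _combine(solute, solvent)
    return float(
        K.softcore_solute_energy_r2(
            r * r, eps, rbar, state.lam, state.softcore_delta, r_on * r_on, r_off * r_off
        )
    )


def _kernel_args(spec: SimulationSpec, state: Optional[LambdaState]):
    eps_nn, rbar_nn = _combine(spec.solvent, spec.solvent)
    if spec.solute is not None:
        eps_sn, rbar_sn = _combine(spec.solute, spec.solvent)
        lam = state.lam if state is not None else 0.0
        delta = state.softcore_delta if state is not None else 5.0
    else:
        eps_sn, rbar_sn, lam, delta = -1.0, 1.0, 0.0, 5.0  # eps_sn < 0: no solute
    return (
        eps_nn,
        rbar_nn,
        spec.cutoff_on**2,
        spec.cutoff_off**2,
        eps_sn,
        rbar_sn,
        lam,
        delta,
    )


def total_energy(
    frame: Frame | np.ndarray, spec: SimulationSpec, state: Optional[LambdaState] = None
) -> float:
    """Total potential energy of one frame under ``spec`` (kcal/mol)."""
    coords = frame.coordinates if isinstance(frame, Frame) else np.asarray(frame, float)
    if coords.shape[0] != spec.solvent_count:
        raise ValueError(
            f"frame has {coords.shape[0]} atoms but spec.solvent_count={spec.solvent_count}"
        )
    eps_nn, rbar_nn, ron2, roff2, eps_sn, rbar_sn, lam, delta = _kernel_args(spec, state)
    return float(
        K.total_energy_kernel(
            np.ascontiguousarray(coords), spec.box_edge, eps_nn, rbar_nn, ron2, roff2,
            eps_sn, rbar_sn, lam, delta,
        )
    )


def solute_solvent_energy(
    coords: np.ndarray, spec: SimulationSpec, state: LambdaState
) -> float:
    """Soft-core solute-solvent energy of one frame (used by the FEP layer)."""
    if spec.solute is None:
        return 0.0
    eps_sn, rbar_sn = _combine(spec.solute, spec.solvent)
    return float(
        K.solute_energy_kernel(
            np.ascontiguousarray(coords), spec.box_edge, eps_sn, rbar_sn,
            state.lam, state.softcore_delta, spec.cutoff_on**2, spec.cutoff_off**2,
        )
    )


# ---------------------------------------------------------------------------
# sampling


def initial_configuration(spec: SimulationSpec, seed: int = 0) -> np.ndarray:
    """Solvent atoms on a jittered simple-cubic lattice, avoiding the centre.

    When a solute is present the lattice site nearest the box centre is left
    vacant (candidate sites are generated for N+1 atoms and the most central
    one dropped) so the fixed solute never starts inside a solvent core.
    """
    rng = np.random.default_rng(seed)
    n = spec.solvent_count
    n_sites = n + (1 if spec.solute is not None else 0)
    n_side = int(math.ceil(n_sites ** (1.0 / 3.0)))
    a = spec.box_edge / n_side
    grid = (np.arange(n_side) + 0.5) * a
    sites = np.array(np.meshgrid(grid, grid, grid, indexing="ij")).reshape(3, -1).T
    centre = np.full(3, 0.5 * spec.box_edge)
    # order sites by distance from centre, farthest first, so dropping the
    # tail removes the most central ones
    order = np.argsort(-np.linalg.norm(sites - centre, axis=1))
    coords = sites[order[:n]].copy()
    coords += rng.uniform(-0.05 * a, 0.05 * a, size=coords.shape)
    coords -= spec.box_edge * np.floor(coords / spec.box_edge)
    return coords


def mc_nvt_sample(
    spec: SimulationSpec,
    n_sweeps: int,
    stride: int,
    seed: int,
    state: Optional[LambdaState] = None,
    initial_coords: Optional[np.ndarray] = None,
    replicate_id: int = 0,
    return_energies: bool = False,
):
    """Metropolis NVT chain; returns a Trajectory of frames saved every ``stride`` sweeps.

    The maximum displacement is auto-tuned toward ~40% acceptance during
    burn-in and frozen for production (tuning breaks detailed balance).  The
    solute, if any, never moves.  Identical (spec, seed) give identical
    trajectories.  With ``return_energies`` the per-frame total potential
    energies (tracked incrementally, kcal/mol) are returned alongside.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    coords = (
        np.array(initial_coords, dtype=float, copy=True)
        if initial_coords is not None
        else initial_configuration(spec, seed)
    )
    beta = 1.0 / (KB * spec.temperature)
    args = _kernel_args(spec, state)
    # burn-in with step-size tuning
    _, _, _, max_disp, _ = K.run_nvt_chain(
        coords, spec.box_edge, *args, beta, spec.burn_in_sweeps, 0,
        spec.max_displacement, True, seed,
    )
    frames, energies, _, _, drift = K.run_nvt_chain(
        coords, spec.box_edge, *args, beta, n_sweeps, stride, max_disp, False, seed + 1
    )
    if abs(drift) > 1e-6:
        raise RuntimeError(f"incremental energy bookkeeping drifted by {drift} kcal/mol")
    traj = Trajectory(
        coordinates=frames,
        box_edge=spec.box_edge,
        stride=stride,
        seed=seed,
        replicate_id=replicate_id,
        spec=spec,
    )
    if return_energies:
        return traj, energies
    return traj


def mc_nvt_independent_frames(
    spec: SimulationSpec,
    n_frames: int,
    seed: int,
    state: Optional[LambdaState] = None,
    sweeps_after_burn: int = 10,
    replicate_id: int = 0,
) -> Trajectory:
    """One frame from each of ``n_frames`` independent NVT chains.

    The KNN estimators require frames that are uncorrelated at the
    nearest-neighbour distance scale.  At cold, dense state points the
    structural relaxation of a single Metropolis chain is far slower than
    any practical frame stride (atoms rattle in persistent cages), so this
    sampler pays the burn-in cost per frame and draws every frame from its
    own chain (seeded ``seed``, ``seed+1``, ...).  The ``stride`` metadata is
    set to the full per-chain sweep count.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    frames = np.empty((n_frames, spec.solvent_count, 3))
    for i in range(n_frames):
        chain = mc_nvt_sample(
            spec,
            n_sweeps=sweeps_after_burn,
            stride=sweeps_after_burn,
            seed=seed + i,
            state=state,
        )
        frames[i] = chain.coordinates[-1]
    return Trajectory(
        coordinates=frames,
        box_edge=spec.box_edge,
        stride=spec.burn_in_sweeps + sweeps_after_burn,
        seed=seed,
        replicate_id=replicate_id,
        spec=spec,
    )


def mc_npt_equilibrate(
    spec: SimulationSpec,
    pressure_atm: float,
    n_sweeps: int,
    seed: int,
    state: Optional[LambdaState] = None,
    burn_in_fraction: float = 0.5,
    max_lnv: float = 0.02,
):
    """NpT Metropolis chain with ln-V volume moves; returns the mean box edge.

    The first ``burn_in_fraction`` of the sweep trace is discarded before
    averaging.  Volume moves that would invalidate the minimum-image
    convention (edge < 2 r_off) are rejected.
    """
    from .constants import ATM_TO_KCAL_PER_MOL_A3

    if pressure_atm <= 0:
        raise ValueError(f"pressure must be positive, got {pressure_atm}")
    if n_sweeps < 2:
        raise ValueError("n_sweeps must be >= 2")
    coords = initial_configuration(spec, seed)
    beta = 1.0 / (KB * spec.temperature)
    p = pressure_atm * ATM_TO_KCAL_PER_MOL_A3
    args = _kernel_args(spec, state)
    min_box = 2.0 * spec.cutoff_off
    n_burn = max(1, int(burn_in_fraction * n_sweeps))
    # burn-in with displacement tuning, then a frozen production chain
    _, box, _, max_disp = K.run_npt_chain(
        coords, spec.box_edge, *args, beta, p, n_burn,
        spec.max_displacement, max_lnv, min_box, True, seed,
    )
    edges, _, _, _ = K.run_npt_chain(
        coords, box, *args, beta, p, n_sweeps - n_burn,
        max_disp, max_lnv, min_box, False, seed + 1,
    )
    return float(np.mean(edges))
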