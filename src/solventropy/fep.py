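"""Free energy perturbation reference route: lambda schedules, window sampling, BAR.

The annihilation path is parameterised by lambda in [0, 1] (0 = solute
fully present, 1 = fully annihilated) through the soft-core potential of the
engine.  Schedules place N+1 states over N windows using the closed forms

    lam_f(n) = (1/N) sum_{k=1..N} [ 1 - (1 - n/N)^max(k-N+n, 1) ]
    lam_b(n) = (1/N) sum_{k=1..N} [ 1 - (n/N)^max(k-n, 1) ]

which satisfy lam_f(0)=0, lam_f(N)=1, lam_b(0)=1, lam_b(N)=0 and sample the
annihilation endpoint densely.  Each window boundary is estimated with the
Bennett Acceptance Ratio from forward and backward energy-difference
samples, and boundaries are summed per direction.  "N windows" counts the N
intervals between the N+1 lambda states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .constants import KB
from .engine import LambdaState, SimulationSpec, mc_nvt_sample, solute_solvent_energy

__all__ = [
    "LambdaSchedule",
    "FepResult",
    "lambda_schedule",
    "sample_window",
    "bar_estimate",
    "run_fep",
]


@dataclass(frozen=True)
class LambdaSchedule:
    """Lambda values for the N+1 states of an N-window schedule."""

    n_windows: int
    direction: str  # "forward" | "backward"
    values: np.ndarray  # length n_windows + 1, in [0, 1]


@dataclass(frozen=True)
class FepResult:
    """Per-window free-energy differences and direction totals (kcal/mol)."""

    per_window_dA: np.ndarray  # forward-direction window estimates
    per_window_error: np.ndarray  # BAR asymptotic standard errors
    total_forward: float  # sum over the forward schedule (0 -> 1)
    total_backward: float  # sum over the backward schedule (1 -> 0)
    hysteresis: float  # |total_forward + total_backward|

    @property
    def annihilation_free_energy(self) -> float:
        """Direction-averaged annihilation free energy."""
        return 0.5 * (self.total_forward - self.total_backward)


def lambda_schedule(n_windows: int, direction: str) -> LambdaSchedule:
    """Evaluate the printed closed-form schedules exactly for n = 0..N."""
    if n_windows < 2:
        raise ValueError(f"n_windows must be >= 2, got {n_windows}")
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    n_total = n_windows
    vals = np.empty(n_total + 1)
    for n in range(n_total + 1):
        acc = 0.0
        for k in range(1, n_total + 1):
            if direction == "forward":
                expo = max(k - n_total + n, 1)
                acc += 1.0 - (1.0 - n / n_total) ** expo
            else:
                expo = max(k - n, 1)
                acc += 1.0 - (n / n_total) ** expo
        vals[n] = acc / n_total
    return LambdaSchedule(n_windows=n_windows, direction=direction, values=vals)


def sample_window(
    spec: SimulationSpec,
    lam: LambdaState,
    lam_next: LambdaState,
    n_sweeps: int,
    stride: int,
    seed: int,
    burn_in_fraction: float = 0.1,
    initial_coords: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample U(lam_next) - U(lam) on configurations equilibrated at ``lam``.

    Returns (delta_u_samples, final_coords); the final coordinates let the
    caller seed the next window's chain (sequential window continuation).
    Only solute-solvent terms depend on lambda, so the difference is exact
    and O(N) per frame.
    """
    if spec.solute is None:
        raise ValueError("sample_window requires a solute in the spec")
    burn = max(1, int(burn_in_fraction * n_sweeps))
    spec_burn = replace(spec, burn_in_sweeps=burn)
    traj = mc_nvt_sample(
        spec_burn, n_sweeps=n_sweeps, stride=stride, seed=seed,
        state=lam, initial_coords=initial_coords,
    )
    du = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        du[i] = solute_solvent_energy(traj.coordinates[i], spec, lam_next) - \
            solute_solvent_energy(traj.coordinates[i], spec, lam)
    return du, traj.coordinates[-1].copy()


def _fermi(x: np.ndarray) -> np.ndarray:
    # numerically safe logistic 1/(1+e^x)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return out


def bar_estimate(
    forward_samples: Sequence[float],
    backward_samples: Sequence[float],
    temperature: float,
) -> tuple[float, float]:
    """Bennett Acceptance Ratio free-energy difference between two states.

    ``forward_samples`` are U1 - U0 evaluated on state-0 configurations;
    ``backward_samples`` are U0 - U1 on state-1 configurations (both
    kcal/mol).  Solves the self-consistent Bennett equation by bracketed
    root finding and reports the standard asymptotic-variance error.  Both
    sample sets must be non-empty (one-sided exponential averaging is
    deliberately not supported).
    """
    wf = np.asarray(forward_samples, dtype=float)
    wr = np.asarray(backward_samples, dtype=float)
    if wf.size == 0 or wr.size == 0:
        raise ValueError("BAR requires non-empty forward and backward sample sets")
    kt = KB * temperature
    beta = 1.0 / kt
    m = math.log(wf.size / wr.size)

    def implicit(da: float) -> float:
        # sum f(beta(wf - da) + M) - sum f(beta(wr + da) - M)
        a = _fermi(beta * (wf - da) + m).sum()
        b = _fermi(beta * (wr + da) - m).sum()
        return a - b

    # bracket: the implicit function is monotone decreasing in da
    lo = min(-wr.max(), wf.min()) - 10.0 * kt
    hi = max(wf.max(), -wr.min()) + 10.0 * kt
    flo, fhi = implicit(lo), implicit(hi)
    if flo * fhi > 0:
        raise RuntimeError(
            "BAR self-consistency root not bracketed: forward/backward "
            "distributions may not overlap"
        )
    da = brentq(implicit, lo, hi, xtol=1e-12, rtol=1e-14)

    ff = _fermi(beta * (wf - da) + m)
    fr = _fermi(beta * (wr + da) - m)
    var = 0.0
    if ff.mean() > 0:
        var += (np.mean(ff**2) / np.mean(ff) ** 2 - 1.0) / ff.size
    if fr.mean() > 0:
        var += (np.mean(fr**2) / np.mean(fr) ** 2 - 1.0) / fr.size
    return float(da), float(kt * math.sqrt(max(var, 0.0)))


def run_fep(
    spec: SimulationSpec,
    n_windows: int = 64,
    sweeps_per_window: int = 400,
    stride: int = 2,
    seed: int = 0,
    burn_in_fraction: float = 0.1,
    softcore_delta: float = 5.0,
) -> FepResult:
    """Forward and backward FEP with per-boundary BAR estimates.

    For each direction, every lambda state of the schedule is sampled once
    (windows continue from the previous window's final configuration); each
    boundary's free-energy difference combines the forward samples from its
    lower state and the reverse samples from its upper state via BAR.
    Totals are the per-direction sums; the backward total is the free energy
    of the reverse (1 -> 0) path, so forward + backward ~ 0 at convergence.
    """
    if spec.solute is None:
        raise ValueError("run_fep requires a solute in the spec")

    def direction_run(sched: LambdaSchedule, dir_seed: int):
        lams = sched.values
        n_states = len(lams)
        # per state: samples of dU to the next and to the previous state
        du_next: list[Optional[np.ndarray]] = [None] * n_states
        du_prev: list[Optional[np.ndarray]] = [None] * n_states
        coords = None
        for s in range(n_states):
            state = LambdaState(lam=float(lams[s]), softcore_delta=softcore_delta)
            if s == 0:
                # first window starts from a lattice: full equilibration
                burn = spec.burn_in_sweeps
            else:
                burn = max(1, int(burn_in_fraction * sweeps_per_window))
            spec_s = replace(spec, burn_in_sweeps=burn)
            traj = mc_nvt_sample(
                spec_s, n_sweeps=sweeps_per_window, stride=stride,
                seed=dir_seed + 1000 * s, state=state, initial_coords=coords,
            )
            coords = traj.coordinates[-1].copy()
            n_f = traj.n_frames
            if s + 1 < n_states:
                nxt = LambdaState(lam=float(lams[s + 1]), softcore_delta=softcore_delta)
                du = np.empty(n_f)
                for i in range(n_f):
                    du[i] = solute_solvent_energy(traj.coordinates[i], spec, nxt) - \
                        solute_solvent_energy(traj.coordinates[i], spec, state)
                du_next[s] = du
            if s > 0:
                prv = LambdaState(lam=float(lams[s - 1]), softcore_delta=softcore_delta)
                du = np.empty(n_f)
                for i in range(n_f):
                    du[i] = solute_solvent_energy(traj.coordinates[i], spec, prv) - \
                        solute_solvent_energy(traj.coordinates[i], spec, state)
                du_prev[s] = du
        das = np.empty(n_states - 1)
        errs = np.empty(n_states - 1)
        for b in range(n_states - 1):
            try:
                das[b], errs[b] = bar_estimate(
                    du_next[b], du_prev[b + 1], spec.temperature
                )
            except RuntimeError as exc:
                raise RuntimeError(f"window {b} ({sched.direction}): {exc}") from exc
        return das, errs

    fwd = lambda_schedule(n_windows, "forward")
    bwd = lambda_schedule(n_windows, "backward")
    das_f, errs_f = direction_run(fwd, seed)
    das_b, errs_b = direction_run(bwd, seed + 777_000)
    total_f = float(das_f.sum())
    total_b = float(das_b.sum())
    return FepResult(
        per_window_dA=das_f,
        per_window_error=errs_f,
        total_forward=total_f,
        total_backward=total_b,
        hysteresis=abs(total_f + total_b),
    )
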