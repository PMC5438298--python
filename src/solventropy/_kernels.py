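"""Numba-compiled inner loops for the Monte Carlo engine.

Everything here operates on plain float64 arrays.  The solute, when present,
is pinned at the centre of the cubic box (L/2, L/2, L/2) and is described by
``(eps_s, rmin_s, lam, sc_delta)``; ``eps_s < 0`` encodes "no solute" so the
kernels stay monomorphic.  Distances use the minimum-image convention.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "switch_factor",
    "pair_energy_r2",
    "softcore_solute_energy_r2",
    "total_energy_kernel",
    "particle_energy_kernel",
    "solute_energy_kernel",
    "run_nvt_chain",
    "run_npt_chain",
]


@njit(cache=True, fastmath=False)
def switch_factor(r2, ron2, roff2):
    """CHARMM cubic-in-r^2 switching function S(r); 1 below r_on, 0 above r_off."""
    if r2 <= ron2:
        return 1.0
    if r2 >= roff2:
        return 0.0
    num = (roff2 - r2) * (roff2 - r2) * (roff2 + 2.0 * r2 - 3.0 * ron2)
    return num / ((roff2 - ron2) ** 3)


@njit(cache=True, fastmath=False)
def pair_energy_r2(r2, eps, rbar, ron2, roff2):
    """Switched LJ pair energy from the squared separation.

    eps is the combined well depth sqrt(eps_i eps_j); rbar the combined
    radius (R_i + R_j)/2.  Returns 0 beyond r_off.
    """
    if eps == 0.0 or r2 >= roff2:
        return 0.0
    s6 = (rbar * rbar / r2) ** 3
    return eps * (s6 * s6 - 2.0 * s6) * switch_factor(r2, ron2, roff2)


@njit(cache=True, fastmath=False)
def softcore_solute_energy_r2(r2, eps, rbar, lam, sc_delta, ron2, roff2):
    """Separation-shifted soft-core solute-solvent energy from squared separation.

    r_eff^2 = r^2 + sc_delta * lam; prefactor (1 - lam); the switching factor
    is evaluated on the physical separation so the lam = 0 limit coincides
    with the plain switched pair energy.
    """
    if lam >= 1.0 or eps == 0.0:
        return 0.0
    if r2 >= roff2:
        return 0.0
    reff2 = r2 + sc_delta * lam
    s6 = (rbar * rbar / reff2) ** 3
    return (1.0 - lam) * eps * (s6 * s6 - 2.0 * s6) * switch_factor(r2, ron2, roff2)


@njit(cache=True, fastmath=False)
def _min_image_r2(dx, dy, dz, box):
    dx -= box * np.rint(dx / box)
    dy -= box * np.rint(dy / box)
    dz -= box * np.rint(dz / box)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True, fastmath=False)
def solute_energy_kernel(coords, box, eps_sn, rbar_sn, lam, sc_delta, ron2, roff2):
    """Total solute-solvent energy for one frame; solute at the box centre."""
    n = coords.shape[0]
    cx = 0.5 * box
    e = 0.0
    for i in range(n):
        r2 = _min_image_r2(coords[i, 0] - cx, coords[i, 1] - cx, coords[i, 2] - cx, box)
        e += softcore_solute_energy_r2(r2, eps_sn, rbar_sn, lam, sc_delta, ron2, roff2)
    return e


@njit(cache=True, fastmath=False)
def total_energy_kernel(
    coords, box, eps_nn, rbar_nn, ron2, roff2, eps_sn, rbar_sn, lam, sc_delta
):
    """Full potential energy: switched solvent pairs plus soft-core solute terms.

    eps_sn < 0 means no solute.
    """
    n = coords.shape[0]
    e = 0.0
    for i in range(n - 1):
        xi = coords[i, 0]
        yi = coords[i, 1]
        zi = coords[i, 2]
        for j in range(i + 1, n):
            r2 = _min_image_r2(xi - coords[j, 0], yi - coords[j, 1], zi - coords[j, 2], box)
            e += pair_energy_r2(r2, eps_nn, rbar_nn, ron2, roff2)
    if eps_sn >= 0.0:
        e += solute_energy_kernel(coords, box, eps_sn, rbar_sn, lam, sc_delta, ron2, roff2)
    return e


@njit(cache=True, fastmath=False)
def particle_energy_kernel(
    coords, idx, px, py, pz, box, eps_nn, rbar_nn, ron2, roff2,
    eps_sn, rbar_sn, lam, sc_delta,
):
    """Interaction energy of particle ``idx`` placed at (px,py,pz) with the rest."""
    n = coords.shape[0]
    e = 0.0
    for j in range(n):
        if j == idx:
            continue
        r2 = _min_image_r2(px - coords[j, 0], py - coords[j, 1], pz - coords[j, 2], box)
        e += pair_energy_r2(r2, eps_nn, rbar_nn, ron2, roff2)
    if eps_sn >= 0.0:
        cx = 0.5 * box
        r2 = _min_image_r2(px - cx, py - cx, pz - cx, box)
        e += softcore_solute_energy_r2(r2, eps_sn, rbar_sn, lam, sc_delta, ron2, roff2)
    return e


@njit(cache=True, fastmath=False)
def run_nvt_chain(
    coords, box, eps_nn, rbar_nn, ron2, roff2, eps_sn, rbar_sn, lam, sc_delta,
    beta, n_sweeps, stride, max_disp, tune, seed,
):
    """Metropolis single-particle-move NVT chain.

    Mutates ``coords`` in place.  When ``stride > 0`` a frame (copy of
    coords) and its incrementally tracked total energy are recorded every
    ``stride`` sweeps.  When ``tune`` is true the maximum displacement is
    adjusted every 50 sweeps toward ~40% acceptance (burn-in only; tuning
    breaks detailed balance and must be frozen for production).

    Returns (frames, energies, acceptance_rate, final_max_disp, e_drift_check)
    where e_drift_check is the difference between the tracked energy and a
    full recomputation at the end of the chain.
    """
    np.random.seed(seed)
    n = coords.shape[0]
    n_frames = n_sweeps // stride if stride > 0 else 0
    frames = np.empty((n_frames, n, 3))
    energies = np.empty(n_frames)

    e_total = total_energy_kernel(
        coords, box, eps_nn, rbar_nn, ron2, roff2, eps_sn, rbar_sn, lam, sc_delta
    )
    n_acc = 0
    n_try = 0
    acc_window = 0
    try_window = 0
    frame_idx = 0
    for sweep in range(n_sweeps):
        for _ in range(n):
            i = np.random.randint(0, n)
            px = coords[i, 0] + max_disp * (2.0 * np.random.random() - 1.0)
            py = coords[i, 1] + max_disp * (2.0 * np.random.random() - 1.0)
            pz = coords[i, 2] + max_disp * (2.0 * np.random.random() - 1.0)
            px -= box * np.floor(px / box)
            py -= box * np.floor(py / box)
            pz -= box * np.floor(pz / box)
            e_old = particle_energy_kernel(
                coords, i, coords[i, 0], coords[i, 1], coords[i, 2], box,
                eps_nn, rbar_nn, ron2, roff2, eps_sn, rbar_sn, lam, sc_delta,
            )
            e_new = particle_energy_kernel(
                coords, i, px, py, pz, box,
                eps_nn, rbar_nn, ron2, roff2, eps_sn, rbar_sn, lam, sc_delta,
            )
            de = e_new - e_old
            n_try += 1
            try_window += 1
            if de <= 0.0 or np.random.random() < np.exp(-beta * de):
                coords[i, 0] = px
                coords[i, 1] = py
                coords[i, 2] = pz
                e_total += de
                n_acc += 1
                acc_window += 1
        if tune and (sweep + 1) % 50 == 0 and try_window > 0:
            rate = acc_window / try_window
            if rate > 0.45:
                max_disp = min(max_disp * 1.15, 0.45 * box)
            elif rate < 0.35:
                max_disp = max(max_disp * 0.85, 1e-4)
            acc_window = 0
            try_window = 0
        if stride > 0 and (sweep + 1) % stride == 0 and frame_idx < n_frames:
            frames[frame_idx] = coords
            energies[frame_idx] = e_total
            frame_idx += 1
    e_check = total_energy_kernel(
        coords, box, eps_nn, rbar_nn, ron2, roff2, eps_sn, rbar_sn, lam, sc_delta
    )
    rate = n_acc / n_try if n_try > 0 else 0.0
    return frames, energies, rate, max_disp, e_total - e_check


@njit(cache=True, fastmath=False)
def run_npt_chain(
    coords, box, eps_nn, rbar_nn, ron2, roff2, eps_sn, rbar_sn, lam, sc_delta,
    beta, pressure, n_sweeps, max_disp, max_lnv, min_box, tune, seed,
):
    """Metropolis NpT chain: particle moves plus one ln-V volume move per sweep.

    The volume move samples pi(V) ~ V^(N+1) exp(-beta(U + pV)) via a random
    walk in ln V (the +1 from the ln-V proposal measure; with the fixed
    solute counted the exponent matches the (N_solvent + 1)-particle cell).
    Volume moves shrinking the box below ``min_box`` (minimum-image validity)
    are rejected outright.

    Returns (edge_trace, final_box, acceptance_rate, final_max_disp).
    ``coords`` is mutated in place and rescaled with the box.
    """
    np.random.seed(seed)
    n = coords.shape[0]
    edges = np.empty(n_sweeps)
    e_total = total_energy_kernel(
        coords, box, eps_nn, rbar_nn, ron2, roff2, eps_sn, rbar_sn, lam, sc_delta
    )
    n_acc = 0
    n_try = 0
    acc_window = 0
    try_window = 0
    n_exp = float(n + (1 if eps_sn >= 0.0 else 0))
    for sweep in range(n_sweeps):
        for _ in range(n):
            i = np.random.randint(0, n)
            px = coords[i, 0] + max_disp * (2.0 * np.random.random() - 1.0)
            py = coords[i, 1] + max_disp * (2.0 * np.random.random() - 1.0)
            pz = coords[i, 2] + max_disp * (2.0 * np.random.random() - 1.0)
            px -= box * np.floor(px / box)
            py -= box * np.floor(py / box)
            pz -= box * np.floor(pz / box)
            e_old = particle_energy_kernel(
                coords, i, coords[i, 0], coords[i, 1], coords[i, 2], box,
                eps_nn, rbar_nn, ron2, roff2, eps_sn, rbar_sn, lam, sc_delta,
            )
            e_new = particle_energy_kernel(
                coords, i, px, py, pz, box,
                eps_nn, rbar_nn, ron2, roff2, eps_sn, rbar_sn, lam, sc_delta,
            )
            de = e_new - e_old
            n_try += 1
            try_window += 1
            if de <= 0.0 or np.random.random() < np.exp(-beta * de):
                coords[i, 0] = px
                coords[i, 1] = py
                coords[i, 2] = pz
                e_total += de
                n_acc += 1
                acc_window += 1
        # volume move in ln V
        v_old = box ** 3
        lnv_new = np.log(v_old) + max_lnv * (2.0 * np.random.random() - 1.0)
        v_new = np.exp(lnv_new)
        box_new = v_new ** (1.0 / 3.0)
        if box_new >= min_box:
            scale = box_new / box
            coords_new = coords * scale
            e_new_total = total_energy_kernel(
                coords_new, box_new, eps_nn, rbar_nn, ron2, roff2,
                eps_sn, rbar_sn, lam, sc_delta,
            )
            arg = (
                -beta * (e_new_total - e_total + pressure * (v_new - v_old))
                + (n_exp + 1.0) * np.log(v_new / v_old)
            )
            if arg >= 0.0 or np.random.random() < np.exp(arg):
                for i in range(n):
                    coords[i, 0] = coords_new[i, 0]
                    coords[i, 1] = coords_new[i, 1]
                    coords[i, 2] = coords_new[i, 2]
                box = box_new
                e_total = e_new_total
        if tune and (sweep + 1) % 50 == 0 and try_window > 0:
            rate = acc_window / try_window
            if rate > 0.45:
                max_disp = min(max_disp * 1.15, 0.45 * box)
            elif rate < 0.35:
                max_disp = max(max_disp * 0.85, 1e-4)
            acc_window = 0
            try_window = 0
        edges[sweep] = box
    rate = n_acc / n_try if n_try > 0 else 0.0
    return edges, box, rate, max_disp
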