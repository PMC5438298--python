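import math

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import kstest

from solventropy.constants import ATM_TO_KCAL_PER_MOL_A3, KB
from solventropy.engine import (
    NEON,
    LambdaState,
    SimulationSpec,
    Species,
    lj_pair_energy,
    mc_npt_equilibrate,
    mc_nvt_sample,
    softcore_pair_energy,
    switched_pair_energy,
    switching_function,
    total_energy,
)

from conftest import small_spec


class TestLjPairEnergy:
    def test_minimum_depth(self):
        a = Species(0.2, 3.0)
        b = Species(0.8, 4.0)
        rbar = 3.5
        assert lj_pair_energy(rbar, a, b) == pytest.approx(-math.sqrt(0.16), rel=1e-12)

    def test_zero_crossing(self):
        a = Species(0.2, 3.0)
        r0 = 3.0 / 2.0 ** (1.0 / 6.0)
        assert lj_pair_energy(r0, a, a) == pytest.approx(0.0, abs=1e-12)

    def test_neon_at_3p5(self):
        assert lj_pair_energy(3.5, NEON, NEON) == pytest.approx(-0.0597, abs=5e-5)

    def test_singularity_rejected(self):
        with pytest.raises(ValueError):
            lj_pair_energy(0.0, NEON, NEON)


class TestSwitchedPairEnergy:
    def test_equals_plain_below_r_on(self):
        assert switched_pair_energy(3.5, NEON, NEON) == pytest.approx(
            lj_pair_energy(3.5, NEON, NEON), rel=1e-12
        )
        assert switched_pair_energy(9.5, NEON, NEON) == pytest.approx(
            lj_pair_energy(9.5, NEON, NEON), rel=1e-12
        )

    def test_zero_beyond_r_off(self):
        assert switched_pair_energy(10.5, NEON, NEON) == 0.0
        assert switched_pair_energy(12.0, NEON, NEON) == 0.0

    def test_switch_boundary_conditions_symbolic(self):
        # verify the chosen polynomial satisfies S(r_on)=1, S(r_off)=0 and
        # zero first derivative at both ends, symbolically
        import sympy as sp

        r, ron, roff = sp.symbols("r r_on r_off", positive=True)
        s = (roff**2 - r**2) ** 2 * (roff**2 + 2 * r**2 - 3 * ron**2) / (
            roff**2 - ron**2
        ) ** 3
        assert sp.simplify(s.subs(r, ron)) == 1
        assert sp.simplify(s.subs(r, roff)) == 0
        ds = sp.diff(s, r)
        assert sp.simplify(ds.subs(r, ron)) == 0
        assert sp.simplify(ds.subs(r, roff)) == 0

    def test_value_in_window_matches_polynomial(self):
        r, ron, roff = 10.0, 9.5, 10.5
        s = (roff**2 - r**2) ** 2 * (roff**2 + 2 * r**2 - 3 * ron**2) / (
            roff**2 - ron**2
        ) ** 3
        assert switched_pair_energy(r, NEON, NEON) == pytest.approx(
            lj_pair_energy(r, NEON, NEON) * s, rel=1e-12
        )

    def test_monotone_nonincreasing_switch(self):
        rs = np.linspace(9.5, 10.5, 200)
        ss = [switching_function(r, 9.5, 10.5) for r in rs]
        assert all(b <= a + 1e-12 for a, b in zip(ss, ss[1:]))

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            switched_pair_energy(5.0, NEON, NEON, r_on=10.5, r_off=9.5)


class TestSoftcorePairEnergy:
    def test_full_annihilation_is_zero(self):
        state = LambdaState(lam=1.0)
        for r in (0.0, 1.0, 3.06, 8.0):
            assert softcore_pair_energy(r, NEON, NEON, state) == 0.0

    def test_full_coupling_matches_switched(self):
        state = LambdaState(lam=0.0)
        for r in (2.5, 3.06, 9.8):
            assert softcore_pair_energy(r, NEON, NEON, state) == pytest.approx(
                switched_pair_energy(r, NEON, NEON), rel=1e-12
            )

    def test_finite_at_contact(self):
        # direct evaluation of the r_eff^2 = r^2 + delta*lam form at r = 0
        state = LambdaState(lam=0.5, softcore_delta=5.0)
        reff2 = 0.0 + 5.0 * 0.5
        s6 = (3.06**2 / reff2) ** 3
        expected = 0.5 * 0.086 * (s6 * s6 - 2.0 * s6)  # switch factor = 1 at r=0
        got = softcore_pair_energy(0.0, NEON, NEON, state)
        assert math.isfinite(got)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_continuous_in_lambda(self):
        lams = np.linspace(0.0, 1.0, 101)
        vals = [
            softcore_pair_energy(2.0, NEON, NEON, LambdaState(lam=l)) for l in lams
        ]
        diffs = np.abs(np.diff(vals))
        assert diffs.max() < 0.1 * (np.abs(vals).max() + 1.0)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            LambdaState(lam=0.5, softcore_delta=-1.0)


def _brute_force_energy(coords, spec, state=None):
    """Independent O(N^2) double-loop oracle (pure python/numpy)."""
    box = spec.box_edge
    n = len(coords)
    e = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = coords[i] - coords[j]
            d -= box * np.rint(d / box)
            r = float(np.linalg.norm(d))
            e += switched_pair_energy(r, spec.solvent, spec.solvent,
                                      spec.cutoff_on, spec.cutoff_off)
    if spec.solute is not None:
        centre = np.full(3, box / 2.0)
        st = state if state is not None else LambdaState(0.0)
        for i in range(n):
            d = coords[i] - centre
            d -= box * np.rint(d / box)
            r = float(np.linalg.norm(d))
            e += softcore_pair_energy(r, spec.solute, spec.solvent, st,
                                      spec.cutoff_on, spec.cutoff_off)
    return e


class TestTotalEnergy:
    def test_ideal_gas_zero(self):
        spec = SimulationSpec(
            box_edge=12.0, temperature=25.0, solvent=Species(0.0, 3.0),
            solvent_count=5, cutoff_on=4.5, cutoff_off=5.5,
        )
        coords = np.random.default_rng(0).uniform(0, 12.0, (5, 3))
        assert total_energy(coords, spec) == 0.0

    def test_single_pair(self):
        spec = small_spec(n=2)
        coords = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 4.2]])
        assert total_energy(coords, spec) == pytest.approx(
            switched_pair_energy(3.2, NEON, NEON, 4.5, 5.5), rel=1e-12
        )

    @pytest.mark.parametrize("with_solute", [False, True])
    def test_matches_brute_force_oracle(self, with_solute):
        rng = np.random.default_rng(42)
        spec = small_spec(0.43 if with_solute else None, n=5)
        coords = rng.uniform(0, spec.box_edge, (5, 3))
        assert total_energy(coords, spec) == pytest.approx(
            _brute_force_energy(coords, spec), abs=1e-10
        )

    def test_minimum_image_translation_invariance(self):
        rng = np.random.default_rng(1)
        spec = small_spec(0.215, n=8)
        coords = rng.uniform(0, spec.box_edge, (8, 3))
        e0 = total_energy(coords, spec)
        shifted = coords.copy()
        shifted[3] += spec.box_edge * np.array([1.0, -2.0, 3.0])
        assert total_energy(shifted, spec) == pytest.approx(e0, abs=1e-9)


class TestMcNvt:
    def test_determinism(self):
        spec = small_spec(0.215, n=20, burn_in=50)
        t1 = mc_nvt_sample(spec, n_sweeps=40, stride=10, seed=5)
        t2 = mc_nvt_sample(spec, n_sweeps=40, stride=10, seed=5)
        np.testing.assert_array_equal(t1.coordinates, t2.coordinates)

    def test_seed_changes_trajectory(self):
        spec = small_spec(0.215, n=20, burn_in=50)
        t1 = mc_nvt_sample(spec, n_sweeps=40, stride=10, seed=5)
        t2 = mc_nvt_sample(spec, n_sweeps=40, stride=10, seed=6)
        assert not np.array_equal(t1.coordinates, t2.coordinates)

    def test_incremental_energy_matches_recomputation(self):
        # the chain tracks energy incrementally; recompute frames from scratch
        spec = small_spec(0.43, n=30, burn_in=100)
        traj, energies = mc_nvt_sample(
            spec, n_sweeps=400, stride=40, seed=9, return_energies=True,
            state=LambdaState(0.0),
        )
        for i in range(traj.n_frames):
            assert energies[i] == pytest.approx(
                total_energy(traj.coordinates[i], spec, LambdaState(0.0)), abs=1e-8
            )

    def test_ideal_gas_uniformity(self):
        spec = SimulationSpec(
            box_edge=10.0, temperature=25.0, solvent=Species(0.0, 3.0),
            solvent_count=25, cutoff_on=4.0, cutoff_off=4.9, burn_in_sweeps=100,
            max_displacement=4.5,  # free particles: large steps decorrelate frames
        )
        traj = mc_nvt_sample(spec, n_sweeps=2000, stride=5, seed=11)
        samples = traj.coordinates.reshape(-1, 3)
        assert samples.shape[0] >= 10_000
        for axis in range(3):
            stat = kstest(samples[:, axis] / 10.0, "uniform")
            assert stat.pvalue > 0.01

    def test_two_atom_separation_matches_quadrature(self):
        # histogram of pair separation vs r^2 exp(-V/kT) quadrature, r < L/2
        spec = SimulationSpec(
            box_edge=8.0, temperature=25.0, solvent=NEON, solvent_count=2,
            cutoff_on=3.0, cutoff_off=3.9, burn_in_sweeps=200,
        )
        traj = mc_nvt_sample(spec, n_sweeps=60_000, stride=10, seed=13)
        box = spec.box_edge
        d = traj.coordinates[:, 0] - traj.coordinates[:, 1]
        d -= box * np.rint(d / box)
        r = np.linalg.norm(d, axis=1)
        r = r[r < box / 2.0]
        edges = np.arange(2.4, 4.0, 0.2)
        counts, _ = np.histogram(r, bins=edges)

        beta = 1.0 / (KB * spec.temperature)
        from scipy.integrate import quad

        def integrand(x):
            return x**2 * math.exp(
                -beta * switched_pair_energy(x, NEON, NEON, 3.0, 3.9)
            )

        # normalise over the full r < L/2 range (the PBC shell factor is
        # exactly 4 pi r^2 there)
        z, _ = quad(integrand, 1e-6, box / 2.0, limit=200)
        n_tot = len(r)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            p, _ = quad(integrand, lo, hi, limit=200)
            expected = n_tot * p / z
            se = math.sqrt(max(expected, 1.0))
            # 3 standard errors, plus slack for residual chain correlation
            assert abs(c - expected) <= 5.0 * se, (lo, hi, c, expected)

    def test_mean_energy_stable_across_seeds(self):
        spec = small_spec(None, n=40, burn_in=400)
        means, sems = [], []
        for seed in (31, 32):
            _, e = mc_nvt_sample(
                spec, n_sweeps=1500, stride=3, seed=seed, return_energies=True
            )
            m = len(e) // 25
            blocks = e[: m * 25].reshape(m, 25).mean(axis=1)
            means.append(e.mean())
            sems.append(blocks.std(ddof=1) / math.sqrt(m))
        combined = math.hypot(*sems)
        assert abs(means[0] - means[1]) <= 4.0 * combined


class TestMcNpt:
    def _ideal_spec(self, n=30):
        return SimulationSpec(
            box_edge=6.0, temperature=25.0, solvent=Species(0.0, 3.0),
            solvent_count=n, cutoff_on=0.5, cutoff_off=0.9, burn_in_sweeps=100,
        )

    def test_ideal_gas_mean_edge(self):
        # pi(V) ~ V^N exp(-beta p V) => V ~ Gamma(N+1, kT/p) and the mean
        # edge has the closed form (kT/p)^(1/3) Gamma(N+4/3)/Gamma(N+1)
        n = 30
        spec = self._ideal_spec(n)
        kt = KB * 25.0
        p_atm = 500.0
        p = p_atm * ATM_TO_KCAL_PER_MOL_A3
        expected_edge = (kt / p) ** (1.0 / 3.0) * math.exp(
            gammaln(n + 1 + 1.0 / 3.0) - gammaln(n + 1)
        )
        edges = [
            mc_npt_equilibrate(spec, p_atm, n_sweeps=4000, seed=s, max_lnv=0.3)
            for s in (41, 42, 43)
        ]
        mean = np.mean(edges)
        sem = np.std(edges, ddof=1) / math.sqrt(len(edges))
        assert abs(mean - expected_edge) <= max(3.0 * sem, 0.02 * expected_edge)

    def test_boyle_halving(self):
        spec = self._ideal_spec(30)
        e1 = mc_npt_equilibrate(spec, 400.0, n_sweeps=4000, seed=51, max_lnv=0.3)
        e2 = mc_npt_equilibrate(spec, 800.0, n_sweeps=4000, seed=52, max_lnv=0.3)
        # doubling pressure halves the volume: edge ratio 2^(-1/3)
        assert e2 / e1 == pytest.approx(2.0 ** (-1.0 / 3.0), rel=0.03)

    def test_nonphysical_pressure_rejected(self):
        with pytest.raises(ValueError):
            mc_npt_equilibrate(self._ideal_spec(), -1.0, n_sweeps=100, seed=0)


class TestSpecValidation:
    def test_box_must_hold_cutoff(self):
        with pytest.raises(ValueError):
            SimulationSpec(
                box_edge=20.0, temperature=25.0, solvent=NEON, solvent_count=10
            )

    def test_switch_window_ordering(self):
        with pytest.raises(ValueError):
            SimulationSpec(
                box_edge=30.0, temperature=25.0, solvent=NEON, solvent_count=10,
                cutoff_on=11.0, cutoff_off=10.5,
            )

    def test_round_trip_dict(self):
        spec = small_spec(0.43)
        again = SimulationSpec.from_dict(spec.to_dict())
        assert again == spec
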