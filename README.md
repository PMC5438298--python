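# solventropy

Endpoint solvation free energies for monatomic Lennard-Jones fluids.

The package computes the free energy of annihilating a fixed LJ solute in a
monatomic solvent **from the two endpoint simulations alone**: the mean
potential-energy change is combined with conditional solvation entropies
estimated by k-nearest-neighbour (KNN) methods —

* **C1PE** (conditional one-particle entropy): solute–solvent correlations
  only, estimated from 3-D nearest-neighbour distances and cross-checked by
  an independent radial-distribution-function quadrature;
* **C2PE** (conditional two-particle entropy): adds the solvent-pair
  correlation correction, estimated in 6-D pair space.

Finite-sampling bias is removed by fitting `H(F) = a F^b + H_inf` over a
ladder of frame counts.  A built-in Free Energy Perturbation route
(64-window forward/backward lambda schedules, soft-core annihilation,
Bennett Acceptance Ratio per window) provides the reference values, and the
package simulates its own trajectories with a Metropolis Monte Carlo engine
(NVT production, NpT equilibration) for a neon-like solvent with a fixed
central solute.

## Layout

| module | contents |
| --- | --- |
| `solventropy.constants` | physical constants, reduced-unit transforms |
| `solventropy.engine` | LJ energetics (switched, soft-core), Metropolis NVT/NpT samplers |
| `solventropy.trajectory` | trajectory container, internal format, DCD reader, thinning |
| `solventropy.rdf` | radial distribution functions, quadrature entropy oracle |
| `solventropy.knn` | generic / one-particle / two-particle KNN entropy estimators |
| `solventropy.extrapolation` | power-law infinite-sampling extrapolation |
| `solventropy.assembly` | free-energy assembly at both truncation levels |
| `solventropy.fep` | lambda schedules, window sampling, BAR, FEP totals |
| `solventropy.cli` | `solventropy` command-line pipeline |

## CLI

```bash
solventropy simulate config.yaml --out runs/sol1        # replicate MC trajectories
solventropy entropy runs/sol1/*.traj --level c1pe --out h1.csv
solventropy rdf runs/sol1/replicate_00.traj --out rdf.csv
solventropy fep config.yaml --out fep.csv
solventropy assemble --du -1.717 --tds1 -0.541 --out result.json
solventropy reproduce-table2 --out table2.csv           # published-table replay
```

A config file looks like:

```yaml
system:
  box_edge_A: 27.376
  temperature_K: 25.0
  solvent: {epsilon: 0.086, r_min: 3.06, count: 899}
  solute: {epsilon: 0.215, r_min: 3.06}   # omit for bulk
sampler:
  n_sweeps: 2000
  stride: 5
  burn_in_sweeps: 500
  replicates: 16
  seed: 1
```

Every command writes a `manifest.json` (config digest, seeds, versions)
sufficient to reproduce its outputs bit-identically.

## Sampling caveat

KNN estimators need frames that are uncorrelated at the nearest-neighbour
distance scale.  At the cold, dense reference state point a single
Metropolis chain relaxes its structure far more slowly than any practical
frame stride, so entropy estimation should use
`engine.mc_nvt_independent_frames`, which draws every frame from its own
equilibrated chain.  Energy averages (and FEP windows) are insensitive to
this and use ordinary strided chains.

## Tests and acceptance report

```bash
python -m pytest -q                  # full suite (~15 min single-core)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the acceptance targets from scratch:
reduced-units arithmetic and published-table assembly instantly, then
reduced-scale Monte Carlo for the SOL1 FEP total and the SOL1/SOL4 energy
changes (~10–15 min single-core).  The full-scale protocol (16 replicates,
60 ns equivalents, 12 000-frame extrapolation ladders) is a cluster job:
run `simulate`/`entropy`/`fep` per system with `replicates: 16` and the
ladders produced by `solventropy.extrapolation.schedule_frame_counts`.
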