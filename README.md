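# condensotherm

Thermodynamic decomposition of protein condensate formation from molecular
dynamics data. Given velocity/position trajectories and interaction-energy
tables of protein solutions at a series of concentrations, the package
computes:

* **water entropies** via the two-phase thermodynamics (2PT) method —
  velocity autocorrelation → vibrational density of states → solid/gas
  partition via the fluidicity equation → translational (harmonic
  oscillator + hard sphere) and rotational (harmonic oscillator + rigid
  rotor) molar entropies;
* **hydration-structure metrics** — tetrahedral order parameter
  distributions, water–water and protein–water hydrogen bonds,
  hydration-layer populations (waters within 0.3 nm of the protein
  surface), chain radii of gyration, and piecewise-linear crossover fits
  of concentration trends;
* **released/retained water accounting** and the full **free-energy
  ledger**: solvation entropy tug-of-war, water–water enthalpy/entropy
  cancellation, protein interaction energy, protein conformational
  entropy (kNN/MIST torsion entropies), plus analytic mixing-entropy and
  droplet-interface estimates;
* **synthetic data generators** with attached analytic ground truth for
  every pipeline stage, including a numba-compiled rigid four-site water
  MD engine used to produce bulk-water velocity trajectories at desk
  scale.

Units package-wide: nm, ps, amu, kJ/mol, K; entropies in J mol⁻¹ K⁻¹.

## Layout

| module | contents |
| --- | --- |
| `condensotherm.trajectory` | domain types (Topology, Frame, VelocitySeries, EnergySeries, ConcentrationSeries) and GRO/PDB/TRR/xvg/text-frame IO |
| `condensotherm.synth` | generators: harmonic ensemble, ideal gas, Langevin soft-sphere fluid, toy condensate, planted concentration tables, torsion samples |
| `condensotherm.waterbox` | rigid four-site water MD engine (fixture generation) |
| `condensotherm.twopt` | 2PT entropy engine (VACF, DoS, fluidicity, partition, entropy) |
| `condensotherm.hydration` | tetrahedral order, hydrogen bonds, hydration layer, Rg, crossover fits |
| `condensotherm.ledger` | released/retained budgets and the free-energy ledger |
| `condensotherm.conformational` | torsion extraction, circular kNN entropy, KSG mutual information, MIST totals |
| `condensotherm.pipeline` / `.cli` | manifest-driven orchestration and the `condensotherm` CLI |

## CLI

```bash
# synthetic inputs with ground truth
condensotherm synth tables --noise-sd 0.3 --out series.csv
condensotherm synth condensate --rho 350 --out-dir systems/
condensotherm synth harmonic --frequency 6.25 --out harmonic.vel

# 2PT entropy from a velocity trajectory
condensotherm entropy --traj traj.ctf --top system.gro --temperature 300 \
    --output entropy.json

# hydration metrics
condensotherm hydration --structure system.gro --out hydration.json

# free-energy ledger from a concentration series
condensotherm ledger --series series.csv --rho-cond 350 --out ledger

# full manifest-driven run
condensotherm run --manifest manifest.yaml --out-dir out/
```

A run manifest (YAML or JSON) lists either a precomputed per-concentration
series table (`series_table`, optional `replicate_tables`) or raw
`systems` entries (structure, velocity trajectory, energy tables) per
concentration and replicate, plus `rho_cond`, `temperature`, and option
flags. See `condensotherm.pipeline.validate_manifest` for the schema.

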