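# bridgeswitch

Salt-bridge *shuttle* dynamics in protein MD trajectories: detection and
quantification of a two-state conformational switch in which a central basic
residue alternates between two acidic salt-bridge partners.

## The problem

In E2 ubiquitin-conjugating enzymes such as UbcH6 and UbcH8, a conserved
lysine (K109/K117) acts as a gatekeeper for an interface acid (E105/D113)
that mediates binding to E3 RING-finger domains.  The lysine shuttles between
two intramolecular salt bridges: when it pairs with a remote aspartate
(D137/D145) the interface acid is free and the enzyme is in an **open**,
binding-competent conformation; when it hijacks the interface acid the enzyme
is **bridged** and binding-impaired.  The balance between these two states —
not any large conformational change — controls E2–E3 interaction selectivity.

`bridgeswitch` takes a multi-model PDB trajectory (or distance tables),
identifies ionizable side-chain groups under a pH-aware protonation policy,
builds the occupancy-filtered salt-bridge network, screens every basic hub
for *shuttle motifs* — partner pairs whose central–partner distances are
strongly anticorrelated — and quantifies the equilibrium: state occupancies,
exchange rate, dwell times, and the anticorrelation statistic

```
rho = Σ (a_i − ā)(b_i − b̄) / sqrt( Σ (a_i − ā)² · Σ (b_i − b̄)² )
```

with a circular moving-block bootstrap confidence interval.  A Kabsch-based
cross-RMSD matrix (Cα/Cβ) summarises overall conformational stability.
Because real shuttle trajectories require hundreds of nanoseconds of
explicit-solvent MD, the package ships a synthetic generator — a two-state
continuous-time Markov chain with state-dependent Gaussian distance emissions
— that produces ground-truth-labelled trajectories for every pipeline stage.

Intended users: structural bioinformaticians analysing salt-bridge networks
and conformational gating in MD output, and method developers who need a
fully testable reference pipeline for two-state distance dynamics.

## Worked example

Simulate a BRIDGED-biased shuttle (k_ob = 3/ns, k_bo = 1/ns, 200 ns at 10 ps
frames), call states and measure the equilibrium:

```python
from bridgeswitch import (SyntheticShuttleParams, simulate_shuttle,
                          bridge_state_series, classify_shuttle_states,
                          shuttle_kinetics, anticorrelation)

truth = simulate_shuttle(SyntheticShuttleParams(k_ob=3, k_bo=1, n_frames=20_000, seed=1))
states = classify_shuttle_states(bridge_state_series(truth.d_interface),
                                 bridge_state_series(truth.d_remote))
stats = shuttle_kinetics(states)
rho = anticorrelation(truth.d_interface, truth.d_remote).rho
print(f"BRIDGED occupancy {stats.occupancy['BRIDGED']:.3f} "
      f"(stationary 0.75), exchange rate {stats.exchange_rate_per_ns:.2f}/ns, rho {rho:.3f}")
```

prints

```
BRIDGED occupancy 0.774 (stationary 0.75), exchange rate 1.45/ns, rho -0.872
```

i.e. the pipeline recovers the analytic stationary BRIDGED fraction
k_ob/(k_ob+k_bo) = 0.75 to sampling precision, and the two central–partner
distances are strongly anticorrelated (rho ≈ −0.87: the central residue is
bound to one partner or the other, rarely neither or both).

The same analysis runs end-to-end from a trajectory file:

```bash
bridgeswitch simulate --k-ob 3 --k-bo 1 --seed 1 --out-dir demo/
bridgeswitch report --config config.yaml        # trajectory, thresholds, interface residues
```

The numbered drivers under `analysis/` run the full synthetic study —
scenario suite generation, equilibrium tables, anticorrelation CIs, and the
PDB round-trip check — writing tables under `results/` and bulky
intermediates under `scratch/`:

```bash
python analysis/01_simulate_fixtures.py --seed 1
python analysis/02_shuttle_equilibrium.py --seed 1
python analysis/03_anticorrelation_ci.py --seed 1
python analysis/04_end_to_end_pdb.py --seed 1
```

## Layout

- `src/bridgeswitch/` — library: `io` (PDB/TSV), `saltbridges` (groups,
  distances, hysteretic calling), `shuttle` (network, motifs, kinetics),
  `stats` (smoothing, rho, Kabsch, cross-RMSD, bootstrap), `synthetic`
  (CTMC generator, toy embedding, fixture suite), `pipeline` + `cli`.
- `analysis/` — numbered narrative drivers.
- `docs/methods.md` — model, parameter and design documentation.
- `tests/` — unit, property and end-to-end acceptance tests.
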