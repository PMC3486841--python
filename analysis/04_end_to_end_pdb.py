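#!/usr/bin/env python
"""Full pipeline through the PDB interchange format.

Embeds a balanced shuttle as a toy multi-model PDB, re-reads it, runs the
config-driven pipeline (charged groups -> network -> motif -> kinetics ->
bootstrap CI -> cross-RMSD) and scores the result against the retained
ground truth.  Finding: coordinates survive the fixed-column round trip to
sub-millisecond-Å precision and the recovered state labels agree with truth
on >99% of frames.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from bridgeswitch import (
    AnalysisConfig,
    case_params,
    embed_toy_trajectory,
    read_multimodel_pdb,
    run_analysis,
    simulate_shuttle,
    write_multimodel_pdb,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-frames", type=int, default=2_000)
    args = parser.parse_args()

    scratch = ROOT / "scratch" / "end_to_end"
    scratch.mkdir(parents=True, exist_ok=True)
    params = case_params("wt_ubch6_like", args.seed, n_frames=args.n_frames)
    truth = simulate_shuttle(params)
    pdb = write_multimodel_pdb(embed_toy_trajectory(truth), scratch / "wt.pdb")
    traj = read_multimodel_pdb(pdb, dt_ps=params.dt_ps)

    config = AnalysisConfig(
        trajectory=str(pdb),
        interface_residues=("E105",),
        seed=args.seed,
        output_dir=str(scratch / "report"),
    )
    report = run_analysis(config, traj=traj)
    motif = report.motifs[0]

    states = pd.read_csv(scratch / "report" / "states.tsv", sep="\t")
    keep = truth.times_ps >= config.exclude_ps
    agreement = float(np.mean(states["state"].to_numpy() == truth.states[keep]))

    summary = pd.DataFrame(
        [
            {
                "rho": motif["rho"],
                "rho_ci_low": motif["rho_ci95"][0],
                "rho_ci_high": motif["rho_ci95"][1],
                "bridged_occupancy": motif["occupancy"]["BRIDGED"],
                "true_bridged": float(np.mean(truth.states[keep] == "BRIDGED")),
                "state_agreement": agreement,
                "cross_rmsd_max_A": report.cross_rmsd["max_A"],
                "n_frames": motif["n_frames"],
            }
        ]
    )
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    summary.to_csv(results / "end_to_end.tsv", sep="\t", index=False, float_format="%.4g")
    print(summary.to_string(index=False))
    print(f"\nfull report files under {scratch / 'report'}")


if __name__ == "__main__":
    main()
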