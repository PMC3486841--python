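"""Config-driven end-to-end analysis: trajectory -> report.

Stages, in order: read trajectory, identify charged groups under the
protonation policy, build the occupancy-filtered salt-bridge network, detect
shuttle motifs, classify open/bridged states and their kinetics, attach a
block-bootstrap CI to each motif's anticorrelation, and summarise
conformational stability with a (subsampled) cross-RMSD matrix.

The report is fully deterministic for a fixed config and seed: all randomness
flows from the single config seed, and no timestamps enter the payload.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigValidationError
from .io import Trajectory, read_multimodel_pdb, write_distance_series
from .saltbridges import (
    ProtonationPolicy,
    bridge_state_series,
    distance_series,
    identify_charged_groups,
)
from .shuttle import (
    build_bridge_network,
    classify_shuttle_states,
    detect_shuttle_motifs,
    shuttle_kinetics,
)
from .stats import block_bootstrap_ci, cross_rmsd_matrix, running_average

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "Report", "run_analysis"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All knobs of one analysis run.  Loadable from YAML, echoed in the report."""

    trajectory: str
    dt_ps: float = 10.0
    t0_ps: float = 0.0
    exclude_ps: float = 1000.0
    d_on: float = 4.0
    d_off: float = 6.0
    ph: float = 7.0
    histidine_charged: bool | None = None
    include_termini: bool = False
    interface_residues: tuple[str, ...] = ()
    rho_max: float = -0.5
    min_occupancy: float = 0.05
    window_ps: float = 100.0
    n_boot: int = 1000
    block_frames: int | None = None  # default: frames spanning ~1 ns
    cross_rmsd_selection: str = "CA,CB"
    cross_rmsd_max_frames: int = 150
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "interface_residues", tuple(self.interface_residues))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["interface_residues"] = list(self.interface_residues)
        return d

    @property
    def effective_block_frames(self) -> int:
        if self.block_frames is not None:
            return self.block_frames
        return max(1, round(1000.0 / self.dt_ps))


@dataclass(frozen=True)
class Report:
    """Serializable analysis result with full provenance."""

    config: dict
    version: str
    n_frames_total: int
    n_frames_analyzed: int
    charged_groups: list[str]
    edges: list[dict]
    motifs: list[dict]
    cross_rmsd: dict

    def payload(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.payload(), sort_keys=True, indent=2)


def _validate_interface_residues(config: AnalysisConfig, traj: Trajectory, groups) -> None:
    labels = {g.label for g in groups}
    for res in config.interface_residues:
        if res not in labels:
            raise ConfigValidationError(
                f"interface residue {res!r} not found among charged groups "
                f"{sorted(labels)} (stage: validation)"
            )


def run_analysis(config: AnalysisConfig, traj: Trajectory | None = None) -> Report:
    """Execute every stage and (optionally) write the report files.

    ``traj`` may be supplied directly to skip re-reading the PDB; by default it
    is read from ``config.trajectory``.  On fatal error nothing is written.
    """
    if traj is None:
        logger.info("reading trajectory %s", config.trajectory)
        traj = read_multimodel_pdb(config.trajectory, dt_ps=config.dt_ps, t0_ps=config.t0_ps)

    policy = ProtonationPolicy(pH=config.ph, histidine_charged=config.histidine_charged)
    groups = identify_charged_groups(traj.topology, policy, include_termini=config.include_termini)
    _validate_interface_residues(config, traj, groups)

    logger.info("building salt-bridge network over %d charged groups", len(groups))
    network = build_bridge_network(
        traj, groups,
        d_on=config.d_on, d_off=config.d_off,
        min_occupancy=config.min_occupancy, exclude_ps=config.exclude_ps,
    )
    motifs = detect_shuttle_motifs(
        network, traj,
        rho_max=config.rho_max, exclude_ps=config.exclude_ps,
        interface_residues=set(config.interface_residues),
    )
    logger.info("%d edges, %d shuttle motifs", len(network.edges), len(motifs))

    motif_reports: list[dict] = []
    motif_tables: list[pd.DataFrame] = []
    for motif in motifs:
        ds_i = distance_series(traj, motif.central, motif.interface_partner, config.exclude_ps)
        ds_r = distance_series(traj, motif.central, motif.remote_partner, config.exclude_ps)
        b_i = bridge_state_series(ds_i, config.d_on, config.d_off)
        b_r = bridge_state_series(ds_r, config.d_on, config.d_off)
        states = classify_shuttle_states(b_i, b_r)
        stats = shuttle_kinetics(states, rho=motif.rho)
        block = min(config.effective_block_frames, len(ds_i))
        ci = block_bootstrap_ci(
            ds_i, ds_r, n_boot=config.n_boot, block_frames=block, seed=config.seed
        )
        sm_i = running_average(ds_i, config.window_ps)
        sm_r = running_average(ds_r, config.window_ps)
        motif_reports.append(
            {
                "central": motif.central.label,
                "interface_partner": motif.interface_partner.label,
                "remote_partner": motif.remote_partner.label,
                "roles_assigned": motif.roles_assigned,
                "rho": motif.rho,
                "rho_ci95": [ci.ci_low, ci.ci_high],
                "occupancy": stats.occupancy,
                "n_exchanges": stats.n_exchanges,
                "exchange_rate_per_ns": stats.exchange_rate_per_ns,
                "dwell_mean_ps": stats.dwell_mean_ps,
                "dwell_median_ps": stats.dwell_median_ps,
                "n_frames": stats.n_frames,
                "duration_ns": stats.duration_ns,
            }
        )
        motif_tables.append(
            pd.DataFrame(
                {
                    "time_ps": ds_i.times_ps,
                    f"d_{motif.central.label}_{motif.interface_partner.label}_A": ds_i.values_A,
                    f"d_{motif.central.label}_{motif.remote_partner.label}_A": ds_r.values_A,
                    "smoothed_interface_A": sm_i.values_A,
                    "smoothed_remote_A": sm_r.values_A,
                    "bridge_interface": b_i.labels,
                    "bridge_remote": b_r.labels,
                    "state": states.states,
                }
            )
        )

    stride = max(1, int(np.ceil(traj.n_frames / config.cross_rmsd_max_frames)))
    xrmsd = cross_rmsd_matrix(traj, config.cross_rmsd_selection, frame_stride=stride)
    cross_summary = {
        "selection": xrmsd.atom_selection,
        "n_frames_used": int(xrmsd.frame_indices.size),
        "frame_stride": stride,
        "mean_A": xrmsd.mean_offdiag,
        "max_A": xrmsd.max,
    }

    report = Report(
        config=config.to_dict(),
        version=__version__,
        n_frames_total=traj.n_frames,
        n_frames_analyzed=network.n_frames,
        charged_groups=[g.label for g in groups],
        edges=[
            {
                "group_a": e.group_a.label,
                "group_b": e.group_b.label,
                "occupancy": e.occupancy,
                "mean_distance_A": e.mean_distance_A,
            }
            for e in network.edges
        ],
        motifs=motif_reports,
        cross_rmsd=cross_summary,
    )

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        pd.DataFrame(report.edges).to_csv(out / "edges.tsv", sep="\t", index=False)
        if motif_tables:
            motif_tables[0].to_csv(out / "states.tsv", sep="\t", index=False)
            cols = [c for c in motif_tables[0].columns if c.startswith(("time", "d_", "smoothed"))]
            motif_tables[0][cols].to_csv(out / "distances.tsv", sep="\t", index=False)
        pd.DataFrame(
            xrmsd.values,
            index=xrmsd.frame_indices,
            columns=xrmsd.frame_indices,
        ).to_csv(out / "cross_rmsd.tsv", sep="\t", float_format="%.4f")
        logger.info("report written to %s", out)
    return report
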