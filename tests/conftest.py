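"""Shared fixtures: tiny hand-built topologies/trajectories and PDB text helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bridgeswitch import AtomRecord, Topology, Trajectory

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def atom(serial, name, resname, chain="A", seq=1, x=0.0, y=0.0, z=0.0):
    return AtomRecord(serial, name, resname, chain, seq, x, y, z)


def pdb_line(serial, name, resname, chain, seq, x, y, z, altloc=" ", icode=" ", record="ATOM  "):
    name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"{record}{serial:5d} {name_f}{altloc}{resname:>3s} {chain}{seq:4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {name[0]}\n"
    )


@pytest.fixture
def toy_bridge_traj():
    """LYS NZ fixed at origin; ASP OD1 oscillating between 3 Å and 8.5 Å."""
    atoms = (
        atom(1, "NZ", "LYS", seq=9),
        atom(2, "OD1", "ASP", seq=37),
        atom(3, "CA", "GLY", seq=50),
    )
    d = np.array([3.0, 3.2, 8.5, 8.8, 3.1, 8.6, 3.0, 3.3])
    coords = np.zeros((d.size, 3, 3))
    coords[:, 1, 0] = d
    coords[:, 2] = (5.0, 5.0, 5.0)
    return Trajectory(Topology(atoms), coords, dt_ps=10.0)


@pytest.fixture(scope="session")
def wt_truth():
    """One biased shuttle path reused across tests (k_ob=3, k_bo=1, 20 000 frames)."""
    from bridgeswitch import SyntheticShuttleParams, simulate_shuttle

    return simulate_shuttle(SyntheticShuttleParams(k_ob=3.0, k_bo=1.0, n_frames=20_000, seed=2024))
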