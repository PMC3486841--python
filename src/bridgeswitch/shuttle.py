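"""Shuttle-motif detection and open/bridged equilibrium quantification.

The motif of interest is a central basic residue (a lysine analogous to
K109/K117 in the UbcH6/UbcH8 pair) that alternates between two acidic
partners: an *interface* acid whose availability gates E3-RING binding, and a
*remote* acid that sequesters the lysine away from it.  Per frame:

    OPEN       remote bridge formed, interface bridge broken (binding-competent)
    BRIDGED    interface bridge formed, remote broken       (binding-impaired)
    BIFURCATED both bridges formed
    UNBOUND    neither bridge formed

Exchange counting is gap-tolerant: BIFURCATED/UNBOUND frames between an OPEN
and a BRIDGED stretch are transient intermediates and do not reset the
transition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np

from .errors import AlignmentError, InsufficientDataError
from .io import Trajectory, check_same_times
from .saltbridges import (
    BridgeStateSeries,
    ChargedGroup,
    bridge_state_series,
    distance_series,
)
from .stats import anticorrelation

logger = logging.getLogger(__name__)

__all__ = [
    "ShuttleState",
    "BridgeEdge",
    "SaltBridgeNetwork",
    "ShuttleMotif",
    "ShuttleStateSeries",
    "ShuttleStats",
    "build_bridge_network",
    "detect_shuttle_motifs",
    "classify_shuttle_states",
    "shuttle_kinetics",
]


class ShuttleState(str, Enum):
    OPEN = "OPEN"
    BRIDGED = "BRIDGED"
    BIFURCATED = "BIFURCATED"
    UNBOUND = "UNBOUND"


_CORE = (ShuttleState.OPEN.value, ShuttleState.BRIDGED.value)


@dataclass(frozen=True)
class BridgeEdge:
    group_a: ChargedGroup
    group_b: ChargedGroup
    occupancy: float
    mean_distance_A: float

    def __post_init__(self):
        if self.group_a.sign * self.group_b.sign >= 0:
            raise ValueError("salt-bridge edges connect opposite charges only")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")


@dataclass(frozen=True)
class SaltBridgeNetwork:
    """Time-averaged salt-bridge contact network over a trajectory."""

    groups: tuple[ChargedGroup, ...]
    edges: tuple[BridgeEdge, ...]
    n_frames: int

    def partners_of(self, group: ChargedGroup) -> list[tuple[ChargedGroup, BridgeEdge]]:
        out = []
        for e in self.edges:
            if e.group_a is group or e.group_a == group:
                out.append((e.group_b, e))
            elif e.group_b is group or e.group_b == group:
                out.append((e.group_a, e))
        return out

    def as_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for grp in self.groups:
            g.add_node(grp.label, sign=grp.sign, group_type=grp.group_type.value)
        for e in self.edges:
            g.add_edge(
                e.group_a.label,
                e.group_b.label,
                occupancy=e.occupancy,
                mean_distance_A=e.mean_distance_A,
            )
        return g


def build_bridge_network(
    traj: Trajectory,
    groups: list[ChargedGroup],
    d_on: float = 4.0,
    d_off: float = 6.0,
    min_occupancy: float = 0.05,
    exclude_ps: float = 0.0,
) -> SaltBridgeNetwork:
    """Edges for every opposite-sign pair with FORMED occupancy >= min_occupancy."""
    if not groups:
        logger.info("no charged groups; returning empty network")
        return SaltBridgeNetwork(groups=(), edges=(), n_frames=0)
    edges: list[BridgeEdge] = []
    n_frames = 0
    for ga, gb in itertools.combinations(groups, 2):
        if ga.sign * gb.sign >= 0:
            continue
        ds = distance_series(traj, ga, gb, exclude_ps=exclude_ps)
        n_frames = len(ds)
        occ = bridge_state_series(ds, d_on=d_on, d_off=d_off).occupancy
        if occ >= min_occupancy:
            edges.append(
                BridgeEdge(
                    group_a=ga,
                    group_b=gb,
                    occupancy=occ,
                    mean_distance_A=float(ds.values_A.mean()),
                )
            )
    return SaltBridgeNetwork(groups=tuple(groups), edges=tuple(edges), n_frames=n_frames)


@dataclass(frozen=True)
class ShuttleMotif:
    """A (central basic, interface acid, remote acid) triple with its rho.

    Which acidic partner is the interface one cannot be inferred from geometry
    alone; it comes from user annotation (``interface_residues``).  When the
    annotation decides neither partner, roles are left in (chain, seq) order
    with ``roles_assigned`` False.
    """

    central: ChargedGroup
    interface_partner: ChargedGroup
    remote_partner: ChargedGroup
    rho: float
    roles_assigned: bool = False

    def __post_init__(self):
        if self.central.sign != +1:
            raise ValueError("central group must be basic (+1)")
        if self.interface_partner.sign != -1 or self.remote_partner.sign != -1:
            raise ValueError("partner groups must be acidic (-1)")
        if self.interface_partner == self.remote_partner:
            raise ValueError("partners must be distinct")


def detect_shuttle_motifs(
    network: SaltBridgeNetwork,
    traj: Trajectory,
    rho_max: float = -0.5,
    exclude_ps: float = 0.0,
    interface_residues: set[str] | frozenset[str] | None = None,
) -> list[ShuttleMotif]:
    """Screen every basic hub with >= 2 acidic partners for anticorrelated pairs.

    For each candidate partner pair the Pearson rho between the two raw
    central–partner distance series is computed; pairs with rho <= rho_max are
    emitted, strongest anticorrelation first.
    """
    interface_residues = set(interface_residues or ())
    motifs: list[ShuttleMotif] = []
    for hub in network.groups:
        if hub.sign != +1:
            continue
        partners = [p for p, _ in network.partners_of(hub) if p.sign == -1]
        if len(partners) < 2:
            continue
        series = {
            p.label: distance_series(traj, hub, p, exclude_ps=exclude_ps) for p in partners
        }
        for pa, pb in itertools.combinations(partners, 2):
            rho = anticorrelation(series[pa.label], series[pb.label]).rho
            if rho > rho_max:
                continue
            in_a, in_b = pa.label in interface_residues, pb.label in interface_residues
            if in_a != in_b:
                iface, remote = (pa, pb) if in_a else (pb, pa)
                assigned = True
            else:
                iface, remote = sorted((pa, pb), key=lambda g: (g.chain, g.residue_seq))
                assigned = False
            motifs.append(
                ShuttleMotif(
                    central=hub,
                    interface_partner=iface,
                    remote_partner=remote,
                    rho=rho,
                    roles_assigned=assigned,
                )
            )
    motifs.sort(key=lambda m: m.rho)
    return motifs


@dataclass(frozen=True)
class ShuttleStateSeries:
    times_ps: np.ndarray
    states: np.ndarray  # str array of ShuttleState values

    def __len__(self) -> int:
        return self.times_ps.size

    def fraction(self, state: ShuttleState) -> float:
        return float(np.mean(self.states == state.value))


def classify_shuttle_states(
    b_interface: BridgeStateSeries, b_remote: BridgeStateSeries
) -> ShuttleStateSeries:
    """Combine the two bridge-state series into per-frame shuttle states."""
    if len(b_interface) != len(b_remote):
        raise AlignmentError(
            f"bridge series lengths differ: {len(b_interface)} vs {len(b_remote)}"
        )
    check_same_times(b_interface.times_ps, b_remote.times_ps, "bridge state series")
    i = b_interface.formed
    r = b_remote.formed
    states = np.select(
        [i & ~r, ~i & r, i & r],
        [ShuttleState.BRIDGED.value, ShuttleState.OPEN.value, ShuttleState.BIFURCATED.value],
        default=ShuttleState.UNBOUND.value,
    ).astype("U10")
    return ShuttleStateSeries(times_ps=b_interface.times_ps, states=states)


@dataclass(frozen=True)
class ShuttleStats:
    """Occupancies, exchange kinetics and dwell times of a shuttle motif."""

    occupancy: dict[str, float]
    n_exchanges: int
    exchange_rate_per_ns: float
    dwell_mean_ps: dict[str, float]
    dwell_median_ps: dict[str, float]
    n_frames: int
    duration_ns: float
    rho: float | None = None

    def __post_init__(self):
        total = sum(self.occupancy.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"occupancies must sum to 1, got {total}")
        if self.n_exchanges < 0:
            raise ValueError("n_exchanges must be >= 0")


def _runs(states: np.ndarray) -> list[tuple[str, int]]:
    """(label, run length) for each maximal contiguous run."""
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    bounds = np.concatenate(([0], change, [states.size]))
    return [(str(states[a]), int(b - a)) for a, b in zip(bounds[:-1], bounds[1:])]


def shuttle_kinetics(states: ShuttleStateSeries, rho: float | None = None) -> ShuttleStats:
    """Occupancies, gap-tolerant OPEN<->BRIDGED exchange count and dwell times.

    Dwell times are contiguous-run lengths times the frame interval (censored
    first/last runs included).  The exchange rate divides the count by the
    total sampled time n_frames * dt in ns.
    """
    n = len(states)
    if n < 2:
        raise InsufficientDataError("need at least 2 frames for kinetics")
    dt = float(np.median(np.diff(states.times_ps)))
    occupancy = {s.value: states.fraction(s) for s in ShuttleState}

    core_seq = states.states[np.isin(states.states, _CORE)]
    n_exchanges = int(np.sum(core_seq[1:] != core_seq[:-1])) if core_seq.size else 0

    duration_ns = n * dt / 1000.0
    dwell_mean: dict[str, float] = {}
    dwell_median: dict[str, float] = {}
    runs = _runs(states.states)
    for s in ShuttleState:
        lengths = np.array([m for lab, m in runs if lab == s.value], dtype=float) * dt
        dwell_mean[s.value] = float(lengths.mean()) if lengths.size else float("nan")
        dwell_median[s.value] = float(np.median(lengths)) if lengths.size else float("nan")

    return ShuttleStats(
        occupancy=occupancy,
        n_exchanges=n_exchanges,
        exchange_rate_per_ns=n_exchanges / duration_ns,
        dwell_mean_ps=dwell_mean,
        dwell_median_ps=dwell_median,
        n_frames=n,
        duration_ns=duration_ns,
        rho=rho,
    )
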