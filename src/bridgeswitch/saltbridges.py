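"""Charged-group definitions and salt-bridge distance/state calling.

A salt bridge is called on the *minimum* distance between the charge-bearing
terminal atoms of two oppositely charged side-chain groups (e.g. Lys NZ
against either Asp carboxylate oxygen).  State assignment is hysteretic:
FORMED below ``d_on``, BROKEN above ``d_off``, and the previous label is held
inside the gap, which suppresses boundary flicker and makes dwell/exchange
statistics robust.

Histidine is treated as charged (imidazolium) below pH 6 by default — yeast
cytosol sits near pH 5.5, where solvent-exposed histidines are expected to be
protonated — and neutral otherwise; the call is overridable per residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    EmptyAnalysisError,
    GroupLookupError,
    ParameterError,
    SeriesValidationError,
)
from .io import DistanceSeries, Topology, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "GroupType",
    "ChargedGroup",
    "ProtonationPolicy",
    "BridgeStateSeries",
    "identify_charged_groups",
    "min_pair_distance",
    "distance_series",
    "bridge_state_series",
]


class GroupType(str, Enum):
    CARBOXYLATE = "carboxylate"
    AMMONIUM = "ammonium"
    GUANIDINIUM = "guanidinium"
    IMIDAZOLIUM = "imidazolium"
    N_TERMINUS = "n_terminus"
    C_TERMINUS = "c_terminus"


# residue name -> (group type, sign, charge-bearing atom names)
_SIDECHAIN_GROUPS: dict[str, tuple[GroupType, int, tuple[str, ...]]] = {
    "ASP": (GroupType.CARBOXYLATE, -1, ("OD1", "OD2")),
    "GLU": (GroupType.CARBOXYLATE, -1, ("OE1", "OE2")),
    "LYS": (GroupType.AMMONIUM, +1, ("NZ",)),
    "ARG": (GroupType.GUANIDINIUM, +1, ("NE", "NH1", "NH2")),
    "HIS": (GroupType.IMIDAZOLIUM, +1, ("ND1", "NE2")),
}

_ONE_LETTER = {"ASP": "D", "GLU": "E", "LYS": "K", "ARG": "R", "HIS": "H"}


@dataclass(frozen=True)
class ChargedGroup:
    """An ionizable group: residue identity, charge sign and charge atoms."""

    chain: str
    residue_seq: int
    residue_name: str
    group_type: GroupType
    sign: int
    atom_names: tuple[str, ...]
    atom_indices: tuple[int, ...]

    @property
    def label(self) -> str:
        """Field-style label, e.g. Glu 105 -> 'E105'."""
        code = _ONE_LETTER.get(self.residue_name, self.residue_name)
        suffix = ""
        if self.group_type in (GroupType.N_TERMINUS, GroupType.C_TERMINUS):
            suffix = "^Nt" if self.group_type is GroupType.N_TERMINUS else "^Ct"
        return f"{code}{self.residue_seq}{suffix}"


@dataclass(frozen=True)
class ProtonationPolicy:
    """pH-driven protonation calls for titratable histidines.

    ``histidine_charged`` forces the global call; ``overrides`` maps residue
    labels (e.g. ``"H75"``) to per-residue calls.
    """

    pH: float = 7.0
    histidine_charged: bool | None = None
    overrides: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.pH <= 14.0:
            raise ParameterError(f"pH must be in [0, 14], got {self.pH}")

    def his_is_charged(self, label: str) -> bool:
        if label in self.overrides:
            return self.overrides[label]
        if self.histidine_charged is not None:
            return self.histidine_charged
        return self.pH < 6.0


def identify_charged_groups(
    topology: Topology,
    policy: ProtonationPolicy | None = None,
    include_termini: bool = False,
) -> list[ChargedGroup]:
    """Enumerate ionizable groups present in a topology, in (chain, seq) order.

    A residue whose charge atoms are entirely absent is skipped with a logged
    warning; partial groups (e.g. a single carboxylate oxygen in reduced
    models) are kept with the atoms found.
    """
    policy = policy or ProtonationPolicy()
    groups: list[ChargedGroup] = []

    def _build(key, gtype, sign, wanted) -> None:
        chain, seq, resname = key
        positions = topology.residue_index[key]
        found = [
            (topology.atoms[i].name, i) for i in positions if topology.atoms[i].name in wanted
        ]
        if not found:
            logger.warning(
                "residue %s %s%d claims %s group but none of %s present; skipped",
                resname, chain, seq, gtype.value, wanted,
            )
            return
        groups.append(
            ChargedGroup(
                chain=chain,
                residue_seq=seq,
                residue_name=resname,
                group_type=gtype,
                sign=sign,
                atom_names=tuple(n for n, _ in found),
                atom_indices=tuple(i for _, i in found),
            )
        )

    residues = sorted(topology.residue_index, key=lambda k: (k[0], k[1]))
    for key in residues:
        resname = key[2]
        if resname not in _SIDECHAIN_GROUPS:
            continue
        gtype, sign, wanted = _SIDECHAIN_GROUPS[resname]
        if gtype is GroupType.IMIDAZOLIUM:
            label = f"{_ONE_LETTER['HIS']}{key[1]}"
            if not policy.his_is_charged(label):
                continue
        _build(key, gtype, sign, set(wanted))

    if include_termini:
        by_chain: dict[str, list] = {}
        for key in residues:
            by_chain.setdefault(key[0], []).append(key)
        for chain_keys in by_chain.values():
            _build(chain_keys[0], GroupType.N_TERMINUS, +1, {"N"})
            _build(chain_keys[-1], GroupType.C_TERMINUS, -1, {"O", "OXT"})

    groups.sort(key=lambda g: (g.chain, g.residue_seq, g.group_type.value))
    return groups


def min_pair_distance(frame: np.ndarray, group_a: ChargedGroup, group_b: ChargedGroup) -> float:
    """Minimum Euclidean distance (Å) over all charge-atom pairs of two groups."""
    frame = np.asarray(frame, dtype=float)
    n = frame.shape[0]
    for g in (group_a, group_b):
        if not g.atom_indices or max(g.atom_indices) >= n:
            raise GroupLookupError(f"group {g.label} references atoms absent from frame")
    a = frame[list(group_a.atom_indices)]
    b = frame[list(group_b.atom_indices)]
    return float(cdist(a, b).min())


def distance_series(
    traj: Trajectory,
    group_a: ChargedGroup,
    group_b: ChargedGroup,
    exclude_ps: float = 1000.0,
) -> DistanceSeries:
    """Per-frame minimum inter-group distance, dropping the initial transient.

    Frames earlier than ``t0 + exclude_ps`` are excluded (the conventional
    equilibration discard; 1 ns by default).
    """
    if exclude_ps < 0:
        raise ParameterError("exclude_ps must be >= 0")
    times = traj.times_ps
    keep = times >= traj.t0_ps + exclude_ps
    if not keep.any():
        raise EmptyAnalysisError(
            f"exclude_ps={exclude_ps} drops all {traj.n_frames} frames"
        )
    n_atoms = traj.topology.n_atoms
    for g in (group_a, group_b):
        if not g.atom_indices or max(g.atom_indices) >= n_atoms:
            raise GroupLookupError(f"group {g.label} references atoms absent from trajectory")
    a = traj.coords[keep][:, list(group_a.atom_indices), :]
    b = traj.coords[keep][:, list(group_b.atom_indices), :]
    d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)
    return DistanceSeries(
        times_ps=times[keep],
        values_A=d.min(axis=(1, 2)),
        label_a=group_a.label,
        label_b=group_b.label,
    )


@dataclass(frozen=True)
class BridgeStateSeries:
    """Hysteretic FORMED/BROKEN labels for one salt-bridge distance series."""

    times_ps: np.ndarray
    formed: np.ndarray  # bool per frame
    d_on: float
    d_off: float
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self):
        if not self.d_on < self.d_off:
            raise ParameterError(f"d_on ({self.d_on}) must be < d_off ({self.d_off})")
        if self.times_ps.shape != self.formed.shape:
            raise SeriesValidationError("times and labels must have equal length")

    def __len__(self) -> int:
        return self.times_ps.size

    @property
    def labels(self) -> np.ndarray:
        return np.where(self.formed, "FORMED", "BROKEN")

    @property
    def occupancy(self) -> float:
        """Fraction of frames with the bridge FORMED."""
        return float(self.formed.mean())


def bridge_state_series(
    series: DistanceSeries, d_on: float = 4.0, d_off: float = 6.0
) -> BridgeStateSeries:
    """Two-threshold (hysteretic) salt-bridge state calling.

    FORMED below ``d_on``, BROKEN above ``d_off``; inside the gap the previous
    label is held.  The first frame, if it falls in the gap, is labelled by the
    midpoint rule: FORMED iff value < (d_on + d_off) / 2.
    """
    if not d_on < d_off:
        raise ParameterError(f"d_on ({d_on}) must be < d_off ({d_off})")
    if len(series) == 0:
        raise EmptyAnalysisError("cannot assign bridge states to an empty series")
    v = series.values_A
    raw = np.where(v < d_on, 1, np.where(v > d_off, 0, -1))
    if raw[0] == -1:
        raw[0] = 1 if v[0] < 0.5 * (d_on + d_off) else 0
    # forward-fill the in-gap (-1) entries with the last decided label
    decided = np.where(raw != -1, np.arange(raw.size), 0)
    np.maximum.accumulate(decided, out=decided)
    formed = raw[decided].astype(bool)
    return BridgeStateSeries(
        times_ps=series.times_ps,
        formed=formed,
        d_on=d_on,
        d_off=d_off,
        label_a=series.label_a,
        label_b=series.label_b,
    )
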