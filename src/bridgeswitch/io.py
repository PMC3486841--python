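"""Trajectory and distance-series I/O.

Trajectories are exchanged as multi-model PDB files (wwPDB v3.3 fixed columns,
one MODEL/ENDMDL block per frame).  PDB carries no time axis, so the frame
interval ``dt_ps`` is supplied by the caller and attached as metadata; frame
``i`` sits at ``t0_ps + i * dt_ps``.

Distance time series are exchanged as two-column TSV
(``time_ps``, ``distance_A``) with ``# key=value`` metadata lines carrying the
group labels.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    PDBParseError,
    SchemaError,
    SeriesValidationError,
    TopologyMismatchError,
)

__all__ = [
    "AtomRecord",
    "Topology",
    "Trajectory",
    "DistanceSeries",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_distance_series",
    "write_distance_series",
]


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record.  ``residue_seq`` is kept verbatim (no renumbering)."""

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_seq: int
    x: float
    y: float
    z: float
    hetatm: bool = False

    def __post_init__(self):
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not all(np.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinates for atom {self.serial} {self.name}")

    @property
    def identity(self) -> tuple[str, str, str, int]:
        """Identity used for topology matching (everything but coordinates/serial)."""
        return (self.name, self.residue_name, self.chain, self.residue_seq)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_seq, self.residue_name)


@dataclass(frozen=True)
class Topology:
    """Ordered atom identities shared by every frame of a trajectory."""

    atoms: tuple[AtomRecord, ...]

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("topology must contain at least one atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @cached_property
    def residue_index(self) -> dict[tuple[str, int, str], list[int]]:
        """(chain, residue_seq, residue_name) -> positions of its atoms."""
        index: dict[tuple[str, int, str], list[int]] = {}
        for i, atom in enumerate(self.atoms):
            index.setdefault(atom.residue_key, []).append(i)
        return index

    def residues(self) -> list[tuple[str, int, str]]:
        """Residue keys in order of first appearance."""
        return list(self.residue_index)

    def atom_positions(self, names: set[str]) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.name in names]

    def matches(self, atoms: list[AtomRecord]) -> str | None:
        """None if ``atoms`` matches this topology, else a human-readable reason."""
        if len(atoms) != self.n_atoms:
            return f"atom count {len(atoms)} != {self.n_atoms}"
        for i, (ref, got) in enumerate(zip(self.atoms, atoms)):
            if ref.identity != got.identity:
                return f"atom {i + 1}: {got.identity} != {ref.identity}"
        return None


@dataclass(frozen=True)
class Trajectory:
    """Frames of coordinates over a fixed topology at uniform time spacing.

    coords has shape (n_frames, n_atoms, 3), in Å.
    """

    topology: Topology
    coords: np.ndarray
    dt_ps: float = 10.0
    t0_ps: float = 0.0

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"coords must be (n_frames, n_atoms, 3), got {coords.shape}")
        if coords.shape[0] < 1:
            raise ValueError("trajectory must have at least one frame")
        if coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {coords.shape[1]} atoms, topology has {self.topology.n_atoms}"
            )
        if not self.dt_ps > 0:
            raise ValueError("dt_ps must be positive")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times_ps(self) -> np.ndarray:
        return self.t0_ps + self.dt_ps * np.arange(self.n_frames)


@dataclass(frozen=True)
class DistanceSeries:
    """A per-frame minimum inter-group distance curve, in Å against ps."""

    times_ps: np.ndarray
    values_A: np.ndarray
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self):
        t = np.asarray(self.times_ps, dtype=float)
        v = np.asarray(self.values_A, dtype=float)
        object.__setattr__(self, "times_ps", t)
        object.__setattr__(self, "values_A", v)
        if t.shape != v.shape or t.ndim != 1:
            raise SeriesValidationError(
                f"times ({t.shape}) and values ({v.shape}) must be equal-length 1-D"
            )
        if t.size and np.any(np.diff(t) <= 0):
            raise SeriesValidationError("times must be strictly increasing")
        if np.any(~np.isfinite(v)) or np.any(v < 0):
            raise SeriesValidationError("distances must be finite and non-negative")

    def __len__(self) -> int:
        return self.times_ps.size

    @property
    def dt_ps(self) -> float:
        """Median frame spacing (series are uniform in practice)."""
        if len(self) < 2:
            return float("nan")
        return float(np.median(np.diff(self.times_ps)))


# --------------------------------------------------------------------------
# multi-model PDB
# --------------------------------------------------------------------------

_RECORDS = ("ATOM  ", "HETATM")


def _parse_atom_line(line: str, lineno: int) -> AtomRecord | None:
    # wwPDB v3.3 fixed columns (0-based slices). Returns None for skipped altlocs.
    altloc = line[16:17]
    if altloc not in (" ", "", "A"):
        return None
    icode = line[26:27]
    if icode not in (" ", ""):
        raise PDBParseError(f"insertion code {icode!r} not supported", lineno)
    try:
        return AtomRecord(
            serial=int(line[6:11]),
            name=line[12:16].strip(),
            residue_name=line[17:20].strip(),
            chain=line[21:22] or " ",
            residue_seq=int(line[22:26]),
            x=float(line[30:38]),
            y=float(line[38:46]),
            z=float(line[46:54]),
            hetatm=line.startswith("HETATM"),
        )
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"unparseable ATOM/HETATM record ({exc})", lineno) from exc


def read_multimodel_pdb(path: str | Path, dt_ps: float = 10.0, t0_ps: float = 0.0) -> Trajectory:
    """Read a (multi-)model PDB file into a :class:`Trajectory`.

    One frame per MODEL/ENDMDL block; a file without MODEL records yields a
    single frame.  The topology is taken from the first model and every later
    model must match it atom-for-atom.  Alternate locations other than blank
    or 'A' are skipped; insertion codes are rejected.
    """
    if not dt_ps > 0:
        raise ValueError("dt_ps must be positive")
    path = Path(path)
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] | None = None
    loose: list[AtomRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record == "MODEL ":
                current = []
            elif record == "ENDMDL":
                if current is None:
                    raise PDBParseError("ENDMDL without matching MODEL", lineno)
                models.append(current)
                current = None
            elif record in _RECORDS:
                atom = _parse_atom_line(line, lineno)
                if atom is None:
                    continue
                (current if current is not None else loose).append(atom)
    if current is not None:  # MODEL without trailing ENDMDL
        models.append(current)
    if not models:
        models = [loose]
    elif loose:
        raise PDBParseError(f"{len(loose)} ATOM records outside MODEL blocks in {path.name}")
    if not models[0]:
        raise PDBParseError(f"no atoms found in {path}")

    topology = Topology(tuple(models[0]))
    for k, model in enumerate(models[1:], start=2):
        reason = topology.matches(model)
        if reason is not None:
            raise TopologyMismatchError(f"model {k} does not match model 1 topology: {reason}")
    coords = np.array([[(a.x, a.y, a.z) for a in m] for m in models], dtype=float)
    return Trajectory(topology=topology, coords=coords, dt_ps=dt_ps, t0_ps=t0_ps)


def _format_atom_name(name: str) -> str:
    # Names shorter than 4 chars start in column 14 per convention.
    return f" {name:<3s}" if len(name) < 4 else name[:4]


def _guess_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> Path:
    """Write one MODEL/ENDMDL block per frame, coordinates to 3 decimals."""
    path = Path(path)
    buf = _stdio.StringIO()
    atoms = traj.topology.atoms
    for i in range(traj.n_frames):
        buf.write(f"MODEL     {i + 1:4d}\n")
        frame = traj.coords[i]
        for a, (x, y, z) in zip(atoms, frame):
            record = "HETATM" if a.hetatm else "ATOM  "
            buf.write(
                f"{record}{a.serial % 100000:5d} {_format_atom_name(a.name)} "
                f"{a.residue_name:>3s} {a.chain}{a.residue_seq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {_guess_element(a.name):>2s}\n"
            )
        buf.write("ENDMDL\n")
    buf.write("END\n")
    path.write_text(buf.getvalue())
    return path


# --------------------------------------------------------------------------
# distance-series TSV
# --------------------------------------------------------------------------


def write_distance_series(series: DistanceSeries, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame({"time_ps": series.times_ps, "distance_A": series.values_A})
    with path.open("w") as fh:
        fh.write(f"# label_a={series.label_a}\n")
        fh.write(f"# label_b={series.label_b}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return path


def read_distance_series(path: str | Path) -> DistanceSeries:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            if value:
                meta[key.strip()] = value.strip()
    table = pd.read_csv(path, sep="\t", comment="#")
    for col in ("time_ps", "distance_A"):
        if col not in table.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    try:
        return DistanceSeries(
            times_ps=table["time_ps"].to_numpy(float),
            values_A=table["distance_A"].to_numpy(float),
            label_a=meta.get("label_a", "a"),
            label_b=meta.get("label_b", "b"),
        )
    except SeriesValidationError as exc:
        raise SeriesValidationError(f"{path.name}: {exc}") from exc


def check_same_times(a_times: np.ndarray, b_times: np.ndarray, what: str = "series") -> None:
    """Raise :class:`AlignmentError` unless two time axes coincide exactly."""
    if a_times.shape != b_times.shape or not np.array_equal(a_times, b_times):
        raise AlignmentError(f"{what} do not share a time axis")
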