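"""Trajectory statistics: smoothing, anticorrelation, superposition, bootstrap.

The central statistic is the Pearson product-moment correlation between the
two central–partner distance series of a shuttle motif,

    rho = sum (a_i - a_mean)(b_i - b_mean)
          / sqrt( sum (a_i - a_mean)^2 * sum (b_i - b_mean)^2 ),

which is strongly negative when the central residue binds its two partners in
a mutually exclusive way.  rho is computed on raw (unsmoothed) retained
frames; running-average smoothing (100 ps window by convention) is treated as
presentation-only, because smoothing inflates |rho| by construction.

Frame superposition uses the Kabsch algorithm restricted to proper rotations
(det = +1); the cross-RMSD matrix is the pairwise post-superposition RMSD
between frames over a named atom selection (Cα/Cβ by convention).

Uncertainty on rho is provided by a circular moving-block bootstrap, which
tolerates the serial correlation that frame-to-frame dynamics induce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateGeometryError,
    EmptyAnalysisError,
    InsufficientDataError,
    ParameterError,
    SelectionError,
    UndefinedCorrelationError,
)
from .io import DistanceSeries, Trajectory

__all__ = [
    "CorrelationResult",
    "KabschResult",
    "CrossRMSDMatrix",
    "running_average",
    "anticorrelation",
    "kabsch_rmsd",
    "cross_rmsd_matrix",
    "block_bootstrap_ci",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self):
        if abs(self.rho) > 1.0 + 1e-12:
            raise ValueError(f"|rho| > 1: {self.rho}")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("CI bounds must be given together")
        if self.ci_low is not None and not self.ci_low <= self.rho <= self.ci_high:
            raise ValueError("CI must contain the point estimate")


def _as_values(series) -> np.ndarray:
    if isinstance(series, DistanceSeries):
        return series.values_A
    return np.asarray(series, dtype=float)


def running_average(series: DistanceSeries, window_ps: float = 100.0) -> DistanceSeries:
    """Centered running mean over the largest odd frame window spanning <= window_ps.

    The window is truncated symmetrically at the series edges (so the first and
    last points keep their raw values), and the time axis is unchanged.
    """
    if not window_ps > 0:
        raise ParameterError("window_ps must be positive")
    n = len(series)
    if n == 0:
        raise EmptyAnalysisError("cannot smooth an empty series")
    if n == 1:
        return series
    dt = series.dt_ps
    half = int(np.floor(window_ps / (2.0 * dt) + 1e-9))  # window = 2*half + 1 frames
    if half == 0:
        return series
    v = series.values_A
    csum = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    smoothed = (csum[idx + h + 1] - csum[idx - h]) / (2 * h + 1)
    return DistanceSeries(
        times_ps=series.times_ps,
        values_A=smoothed,
        label_a=series.label_a,
        label_b=series.label_b,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    ssa = float(ac @ ac)
    ssb = float(bc @ bc)
    if ssa == 0.0 or ssb == 0.0:
        raise UndefinedCorrelationError("correlation undefined for a constant series")
    return float(np.clip((ac @ bc) / np.sqrt(ssa * ssb), -1.0, 1.0))


def anticorrelation(series_a, series_b) -> CorrelationResult:
    """Pearson correlation between two (distance) series of equal length >= 3."""
    a = _as_values(series_a)
    b = _as_values(series_b)
    if a.shape != b.shape:
        raise AlignmentError(f"series lengths differ: {a.size} vs {b.size}")
    if a.size < 3:
        raise InsufficientDataError("need at least 3 points for a correlation")
    return CorrelationResult(rho=_pearson(a, b), n=int(a.size))


@dataclass(frozen=True)
class KabschResult:
    """Optimal proper-rotation superposition of y onto x: y_fit = y @ R.T + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def kabsch_rmsd(
    coords_x: np.ndarray, coords_y: np.ndarray, weights: np.ndarray | None = None
) -> KabschResult:
    """Least-squares rigid superposition (Kabsch, proper rotations only).

    Reflections are corrected by flipping the sign of the smallest singular
    direction when det(V U^T) < 0.  Requires >= 3 non-collinear atoms.
    """
    x = np.asarray(coords_x, dtype=float)
    y = np.asarray(coords_y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise DegenerateGeometryError(f"coordinate shapes must match (n, 3): {x.shape} vs {y.shape}")
    n = x.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 atoms for superposition")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ParameterError("weights must be non-negative with positive sum")
        w = w / w.sum()
    xbar = w @ x
    ybar = w @ y
    xc = x - xbar
    yc = y - ybar
    for c in (xc, yc):
        s = np.linalg.svd(c * np.sqrt(w)[:, None], compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise DegenerateGeometryError("collinear atom set: superposition not unique")
    h = (yc * w[:, None]).T @ xc  # covariance mapping y -> x
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = xbar - rotation @ ybar
    yfit = yc @ rotation.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (xc - yfit) ** 2)))
    return KabschResult(rotation=rotation, translation=translation, rmsd=rmsd)


@dataclass(frozen=True)
class CrossRMSDMatrix:
    """Pairwise post-superposition RMSD between frames over an atom selection."""

    values: np.ndarray
    atom_selection: str
    frame_indices: np.ndarray  # original frame numbers of the rows/columns

    def __post_init__(self):
        m = self.values
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("cross-RMSD matrix must be square")

    @property
    def mean_offdiag(self) -> float:
        n = self.values.shape[0]
        if n < 2:
            return 0.0
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].mean())

    @property
    def max(self) -> float:
        return float(self.values.max())


def cross_rmsd_matrix(
    traj: Trajectory, atom_selection: str = "CA,CB", frame_stride: int = 1
) -> CrossRMSDMatrix:
    """Symmetric matrix of frame-vs-frame RMSD after optimal superposition.

    ``atom_selection`` is a comma-separated list of atom names (default Cα and
    Cβ).  ``frame_stride`` subsamples frames; the matrix is O(n^2) in frames.
    """
    if frame_stride < 1:
        raise ParameterError("frame_stride must be >= 1")
    names = {s.strip() for s in atom_selection.split(",") if s.strip()}
    positions = traj.topology.atom_positions(names)
    if len(positions) < 3:
        raise SelectionError(
            f"selection {atom_selection!r} matched {len(positions)} atoms; need >= 3"
        )
    frame_idx = np.arange(0, traj.n_frames, frame_stride)
    sel = traj.coords[np.ix_(frame_idx, positions)]
    k = len(frame_idx)
    matrix = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r = kabsch_rmsd(sel[i], sel[j]).rmsd
            matrix[i, j] = matrix[j, i] = r
    return CrossRMSDMatrix(values=matrix, atom_selection=atom_selection, frame_indices=frame_idx)


def block_bootstrap_ci(
    series_a,
    series_b,
    n_boot: int = 1000,
    block_frames: int = 100,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> CorrelationResult:
    """Circular moving-block bootstrap percentile CI for the Pearson rho.

    Paired frames are resampled in contiguous blocks of ``block_frames`` with
    circular wrap-around, preserving serial correlation up to the block length.
    Deterministic for a fixed seed.  Degenerate (constant) resamples, which can
    arise only for pathological inputs, are dropped.
    """
    a = _as_values(series_a)
    b = _as_values(series_b)
    if a.shape != b.shape:
        raise AlignmentError(f"series lengths differ: {a.size} vs {b.size}")
    n = a.size
    if block_frames < 1 or block_frames > n:
        raise ParameterError(f"block_frames must be in [1, {n}], got {block_frames}")
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    point = anticorrelation(a, b)
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n / block_frames))
    offsets = np.arange(block_frames)
    rhos = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(2e7 // max(n, 1))))
    pos = 0
    while pos < n_boot:
        m = min(chunk, n_boot - pos)
        starts = rng.integers(0, n, size=(m, n_blocks))
        idx = (starts[:, :, None] + offsets[None, None, :]).reshape(m, -1)[:, :n] % n
        ra = a[idx]
        rb = b[idx]
        rac = ra - ra.mean(axis=1, keepdims=True)
        rbc = rb - rb.mean(axis=1, keepdims=True)
        ssa = np.einsum("ij,ij->i", rac, rac)
        ssb = np.einsum("ij,ij->i", rbc, rbc)
        cov = np.einsum("ij,ij->i", rac, rbc)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.sqrt(ssa * ssb)
        rhos[pos : pos + m] = np.clip(r, -1.0, 1.0)
        pos += m
    rhos = rhos[np.isfinite(rhos)]
    alpha = 100.0 * (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(rhos, [alpha, 100.0 - alpha])
    # percentile intervals can exclude the point estimate in edge cases; widen
    lo = min(float(lo), point.rho)
    hi = max(float(hi), point.rho)
    return CorrelationResult(rho=point.rho, n=n, ci_low=lo, ci_high=hi)
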