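"""Functional-connectivity profiles: construction, vectorization, regularization.

A subject's FC profile is the r x r matrix of Pearson correlations between
the time courses of r regions of interest (ROIs).  Downstream stages work on
the deduplicated strict-upper-triangle "edge vector" of length r(r-1)/2; the
:class:`EdgeIndex` fixes the canonical row-major order once so every module
agrees on which flat position is which ROI pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeries",
    "FCProfile",
    "EdgeIndex",
    "ZeroVarianceError",
    "NotPositiveDefiniteError",
    "compute_fc_profile",
    "vectorize_upper",
    "devectorize_upper",
    "ensure_spd",
    "spd_shrinkage_for",
    "read_timeseries",
    "read_profile",
    "write_profile",
]

SYM_TOL = 1e-12  # absolute tolerance for symmetry / unit-diagonal validation


class ZeroVarianceError(ValueError):
    """An ROI time course has zero variance; its correlations are undefined."""


class NotPositiveDefiniteError(ValueError):
    """A matrix required to be positive definite is singular."""


@dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's ROI time courses.

    Parameters
    ----------
    subject_id : str
    data : ndarray, shape (T, r)
        Rows are time points, columns are ROIs.  Arbitrary signal units.
    sampling_interval : float
        Seconds between consecutive rows (TR).
    """

    subject_id: str
    data: np.ndarray
    sampling_interval: float = 1.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("time series must be a 2-D array (T x r)")
        T, r = data.shape
        if T < 3:
            raise ValueError(f"need at least 3 time points, got {T}")
        if r < 2:
            raise ValueError(f"need at least 2 ROIs, got {r}")
        if not np.all(np.isfinite(data)):
            raise ValueError("time series contains non-finite values")
        sd = data.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ZeroVarianceError(
                f"ROI column(s) {bad.tolist()} have zero variance"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class FCProfile:
    """A subject's symmetric r x r Pearson correlation matrix (unit diagonal)."""

    subject_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("FC profile must be square")
        if not np.all(np.isfinite(m)):
            raise ValueError("FC profile contains non-finite values")
        if np.abs(m - m.T).max() > SYM_TOL:
            raise ValueError(f"FC profile not symmetric to {SYM_TOL}")
        if np.abs(np.diag(m) - 1.0).max() > SYM_TOL:
            raise ValueError("FC profile diagonal must be 1")
        if m.min() < -1.0 - SYM_TOL or m.max() > 1.0 + SYM_TOL:
            raise ValueError("FC entries must lie in [-1, 1]")

    @property
    def r(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class EdgeIndex:
    """Canonical ordering of the r(r-1)/2 ROI pairs (i, j), i < j, row-major."""

    r: int
    rows: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    cols: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.r < 2:
            raise ValueError("EdgeIndex needs r >= 2")
        i, j = np.triu_indices(self.r, k=1)
        object.__setattr__(self, "rows", i)
        object.__setattr__(self, "cols", j)

    def __len__(self) -> int:
        return self.r * (self.r - 1) // 2

    @property
    def n_edges(self) -> int:
        return len(self)

    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.rows.tolist(), self.cols.tolist()))

    def flat_position(self, i: int, j: int) -> int:
        """Flat position of edge (i, j); order of i, j is irrelevant."""
        if i == j:
            raise ValueError("diagonal entries are not edges")
        i, j = (i, j) if i < j else (j, i)
        if not (0 <= i < j < self.r):
            raise IndexError(f"edge ({i}, {j}) out of range for r={self.r}")
        # row-major strict upper triangle offset
        return i * (2 * self.r - i - 1) // 2 + (j - i - 1)


def compute_fc_profile(ts: RoiTimeSeries) -> FCProfile:
    """Pearson-correlate every pair of ROI time courses.

    Entry (i, j) is the sample Pearson correlation of columns i and j of
    ``ts.data``; the diagonal is exactly 1.
    """
    m = np.corrcoef(ts.data, rowvar=False)
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return FCProfile(subject_id=ts.subject_id, matrix=m)


def vectorize_upper(fc: FCProfile | np.ndarray, idx: EdgeIndex) -> np.ndarray:
    """Extract the strict upper triangle in :class:`EdgeIndex` order."""
    m = fc.matrix if isinstance(fc, FCProfile) else np.asarray(fc, dtype=float)
    if m.shape != (idx.r, idx.r):
        raise ValueError(f"matrix shape {m.shape} does not match EdgeIndex r={idx.r}")
    return m[idx.rows, idx.cols].copy()


def devectorize_upper(
    vec: np.ndarray, idx: EdgeIndex, diagonal: float = 1.0
) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`: rebuild the symmetric matrix."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (idx.n_edges,):
        raise ValueError(
            f"vector length {vec.shape} does not match EdgeIndex ({idx.n_edges},)"
        )
    m = np.full((idx.r, idx.r), float(diagonal))
    m[idx.rows, idx.cols] = vec
    m[idx.cols, idx.rows] = vec
    return m


def ensure_spd(fc: FCProfile | np.ndarray, shrinkage: float = 1e-3) -> np.ndarray:
    """Shrink a symmetric matrix toward the identity to force positive definiteness.

    Returns ``(1 - g) * M + g * I`` for shrinkage ``g``.  FC matrices estimated
    from fewer time points than ROIs are rank deficient, so a strictly positive
    ``g`` is required before any Riemannian-geometry operation.

    Raises
    ------
    NotPositiveDefiniteError
        If ``shrinkage`` is 0 and the matrix is singular (or indefinite).
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    m = fc.matrix if isinstance(fc, FCProfile) else np.asarray(fc, dtype=float)
    out = (1.0 - shrinkage) * m + shrinkage * np.eye(m.shape[0])
    if shrinkage == 0.0:
        w = np.linalg.eigvalsh(out)
        if w.min() <= 0:
            raise NotPositiveDefiniteError(
                f"matrix has minimum eigenvalue {w.min():.3e} and shrinkage is 0"
            )
    return out


def spd_shrinkage_for(
    profiles, floor: float = 1e-3, minimum: float = 1e-3
) -> float:
    """Smallest shrinkage putting every profile's minimum eigenvalue above ``floor``.

    Linear shrinkage maps the minimum eigenvalue L to (1 - g) L + g, so the
    required g is (floor - L) / (1 - L) for the worst profile in the set.
    """
    lmin = min(
        float(np.linalg.eigvalsh(p.matrix if isinstance(p, FCProfile) else p).min())
        for p in profiles
    )
    if lmin >= 1.0:
        return minimum
    needed = (floor - lmin) / (1.0 - lmin)
    return float(min(1.0, max(minimum, needed)))


# ---------------------------------------------------------------------------
# plain-text IO


def read_timeseries(
    path, subject_id: str | None = None, sampling_interval: float = 1.0
) -> RoiTimeSeries:
    """Read a delimited text file (rows = time points, columns = ROIs).

    Delimiter is sniffed between comma, tab and whitespace; an optional
    non-numeric header row is skipped.
    """
    df = _read_delimited(path)
    sid = subject_id if subject_id is not None else _stem(path)
    return RoiTimeSeries(
        subject_id=sid, data=df.to_numpy(float), sampling_interval=sampling_interval
    )


def read_profile(path, subject_id: str | None = None) -> FCProfile:
    """Read an r x r FC matrix written by :func:`write_profile`.

    Parsed with numpy's exact float conversion so 17-significant-digit files
    round-trip bit-for-bit.
    """
    try:
        m = np.loadtxt(path)
    except ValueError:
        m = np.loadtxt(path, delimiter=",")
    sid = subject_id if subject_id is not None else _stem(path)
    return FCProfile(subject_id=sid, matrix=np.atleast_2d(m))


def write_profile(fc: FCProfile, path) -> None:
    """Write the full r x r matrix as TSV with 17 significant digits."""
    np.savetxt(path, fc.matrix, delimiter="\t", fmt="%.17g")


def _read_delimited(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    # drop a header row of ROI names if present
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        df = df.iloc[1:].reset_index(drop=True)
    return df.astype(float)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
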