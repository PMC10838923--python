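"""Whole-connectome fingerprint identification between two aligned sets.

Each profile in the target set is matched to the database profile whose
vectorized connectome correlates with it most strongly (Pearson); a hit is a
match landing on the same dyad index.  The permutation test shuffles database
identities and recomputes the rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fc_core import EdgeIndex, FCProfile, vectorize_upper

__all__ = [
    "SimilarityMatrix",
    "IdentificationResult",
    "similarity_matrix",
    "identify",
    "fingerprint_permutation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pearson similarity of each target (row) with each database profile (column)."""

    values: np.ndarray
    row_role: str = "target"
    col_role: str = "database"
    metric: str = "pearson"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square (aligned sets)")
        if not np.all(np.isfinite(v)):
            raise ValueError("similarity matrix contains non-finite values")
        if v.min() < -1 - 1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("Pearson similarities must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class IdentificationResult:
    """Per-row best matches; a hit is a best match on the diagonal."""

    matches: np.ndarray
    hits: np.ndarray
    rate: float


def _edge_matrix(profiles: list[FCProfile]) -> np.ndarray:
    idx = EdgeIndex(profiles[0].r)
    return np.vstack([vectorize_upper(p, idx) for p in profiles])


def similarity_matrix(
    targets: list[FCProfile], database: list[FCProfile]
) -> SimilarityMatrix:
    """Pearson-correlate every target edge vector with every database edge vector."""
    if len(targets) != len(database):
        raise ValueError("target and database sets must have equal size")
    if targets[0].r != database[0].r:
        raise ValueError("target and database profiles must share ROI count")
    t = _edge_matrix(targets)
    d = _edge_matrix(database)
    tc = t - t.mean(axis=1, keepdims=True)
    dc = d - d.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(tc, axis=1)
    dn = np.linalg.norm(dc, axis=1)
    if (tn == 0).any() or (dn == 0).any():
        raise ValueError("a profile has constant edge vector; similarity undefined")
    sim = np.clip((tc @ dc.T) / np.outer(tn, dn), -1.0, 1.0)
    return SimilarityMatrix(values=sim)


def identify(sim: SimilarityMatrix) -> IdentificationResult:
    """Match each row to its argmax column; ties break to the lowest index."""
    v = sim.values
    matches = v.argmax(axis=1)
    for i, j in enumerate(matches):
        if np.sum(v[i] == v[i, j]) > 1:
            logger.warning("row %d has tied best matches; lowest index kept", i)
    hits = matches == np.arange(sim.n)
    return IdentificationResult(matches=matches, hits=hits, rate=float(hits.mean()))


def fingerprint_permutation(
    targets: list[FCProfile],
    database: list[FCProfile],
    n_perm: int = 5000,
    seed: int = 0,
    conservative_p: bool = False,
):
    """Permutation null for the identification rate.

    Database column identities are uniformly shuffled ``n_perm`` times; the
    p-value is the fraction of shuffles whose rate reaches the observed one.
    """
    from .cbi import PermutationReport  # shared report container

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sim = similarity_matrix(targets, database)
    observed = identify(sim).rate
    n = sim.n
    rng = np.random.default_rng(seed)
    argrows = sim.values.argmax(axis=1)  # argmax is permutation-covariant
    rates = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        # shuffling columns by perm relabels column j as position perm^-1[j];
        # equivalently a hit occurs when perm[i] is row i's argmax column
        rates[k] = float(np.mean(argrows == perm))
    return PermutationReport.from_rates(
        observed_rate=observed,
        per_perm_rates=rates,
        seed=seed,
        conservative_p=conservative_p,
    )
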