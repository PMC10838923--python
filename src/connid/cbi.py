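"""Connectome-based identification (CBI): cross-group edgewise feature
selection, positive/negative sub-models, and the two permutation tests.

The model correlates, edge by edge, the parents' FC values against their
children's values across the n dyads (Spearman).  Edges passing the
significance threshold split into a positively and a negatively correlated
feature set; each subject is then represented by its own FC values at those
edges, and couples are matched by extremal Euclidean distance or rank
correlation between parent and child feature vectors:

* positive sub-model -- biological couples are expected at the *minimum*
  Euclidean distance / *maximum* Spearman coefficient;
* negative sub-model -- at the *maximum* distance / *minimum* coefficient.

Test 1 shuffles couple assignments with feature masks held fixed; test 2
re-derives masks from each shuffled pairing and re-scores the original sets.
No multiple-comparison correction is applied to the edgewise screen: the
permutation machinery is the statistical control, so an inflated false-edge
set surfaces as a non-significant permutation p-value rather than being
filtered upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .fingerprint import IdentificationResult
from .synthetic import Cohort

__all__ = [
    "FeatureSelection",
    "FeatureVectors",
    "DistanceMatrix",
    "PermutationReport",
    "EmptyMaskError",
    "edgewise_spearman",
    "build_feature_vectors",
    "cbi_distance",
    "cbi_identify",
    "permutation_test_labels",
    "permutation_test_features",
]

logger = logging.getLogger(__name__)

SUBMODELS = ("positive", "negative")
METRICS = ("euclidean", "spearman")

# per-row decision rule: which extremum marks the predicted couple
_ARGBEST = {
    ("positive", "euclidean"): np.argmin,
    ("positive", "spearman"): np.argmax,
    ("negative", "euclidean"): np.argmax,
    ("negative", "spearman"): np.argmin,
}


class EmptyMaskError(ValueError):
    """No edge survived selection for the requested sub-model."""


@dataclass(frozen=True)
class FeatureSelection:
    """Edgewise cross-group Spearman screen and the derived feature masks."""

    rho: np.ndarray
    p: np.ndarray
    alpha: float = 0.05
    pos_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    neg_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_constant_edges: int = 0

    def __post_init__(self) -> None:
        if self.pos_mask is None:
            valid = np.isfinite(self.rho) & np.isfinite(self.p)
            object.__setattr__(
                self, "pos_mask", valid & (self.p < self.alpha) & (self.rho > 0)
            )
            object.__setattr__(
                self, "neg_mask", valid & (self.p < self.alpha) & (self.rho < 0)
            )

    def mask(self, submodel: str) -> np.ndarray:
        if submodel == "positive":
            return self.pos_mask
        if submodel == "negative":
            return self.neg_mask
        raise ValueError(f"unknown sub-model {submodel!r}")


@dataclass(frozen=True)
class FeatureVectors:
    """Per-subject FC values at the selected edges, one row per dyad index."""

    Pp: np.ndarray
    Pc: np.ndarray
    Np: np.ndarray
    Nc: np.ndarray
    pos_edges: np.ndarray
    neg_edges: np.ndarray

    def pair(self, submodel: str) -> tuple[np.ndarray, np.ndarray]:
        if submodel == "positive":
            return self.Pp, self.Pc
        if submodel == "negative":
            return self.Np, self.Nc
        raise ValueError(f"unknown sub-model {submodel!r}")


@dataclass(frozen=True)
class DistanceMatrix:
    """Parents (rows) by children (columns); diagonal holds biological dyads."""

    values: np.ndarray
    metric: str
    submodel: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.submodel not in SUBMODELS:
            raise ValueError(f"unknown sub-model {self.submodel!r}")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix contains non-finite values")


@dataclass(frozen=True)
class PermutationReport:
    """Null distribution summary for an identification rate."""

    n_perm: int
    observed_rate: float
    per_perm_rates: np.ndarray
    mean_rate: float
    max_rate: float
    max_recurrence: int
    p_value: float
    seed: int
    n_empty_masks: int = 0

    @classmethod
    def from_rates(
        cls,
        observed_rate: float,
        per_perm_rates: np.ndarray,
        seed: int,
        conservative_p: bool = False,
        n_empty_masks: int = 0,
    ) -> "PermutationReport":
        rates = np.asarray(per_perm_rates, dtype=float)
        n_perm = rates.size
        n_ge = int(np.sum(rates >= observed_rate - 1e-12))
        p = (n_ge + 1) / (n_perm + 1) if conservative_p else n_ge / n_perm
        mx = float(rates.max())
        return cls(
            n_perm=n_perm,
            observed_rate=float(observed_rate),
            per_perm_rates=rates,
            mean_rate=float(rates.mean()),
            max_rate=mx,
            max_recurrence=int(np.sum(rates >= mx - 1e-12)),
            p_value=float(p),
            seed=seed,
            n_empty_masks=n_empty_masks,
        )

    def to_dict(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "observed_rate": self.observed_rate,
            "mean_rate": self.mean_rate,
            "max_rate": self.max_rate,
            "max_recurrence": self.max_recurrence,
            "p_value": self.p_value,
            "seed": self.seed,
            "n_empty_masks": self.n_empty_masks,
        }


# ---------------------------------------------------------------------------
# feature selection


def _edge_value_matrices(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    from .fingerprint import _edge_matrix

    return _edge_matrix(cohort.parents), _edge_matrix(cohort.children)


def _rank_columns(x: np.ndarray) -> np.ndarray:
    """Average ranks down each column (ties get mean rank)."""
    return stats.rankdata(x, axis=0, method="average")


def _spearman_from_ranks(rp: np.ndarray, rc: np.ndarray) -> np.ndarray:
    """Columnwise Pearson of two pre-ranked matrices; NaN where a column is constant."""
    rp = rp - rp.mean(axis=0)
    rc = rc - rc.mean(axis=0)
    sp = np.sqrt((rp**2).sum(axis=0))
    sc = np.sqrt((rc**2).sum(axis=0))
    denom = sp * sc
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rp * rc).sum(axis=0) / denom
    rho[denom == 0] = np.nan
    return np.clip(rho, -1.0, 1.0)


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t approximation with n - 2 degrees of freedom."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(rho)] = np.nan
    p[np.abs(rho) >= 1.0] = 0.0  # |rho| = 1 => t -> inf
    return p


def edgewise_spearman(cohort: Cohort, alpha: float = 0.05) -> FeatureSelection:
    """Spearman-correlate parent vs child FC values at every edge across dyads.

    Edges constant across dyads in either set have undefined rank correlation
    and are excluded from both masks (counted in ``n_constant_edges``).
    """
    n = cohort.n_dyads
    if n < 4:
        raise ValueError("edgewise selection needs at least 4 dyads")
    P, C = _edge_value_matrices(cohort)
    rho = _spearman_from_ranks(_rank_columns(P), _rank_columns(C))
    p = _spearman_p(rho, n)
    n_const = int(np.isnan(rho).sum())
    if n_const:
        logger.warning("%d constant edge(s) excluded from feature selection", n_const)
    return FeatureSelection(rho=rho, p=p, alpha=alpha, n_constant_edges=n_const)


def build_feature_vectors(cohort: Cohort, sel: FeatureSelection) -> FeatureVectors:
    """Represent every subject by its own FC values at the selected edges."""
    P, C = _edge_value_matrices(cohort)
    pos = np.flatnonzero(sel.pos_mask)
    neg = np.flatnonzero(sel.neg_mask)
    return FeatureVectors(
        Pp=P[:, pos], Pc=C[:, pos], Np=P[:, neg], Nc=C[:, neg],
        pos_edges=pos, neg_edges=neg,
    )


# ---------------------------------------------------------------------------
# distance matrices and identification


def _spearman_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman correlation of every row of ``a`` with every row of ``b``."""
    ra = stats.rankdata(a, axis=1, method="average")
    rb = stats.rankdata(b, axis=1, method="average")
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ra, axis=1)
    nb = np.linalg.norm(rb, axis=1)
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (ra @ rb.T) / denom
    out[denom == 0] = 0.0  # constant vector: correlation undefined, score 0
    return np.clip(out, -1.0, 1.0)


def cbi_distance(fv: FeatureVectors, submodel: str, metric: str) -> DistanceMatrix:
    """Parents-by-children Euclidean distances or Spearman coefficients."""
    parent, child = fv.pair(submodel)
    if parent.shape[1] != child.shape[1]:
        raise ValueError("parent and child feature widths differ")
    if parent.shape[1] == 0:
        raise EmptyMaskError(f"no features selected for the {submodel} sub-model")
    if metric == "euclidean":
        values = cdist(parent, child, metric="euclidean")
    elif metric == "spearman":
        if parent.shape[1] < 2:
            raise ValueError("Spearman metric needs feature vectors of width >= 2")
        values = _spearman_rows(parent, child)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(values=values, metric=metric, submodel=submodel)


def cbi_identify(D: DistanceMatrix) -> IdentificationResult:
    """Score each parent by whether its row extremum falls on the diagonal."""
    best = _ARGBEST[(D.submodel, D.metric)](D.values, axis=1)
    hits = best == np.arange(D.values.shape[0])
    return IdentificationResult(matches=best, hits=hits, rate=float(hits.mean()))


# ---------------------------------------------------------------------------
# permutation tests


def permutation_test_labels(
    cohort: Cohort,
    sel: FeatureSelection,
    n_perm: int = 5000,
    seed: int = 0,
    conservative_p: bool = False,
) -> dict[tuple[str, str], PermutationReport]:
    """Test 1: shuffle couple assignments, feature masks held fixed.

    Shuffling the child-set order alone induces the same distribution over
    diagonal pairings as independently shuffling both sets, so the simpler
    scheme is used.  Returns one report per (sub-model, metric).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fv = build_feature_vectors(cohort, sel)
    n = cohort.n_dyads
    reports: dict[tuple[str, str], PermutationReport] = {}
    for submodel in SUBMODELS:
        for metric in METRICS:
            try:
                D = cbi_distance(fv, submodel, metric)
            except (EmptyMaskError, ValueError) as exc:
                logger.warning("skipping %s/%s: %s", submodel, metric, exc)
                continue
            observed = cbi_identify(D).rate
            argbest = _ARGBEST[(submodel, metric)](D.values, axis=1)
            rng = np.random.default_rng([seed, _stream(submodel, metric)])
            rates = np.empty(n_perm)
            for k in range(n_perm):
                perm = rng.permutation(n)
                # child j sits at position perm^-1[j]; parent i scores a hit
                # when its extremal child lands on position i, i.e. when
                # perm[i] equals the unpermuted argbest column
                rates[k] = float(np.mean(argbest == perm))
            reports[(submodel, metric)] = PermutationReport.from_rates(
                observed_rate=observed,
                per_perm_rates=rates,
                seed=seed,
                conservative_p=conservative_p,
            )
    return reports


def permutation_test_features(
    cohort: Cohort,
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    conservative_p: bool = False,
) -> dict[tuple[str, str], PermutationReport]:
    """Test 2: re-derive features from shuffled pairings, score the original sets.

    Each permutation re-pairs dyads, reruns the edgewise Spearman screen on the
    shuffled pairing, represents the *original* parent and child sets by the
    resulting masks, and measures identification.  Permutations yielding an
    empty mask score rate 0 and are counted, so the null is not biased by
    dropping them.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = cohort.n_dyads
    P, C = _edge_value_matrices(cohort)
    rankP, rankC = _rank_columns(P), _rank_columns(C)
    # observed rates from the unshuffled screen
    sel0 = edgewise_spearman(cohort, alpha=alpha)
    fv0 = build_feature_vectors(cohort, sel0)
    observed = {
        (s, m): cbi_identify(cbi_distance(fv0, s, m)).rate
        for s in SUBMODELS
        for m in METRICS
    }

    rng = np.random.default_rng([seed, _stream("features")])
    rates = {key: np.empty(n_perm) for key in observed}
    empty_counts = {s: 0 for s in SUBMODELS}
    for k in range(n_perm):
        perm = rng.permutation(n)
        rho = _spearman_from_ranks(rankP, rankC[perm])
        p = _spearman_p(rho, n)
        valid = np.isfinite(rho) & np.isfinite(p)
        masks = {
            "positive": valid & (p < alpha) & (rho > 0),
            "negative": valid & (p < alpha) & (rho < 0),
        }
        for submodel in SUBMODELS:
            cols = np.flatnonzero(masks[submodel])
            if cols.size == 0:
                empty_counts[submodel] += 1
                for metric in METRICS:
                    rates[(submodel, metric)][k] = 0.0
                continue
            pp, cc = P[:, cols], C[:, cols]
            for metric in METRICS:
                if metric == "euclidean":
                    D = cdist(pp, cc, metric="euclidean")
                elif cols.size < 2:
                    rates[(submodel, metric)][k] = 0.0
                    continue
                else:
                    D = _spearman_rows(pp, cc)
                best = _ARGBEST[(submodel, metric)](D, axis=1)
                rates[(submodel, metric)][k] = float(np.mean(best == np.arange(n)))
    return {
        key: PermutationReport.from_rates(
            observed_rate=observed[key],
            per_perm_rates=rates[key],
            seed=seed,
            conservative_p=conservative_p,
            n_empty_masks=empty_counts[key[0]],
        )
        for key in observed
    }


def _stream(*parts: str) -> int:
    """Stable small integer sub-stream id from string tags."""
    import zlib

    return zlib.crc32("/".join(parts).encode()) % (2**31)
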