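"""Diffusion-map embeddings of connectivity profiles and dyad-separation stats.

Profiles (whole-brain SPD matrices or feature vectors) become nodes of a
graph whose affinities are the Gaussian kernel exp(-d(x, y)^2 / eps) of a
chosen metric:

* Euclidean, for feature vectors;
* affine-invariant Riemannian, d(A, B) = ||log(A^{-1/2} B A^{-1/2})||_F, for
  symmetric positive-definite whole-brain profiles (log-Euclidean is offered
  as a cheaper option).

Row-normalizing the kernel gives a Markov transition matrix P whose spectrum
is computed through the symmetric conjugate D^{1/2} P D^{-1/2}; the constant
trivial eigenpair (eigenvalue exactly 1) is discarded and each profile is
mapped to (lambda_1 phi_1(i), ..., lambda_l phi_l(i)) using the right
eigenvectors of P, the standard l-dimensional diffusion coordinates (l = 2
by default).

The embedded distances within biological dyads are then compared with all
cross-dyad parent-child distances by a two-sided Mann-Whitney U test (normal
approximation with tie correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform

__all__ = [
    "ProfileSet",
    "DiffusionEmbedding",
    "DyadDistanceStats",
    "riemannian_distance",
    "log_euclidean_distance",
    "pairwise_distance",
    "select_epsilon",
    "gaussian_kernel",
    "markov_normalize",
    "embed",
    "diffusion_map",
    "dyad_distance_stats",
]


@dataclass(frozen=True)
class ProfileSet:
    """Homogeneous collection of profiles with subject roles and dyad ids.

    ``kind`` is ``whole-brain-spd`` (items are r x r SPD matrices) or
    ``feature-vector`` (items are equal-length 1-D vectors).
    """

    items: list[np.ndarray]
    kind: str
    ids: list[str]
    roles: list[str]
    dyad_ids: list[str]

    def __post_init__(self) -> None:
        if self.kind not in ("whole-brain-spd", "feature-vector"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        n = len(self.items)
        if n < 3:
            raise ValueError("need at least 3 profiles")
        if not (len(self.ids) == len(self.roles) == len(self.dyad_ids) == n):
            raise ValueError("ids, roles and dyad_ids must align with items")
        shapes = {np.asarray(x).shape for x in self.items}
        if len(shapes) != 1:
            raise ValueError(f"profiles must share one shape, got {shapes}")

    @property
    def n(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class DiffusionEmbedding:
    """Embedding coordinates plus the spectral/kernel metadata that produced them."""

    epsilon: float
    distances: np.ndarray
    kernel: np.ndarray
    eigenvalues: np.ndarray  # descending, trivial pair excluded
    coordinates: np.ndarray  # N x l, coordinate k = lambda_k * phi_k
    metric: str
    ids: list[str] = field(default_factory=list)
    roles: list[str] = field(default_factory=list)
    dyad_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class DyadDistanceStats:
    """Biological vs unrelated embedded parent-child distances."""

    mean_bio: float
    se_bio: float
    mean_unrel: float
    se_unrel: float
    u_statistic: float
    p_value: float
    n_bio: int
    n_unrel: int

    def to_dict(self) -> dict:
        return {
            "mean_bio": self.mean_bio,
            "se_bio": self.se_bio,
            "mean_unrel": self.mean_unrel,
            "se_unrel": self.se_unrel,
            "u_statistic": self.u_statistic,
            "p_value": self.p_value,
            "n_bio": self.n_bio,
            "n_unrel": self.n_unrel,
        }


# ---------------------------------------------------------------------------
# metrics


def _check_spd(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("SPD input must be square")
    if np.abs(a - a.T).max() > 1e-10:
        raise ValueError("SPD input must be symmetric")
    return a


def riemannian_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Affine-invariant distance ||log(A^{-1/2} B A^{-1/2})||_F between SPD matrices."""
    a, b = _check_spd(a), _check_spd(b)
    wa, qa = np.linalg.eigh(a)
    if wa.min() <= 0:
        raise ValueError(f"matrix not positive definite (min eigenvalue {wa.min():.3e})")
    inv_sqrt = (qa / np.sqrt(wa)) @ qa.T
    mid = inv_sqrt @ b @ inv_sqrt
    w = np.linalg.eigvalsh((mid + mid.T) / 2.0)
    if w.min() <= 0:
        raise ValueError(f"matrix not positive definite (min eigenvalue {w.min():.3e})")
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def log_euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """||logm(A) - logm(B)||_F; a cheaper SPD metric without full affine invariance."""
    def logm_spd(x: np.ndarray) -> np.ndarray:
        w, q = np.linalg.eigh(_check_spd(x))
        if w.min() <= 0:
            raise ValueError("matrix not positive definite")
        return (q * np.log(w)) @ q.T

    return float(np.linalg.norm(logm_spd(a) - logm_spd(b), ord="fro"))


_SPD_METRICS = {"riemannian": riemannian_distance, "log-euclidean": log_euclidean_distance}


def pairwise_distance(ps: ProfileSet, metric: str = "euclidean") -> np.ndarray:
    """Symmetric zero-diagonal N x N distance matrix under the chosen metric."""
    if ps.kind == "feature-vector":
        if metric != "euclidean":
            raise ValueError("feature-vector profiles support only the euclidean metric")
        x = np.vstack([np.ravel(v) for v in ps.items])
        from scipy.spatial.distance import pdist

        return squareform(pdist(x, metric="euclidean"))
    if metric == "euclidean":
        x = np.vstack([np.ravel(m) for m in ps.items])
        from scipy.spatial.distance import pdist

        return squareform(pdist(x, metric="euclidean"))
    try:
        dist = _SPD_METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None
    n = ps.n
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dist(ps.items[i], ps.items[j])
    return d


# ---------------------------------------------------------------------------
# kernel and spectrum


def select_epsilon(distances: np.ndarray, scale: float = 1.0) -> float:
    """Median of squared off-diagonal distances, times ``scale``.

    A kernel bandwidth of this order keeps the affinity graph well connected
    (every kernel entry is at least exp(-max d^2 / eps) > 0).
    """
    d = np.asarray(distances, dtype=float)
    off = d[~np.eye(d.shape[0], dtype=bool)]
    eps = float(np.median(off**2)) * scale
    if eps <= 0:
        raise ValueError("all off-diagonal distances are zero; epsilon undefined")
    return eps


def gaussian_kernel(distances: np.ndarray, epsilon: float) -> np.ndarray:
    """K(i, j) = exp(-d(i, j)^2 / epsilon); symmetric with unit diagonal."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    d = np.asarray(distances, dtype=float)
    return np.exp(-(d**2) / epsilon)


def markov_normalize(kernel: np.ndarray) -> np.ndarray:
    """Row-normalize a kernel into a Markov transition matrix."""
    k = np.asarray(kernel, dtype=float)
    deg = k.sum(axis=1)
    if (deg <= 0).any():
        raise ValueError("kernel has a non-positive row sum")
    return k / deg[:, None]


def embed(P: np.ndarray, l: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Spectral diffusion coordinates of a row-stochastic matrix.

    Returns ``(eigenvalues, coordinates)`` where eigenvalues are the l
    largest non-trivial eigenvalues (descending) and column k of coordinates
    is lambda_k * phi_k with phi_k the matching right eigenvector of P.

    The decomposition runs on the symmetric conjugate
    S = D^{1/2} P D^{-1/2} (D = diag of the kernel degrees implicit in P),
    whose eigenvectors v map back to right eigenvectors phi = D^{-1/2} v.
    Signs are fixed so each eigenvector's first maximal-magnitude component
    is positive.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if l > n - 1:
        raise ValueError(f"l = {l} exceeds the {n - 1} non-trivial dimensions")
    rows = P.sum(axis=1)
    if np.abs(rows - 1.0).max() > 1e-10:
        raise ValueError("P must be row-stochastic")
    # recover the stationary weights: pi P = pi with pi_i ~ degree d_i; for a
    # kernel-normalized P the conjugacy weight is any positive vector w with
    # P = W^{-1} K, K symmetric.  Row sums of K are proportional to w, and
    # w_i can be recovered from symmetry: K_ij = w_i P_ij = w_j P_ji.
    w = _conjugacy_weights(P)
    sqrt_w = np.sqrt(w)
    S = (sqrt_w[:, None] * P) / sqrt_w[None, :]
    vals, vecs = np.linalg.eigh((S + S.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # drop the trivial pair (eigenvalue 1, constant right eigenvector)
    lam = vals[1 : l + 1]
    phi = vecs[:, 1 : l + 1] / sqrt_w[:, None]
    # unit-norm right eigenvectors: removes the arbitrary scale the conjugacy
    # weights carry, making coordinates equivariant to input reordering
    phi /= np.linalg.norm(phi, axis=0, keepdims=True)
    for k in range(phi.shape[1]):
        col = phi[:, k]
        lead = np.flatnonzero(np.abs(col) >= np.abs(col).max() - 1e-15)[0]
        if col[lead] < 0:
            phi[:, k] = -col
    return lam, phi * lam[None, :]


def _conjugacy_weights(P: np.ndarray) -> np.ndarray:
    """Positive weights w with diag(w) P symmetric (exists for kernel Markov chains)."""
    n = P.shape[0]
    w = np.ones(n)
    # w_j / w_i = P_ij / P_ji; anchor w_0 = 1 and propagate
    for j in range(1, n):
        if P[j, 0] <= 0:
            raise ValueError("transition matrix must be strictly positive")
        w[j] = w[0] * P[0, j] / P[j, 0]
    return w


def diffusion_map(
    ps: ProfileSet,
    metric: str = "euclidean",
    epsilon: float | None = None,
    epsilon_scale: float = 1.0,
    l: int = 2,
) -> DiffusionEmbedding:
    """Full pipeline: distances -> kernel -> Markov matrix -> coordinates."""
    d = pairwise_distance(ps, metric=metric)
    eps = select_epsilon(d, scale=epsilon_scale) if epsilon is None else float(epsilon)
    K = gaussian_kernel(d, eps)
    P = markov_normalize(K)
    lam, coords = embed(P, l=l)
    return DiffusionEmbedding(
        epsilon=eps,
        distances=d,
        kernel=K,
        eigenvalues=lam,
        coordinates=coords,
        metric=metric,
        ids=list(ps.ids),
        roles=list(ps.roles),
        dyad_ids=list(ps.dyad_ids),
    )


# ---------------------------------------------------------------------------
# dyad separation


def dyad_distance_stats(emb: DiffusionEmbedding, dyads=None) -> DyadDistanceStats:
    """Compare embedded parent-child distances within vs across dyads.

    The biological sample holds the n same-dyad distances; the unrelated
    sample holds all n^2 - n cross-dyad parent-child distances (both
    orientations, matching the all-possible-unrelated-couples convention;
    the observations are not independent, which the normal-approximation
    Mann-Whitney test ignores by design).
    """
    roles = np.asarray(emb.roles)
    dyad_ids = np.asarray(emb.dyad_ids if dyads is None else dyads)
    coords = emb.coordinates
    p_idx = np.flatnonzero(roles == "parent")
    c_idx = np.flatnonzero(roles == "child")
    if p_idx.size != c_idx.size or p_idx.size < 2:
        raise ValueError("need equal parent and child counts, at least 2 dyads")
    # align children to parent dyad order
    c_by_dyad = {dyad_ids[j]: j for j in c_idx}
    c_idx = np.array([c_by_dyad[dyad_ids[i]] for i in p_idx])
    n = p_idx.size
    diff = coords[p_idx][:, None, :] - coords[c_idx][None, :, :]
    dmat = np.linalg.norm(diff, axis=2)  # parent i vs child j
    bio = np.diag(dmat)
    unrel = dmat[~np.eye(n, dtype=bool)]
    u, p = stats.mannwhitneyu(
        bio, unrel, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return DyadDistanceStats(
        mean_bio=float(bio.mean()),
        se_bio=float(bio.std(ddof=1) / np.sqrt(bio.size)),
        mean_unrel=float(unrel.mean()),
        se_unrel=float(unrel.std(ddof=1) / np.sqrt(unrel.size)),
        u_statistic=float(u),
        p_value=float(p),
        n_bio=int(bio.size),
        n_unrel=int(unrel.size),
    )
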