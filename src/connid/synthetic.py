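"""Synthetic parent-child FC cohorts with planted cross-dyad edge coupling.

The generator emulates the statistical skeleton of a story-listening dyad
study: two index-aligned sets of FC profiles (parents and children) in which
a chosen subset of edges carries a latent signal shared within each dyad --
with the same sign for both members ("positive" edges), opposite sign
("negative" edges), or not at all (pure noise).  A further dyad-shared
component spread over every edge models a whole-connectome family fingerprint
and is off by default.

Edge values are built on an unbounded latent scale and squashed through tanh,
so profiles always satisfy the FC invariants without clipping artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fc_core import (
    EdgeIndex,
    FCProfile,
    RoiTimeSeries,
    compute_fc_profile,
    devectorize_upper,
    read_profile,
    write_profile,
)

__all__ = ["SyntheticConfig", "Cohort", "generate_cohort", "write_cohort", "read_cohort"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-generation parameters.

    Defaults mirror the study conditions the package targets: 13 dyads,
    264 ROIs, 150 time points, with 5% of edges planted positively coupled
    and a disjoint 5% negatively coupled.

    Parameters
    ----------
    coupling : float
        Strength of the dyad-shared latent signal on planted edges, on the
        pre-tanh latent scale (noise has unit-comparable scale ``noise_sd``).
    noise_sd : float
        Standard deviation of independent per-subject edge noise.
    individual_strength : float
        Strength of a dyad-shared component present on *every* edge of both
        members; this is what a whole-connectome fingerprint can pick up.
    mode : {"fc-direct", "timeseries"}
        ``fc-direct`` synthesizes edge values directly; ``timeseries`` builds
        a per-subject covariance from the same construction, samples a T x r
        series from it, and re-estimates the profile with the Pearson pipeline.
    """

    n_dyads: int = 13
    r: int = 264
    T: int = 150
    planted_pos_edges: tuple[int, ...] | None = None
    planted_neg_edges: tuple[int, ...] | None = None
    planted_fraction: float = 0.05
    coupling: float = 1.0
    noise_sd: float = 0.3
    individual_strength: float = 0.0
    mode: str = "fc-direct"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 2:
            raise ValueError("need at least 2 dyads")
        if self.mode not in ("fc-direct", "timeseries"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.coupling < 0 or self.individual_strength < 0:
            raise ValueError("coupling and individual_strength must be >= 0")


@dataclass(frozen=True)
class Cohort:
    """Index-aligned parent and child FC profiles.

    ``parents[i]`` and ``children[i]`` form the biological dyad
    ``dyad_ids[i]``; every parents-by-children matrix downstream therefore
    carries the true couples on its diagonal.
    """

    dyad_ids: list[str]
    parents: list[FCProfile]
    children: list[FCProfile]
    network_labels: list[str] | None = None
    planted_pos_edges: tuple[int, ...] = field(default=())
    planted_neg_edges: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.dyad_ids)
        if not (len(self.parents) == len(self.children) == n):
            raise ValueError("parents, children and dyad_ids must be index-aligned")
        rs = {p.r for p in self.parents} | {c.r for c in self.children}
        if len(rs) != 1:
            raise ValueError(f"all profiles must share one ROI count, got {rs}")
        if self.network_labels is not None and len(self.network_labels) != self.r:
            raise ValueError("network_labels length must equal ROI count")

    @property
    def n_dyads(self) -> int:
        return len(self.dyad_ids)

    @property
    def r(self) -> int:
        return self.parents[0].r

    def edge_index(self) -> EdgeIndex:
        return EdgeIndex(self.r)


def _resolve_planted(cfg: SyntheticConfig, idx: EdgeIndex, rng: np.random.Generator):
    if cfg.planted_pos_edges is not None or cfg.planted_neg_edges is not None:
        pos = np.asarray(cfg.planted_pos_edges or (), dtype=int)
        neg = np.asarray(cfg.planted_neg_edges or (), dtype=int)
    else:
        m = idx.n_edges
        k = max(1, int(round(cfg.planted_fraction * m)))
        chosen = rng.choice(m, size=min(2 * k, m), replace=False)
        pos, neg = np.sort(chosen[:k]), np.sort(chosen[k : 2 * k])
    if np.intersect1d(pos, neg).size:
        raise ValueError("planted positive and negative edge sets overlap")
    for arr, name in ((pos, "positive"), (neg, "negative")):
        if arr.size and (arr.min() < 0 or arr.max() >= idx.n_edges):
            raise ValueError(f"planted {name} edge outside [0, {idx.n_edges})")
    return pos, neg


def generate_cohort(cfg: SyntheticConfig) -> Cohort:
    """Draw a dyad-coupled cohort; identical seeds give bit-identical cohorts."""
    rng = np.random.default_rng(cfg.seed)
    idx = EdgeIndex(cfg.r)
    m = idx.n_edges
    n = cfg.n_dyads

    pos, neg = _resolve_planted(cfg, idx, rng)
    sign = np.zeros(m)
    sign[pos] = 1.0
    sign[neg] = -1.0

    # fixed per-cohort edge baseline, truncated normal on the latent scale
    mu = rng.normal(0.1, 0.2, size=m)
    while True:
        out = (mu <= -0.8) | (mu >= 0.8)
        if not out.any():
            break
        mu[out] = rng.normal(0.1, 0.2, size=out.sum())

    u = rng.standard_normal((n, m))  # dyad-shared planted signal
    v = rng.standard_normal((n, m))  # dyad-shared fingerprint component
    noise_p = rng.normal(scale=cfg.noise_sd, size=(n, m))
    noise_c = rng.normal(scale=cfg.noise_sd, size=(n, m))

    lat_p = mu + cfg.coupling * u + cfg.individual_strength * v + noise_p
    lat_c = mu + sign * cfg.coupling * u + cfg.individual_strength * v + noise_c

    if cfg.mode == "fc-direct":
        parents = [
            FCProfile(f"P{d:02d}", devectorize_upper(np.tanh(lat_p[d]), idx))
            for d in range(n)
        ]
        children = [
            FCProfile(f"C{d:02d}", devectorize_upper(np.tanh(lat_c[d]), idx))
            for d in range(n)
        ]
    else:
        parents = [
            _sample_profile(f"P{d:02d}", np.tanh(lat_p[d]), idx, cfg.T, rng)
            for d in range(n)
        ]
        children = [
            _sample_profile(f"C{d:02d}", np.tanh(lat_c[d]), idx, cfg.T, rng)
            for d in range(n)
        ]

    return Cohort(
        dyad_ids=[f"D{d:02d}" for d in range(n)],
        parents=parents,
        children=children,
        planted_pos_edges=tuple(int(e) for e in pos),
        planted_neg_edges=tuple(int(e) for e in neg),
    )


def _sample_profile(
    subject_id: str,
    target_edges: np.ndarray,
    idx: EdgeIndex,
    T: int,
    rng: np.random.Generator,
    eig_floor: float = 1e-3,
) -> FCProfile:
    """Sample a T x r series whose population correlation is the target profile.

    The target correlation matrix need not be positive semi-definite once
    structure is planted, so eigenvalues are floored before factorization.
    """
    sigma = devectorize_upper(target_edges, idx)
    w, q = np.linalg.eigh(sigma)
    w = np.maximum(w, eig_floor)
    a = q * np.sqrt(w)  # sigma_spd = a @ a.T
    series = rng.standard_normal((T, idx.r)) @ a.T
    return compute_fc_profile(RoiTimeSeries(subject_id, series))


# ---------------------------------------------------------------------------
# manifest round trip

MANIFEST_COLUMNS = ["subject_id", "role", "dyad_id", "path"]


def write_cohort(cohort: Cohort, directory) -> Path:
    """Write per-subject profile files plus a ``manifest.csv``; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for role, profiles in (("parent", cohort.parents), ("child", cohort.children)):
        for dyad_id, fc in zip(cohort.dyad_ids, profiles):
            rel = f"{fc.subject_id}.tsv"
            write_profile(fc, directory / rel)
            rows.append((fc.subject_id, role, dyad_id, rel))
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    if cohort.network_labels is not None:
        pd.DataFrame(
            {"roi_index": range(cohort.r), "network": cohort.network_labels}
        ).to_csv(directory / "labels.csv", index=False)
    return manifest


def read_cohort(manifest_path, network_labels: list[str] | None = None) -> Cohort:
    """Load a cohort from a manifest written by :func:`write_cohort`.

    Files may hold either ready-made FC matrices or raw ROI time series;
    a square matrix with unit diagonal is taken as a profile, anything else
    is run through the Pearson pipeline.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    base = manifest_path.parent
    by_role: dict[str, dict[str, FCProfile]] = {"parent": {}, "child": {}}
    for row in df.itertuples(index=False):
        if row.role not in by_role:
            raise ValueError(f"unknown role {row.role!r} (expected parent/child)")
        by_role[row.role][str(row.dyad_id)] = _load_subject(
            base / row.path, str(row.subject_id)
        )
    dyads = [str(d) for d in df[df.role == "parent"].dyad_id]
    if sorted(dyads) != sorted(by_role["child"]):
        raise ValueError("parent and child dyad ids do not match")
    return Cohort(
        dyad_ids=dyads,
        parents=[by_role["parent"][d] for d in dyads],
        children=[by_role["child"][d] for d in dyads],
        network_labels=network_labels,
    )


def _load_subject(path: Path, subject_id: str) -> FCProfile:
    from .fc_core import _read_delimited

    arr = _read_delimited(path).to_numpy(float)
    if arr.shape[0] == arr.shape[1] and np.allclose(np.diag(arr), 1.0, atol=1e-9):
        return read_profile(path, subject_id=subject_id)
    return compute_fc_profile(RoiTimeSeries(subject_id, arr))
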