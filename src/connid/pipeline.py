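"""End-to-end orchestration: fingerprint -> CBI -> network nodes -> diffusion maps.

`run_pipeline` ties the stages together on a cohort loaded from a manifest
(or built in memory), writes every per-stage artifact as plain text under the
output directory, and returns one stage-keyed summary dictionary that is also
written as ``summary.json``.  Every default the underlying method leaves open
(p-value method, kernel bandwidth, tie-breaking) is logged so runs are
auditable; a fixed seed makes the whole bundle deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cbi as cbi_mod
from .cbi import SUBMODELS, METRICS
from .diffusion import ProfileSet, diffusion_map, dyad_distance_stats
from .fc_core import EdgeIndex, ensure_spd, spd_shrinkage_for
from .fingerprint import fingerprint_permutation, identify, similarity_matrix
from .networks import NetworkLabels, node_contribution
from .synthetic import Cohort

logger = logging.getLogger(__name__)

ALL_STAGES = ("fingerprint", "cbi", "networks", "dmap")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters; defaults follow the method's standard settings."""

    alpha: float = 0.05
    n_perm: int = 5000
    seed: int = 0
    epsilon_scale: float = 1.0
    shrinkage: float = 1e-3
    stages: tuple[str, ...] = ALL_STAGES
    conservative_p: bool = False
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}")


def run_pipeline(cohort: Cohort, cfg: RunConfig) -> dict:
    """Run the requested stages and return (and optionally write) the summary."""
    out = Path(cfg.out_dir) if cfg.out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "n_dyads": cohort.n_dyads,
        "r": cohort.r,
        "config": {
            "alpha": cfg.alpha,
            "n_perm": cfg.n_perm,
            "seed": cfg.seed,
            "epsilon_scale": cfg.epsilon_scale,
            "shrinkage": cfg.shrinkage,
            "stages": list(cfg.stages),
        },
    }
    logger.info(
        "pipeline defaults: Spearman p via t-approx (df=n-2), argmax ties -> "
        "lowest index, epsilon = %.3g * median squared distance, shrinkage %.3g",
        cfg.epsilon_scale,
        cfg.shrinkage,
    )

    sel = fv = None
    if {"cbi", "networks", "dmap"} & set(cfg.stages):
        sel = cbi_mod.edgewise_spearman(cohort, alpha=cfg.alpha)
        fv = cbi_mod.build_feature_vectors(cohort, sel)

    if "fingerprint" in cfg.stages:
        summary["fingerprint"] = _stage_fingerprint(cohort, cfg, out)
    if "cbi" in cfg.stages:
        summary["cbi"] = _stage_cbi(cohort, sel, fv, cfg, out)
    if "networks" in cfg.stages:
        summary["networks"] = _stage_networks(cohort, sel, out)
    if "dmap" in cfg.stages:
        summary["dmap"] = _stage_dmap(cohort, fv, cfg, out)

    if out is not None:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _stage_fingerprint(cohort: Cohort, cfg: RunConfig, out: Path | None) -> dict:
    res: dict = {}
    for direction, (targets, database) in {
        "parent-to-child": (cohort.parents, cohort.children),
        "child-to-parent": (cohort.children, cohort.parents),
    }.items():
        sim = similarity_matrix(targets, database)
        ident = identify(sim)
        report = fingerprint_permutation(
            targets,
            database,
            n_perm=cfg.n_perm,
            seed=cfg.seed,
            conservative_p=cfg.conservative_p,
        )
        res[direction] = {
            "rate": ident.rate,
            "n_hits": int(ident.hits.sum()),
            "permutation": report.to_dict(),
        }
        if out is not None:
            pd.DataFrame(
                sim.values, index=cohort.dyad_ids, columns=cohort.dyad_ids
            ).to_csv(out / f"fingerprint_similarity_{direction}.csv")
    return res


def _stage_cbi(cohort, sel, fv, cfg: RunConfig, out: Path | None) -> dict:
    res: dict = {
        "n_pos_features": int(sel.pos_mask.sum()),
        "n_neg_features": int(sel.neg_mask.sum()),
        "n_constant_edges": sel.n_constant_edges,
        "identification": {},
    }
    for submodel in SUBMODELS:
        for metric in METRICS:
            D = cbi_mod.cbi_distance(fv, submodel, metric)
            ident = cbi_mod.cbi_identify(D)
            res["identification"][f"{submodel}/{metric}"] = {
                "rate": ident.rate,
                "n_hits": int(ident.hits.sum()),
            }
            if out is not None:
                pd.DataFrame(
                    D.values, index=cohort.dyad_ids, columns=cohort.dyad_ids
                ).to_csv(out / f"cbi_distance_{submodel}_{metric}.csv")
    labels_rep = cbi_mod.permutation_test_labels(
        cohort, sel, n_perm=cfg.n_perm, seed=cfg.seed, conservative_p=cfg.conservative_p
    )
    features_rep = cbi_mod.permutation_test_features(
        cohort,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        alpha=cfg.alpha,
        conservative_p=cfg.conservative_p,
    )
    res["permutation_labels"] = {
        f"{s}/{m}": rep.to_dict() for (s, m), rep in labels_rep.items()
    }
    res["permutation_features"] = {
        f"{s}/{m}": rep.to_dict() for (s, m), rep in features_rep.items()
    }
    if out is not None:
        _write_masks(cohort, sel, out / "cbi_features.csv")
    return res


def _write_masks(cohort: Cohort, sel, path: Path) -> None:
    idx = EdgeIndex(cohort.r)
    selected = sel.pos_mask | sel.neg_mask
    pos = np.flatnonzero(selected)
    pd.DataFrame(
        {
            "roi_i": idx.rows[pos],
            "roi_j": idx.cols[pos],
            "rho": sel.rho[pos],
            "p": sel.p[pos],
            "sign": np.where(sel.pos_mask[pos], "positive", "negative"),
        }
    ).to_csv(path, index=False)


def _stage_networks(cohort: Cohort, sel, out: Path | None) -> dict:
    if cohort.network_labels is None:
        raise ValueError("network stage requested but the cohort has no ROI labels")
    labels = NetworkLabels(roi_to_network=list(cohort.network_labels))
    res: dict = {}
    for submodel, mask in (("positive", sel.pos_mask), ("negative", sel.neg_mask)):
        contrib = node_contribution(mask, labels, submodel)
        res[submodel] = {
            "total_features": int(np.triu(contrib.counts).sum()),
            "networks": contrib.networks,
        }
        if out is not None:
            for which in ("counts", "fraction_of_total", "per_size"):
                contrib.frame(which).to_csv(out / f"networks_{submodel}_{which}.csv")
    return res


def _stage_dmap(cohort: Cohort, fv, cfg: RunConfig, out: Path | None) -> dict:
    ids = [p.subject_id for p in cohort.parents] + [c.subject_id for c in cohort.children]
    roles = ["parent"] * cohort.n_dyads + ["child"] * cohort.n_dyads
    dyads = list(cohort.dyad_ids) * 2
    all_profiles = [*cohort.parents, *cohort.children]
    # rank-deficient or indefinite estimates need more shrinkage than the
    # configured minimum before the Riemannian metric is defined
    gamma = spd_shrinkage_for(all_profiles, minimum=cfg.shrinkage)
    if gamma > cfg.shrinkage:
        logger.info("raised shrinkage to %.3g to reach positive definiteness", gamma)
    sources: dict[str, tuple[ProfileSet, str]] = {
        "whole-brain": (
            ProfileSet(
                items=[ensure_spd(p, gamma) for p in all_profiles],
                kind="whole-brain-spd",
                ids=ids,
                roles=roles,
                dyad_ids=dyads,
            ),
            "riemannian",
        ),
    }
    for submodel in SUBMODELS:
        parent_mat, child_mat = fv.pair(submodel)
        if parent_mat.shape[1] == 0:
            logger.warning("no %s features; skipping its diffusion map", submodel)
            continue
        sources[f"cbi-{submodel[:3]}"] = (
            ProfileSet(
                items=[*parent_mat, *child_mat],
                kind="feature-vector",
                ids=ids,
                roles=roles,
                dyad_ids=dyads,
            ),
            "euclidean",
        )
    res: dict = {}
    for name, (ps, metric) in sources.items():
        emb = diffusion_map(ps, metric=metric, epsilon_scale=cfg.epsilon_scale)
        stats_ = dyad_distance_stats(emb)
        res[name] = {
            "metric": metric,
            "epsilon": emb.epsilon,
            "eigenvalues": emb.eigenvalues.tolist(),
            "stats": stats_.to_dict(),
        }
        if out is not None:
            pd.DataFrame(
                {
                    "subject_id": emb.ids,
                    "role": emb.roles,
                    "dyad_id": emb.dyad_ids,
                    "c1": emb.coordinates[:, 0],
                    "c2": emb.coordinates[:, 1],
                }
            ).to_csv(out / f"dmap_{name}_coordinates.csv", index=False)
    return res
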