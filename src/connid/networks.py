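"""Attribute selected features to network-to-network nodes.

A "node" is the block of edges joining two named brain networks (diagonal
nodes are within-network blocks).  Each selected edge is counted once toward
its node -- masks live on the deduplicated upper triangle, so no symmetric
double counting can occur -- and counts are reported two ways: as a fraction
of all selected features of the sub-model, and relative to the node's size
(its number of possible edges).

ROI self-correlations are constant 1 and can never be selected, so they are
excluded from node sizes; a diagonal node over a network of n_A ROIs has
n_A(n_A - 1)/2 possible edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fc_core import EdgeIndex

__all__ = [
    "NetworkLabels",
    "NodeContribution",
    "count_features_per_node",
    "normalize_by_total",
    "normalize_by_node_size",
    "node_contribution",
    "read_network_labels",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkLabels:
    """ROI-to-network assignment with a fixed network order."""

    roi_to_network: list[str]
    networks: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.roi_to_network:
            raise ValueError("every ROI must be labeled")
        if self.networks is None:
            seen: dict[str, None] = {}
            for name in self.roi_to_network:
                seen.setdefault(name, None)
            object.__setattr__(self, "networks", list(seen))
        unknown = set(self.roi_to_network) - set(self.networks)
        if unknown:
            raise ValueError(f"ROI labels not in network list: {sorted(unknown)}")

    @property
    def r(self) -> int:
        return len(self.roi_to_network)

    @property
    def K(self) -> int:
        return len(self.networks)

    def roi_network_codes(self) -> np.ndarray:
        code = {name: k for k, name in enumerate(self.networks)}
        return np.array([code[name] for name in self.roi_to_network], dtype=int)

    def sizes(self) -> np.ndarray:
        codes = self.roi_network_codes()
        return np.bincount(codes, minlength=self.K)


@dataclass(frozen=True)
class NodeContribution:
    """The three K x K matrices for one sub-model: counts and both normalizations."""

    counts: np.ndarray
    fraction_of_total: np.ndarray
    per_size: np.ndarray
    submodel: str
    networks: list[str]

    def frame(self, which: str = "counts") -> pd.DataFrame:
        mat = getattr(self, which)
        return pd.DataFrame(mat, index=self.networks, columns=self.networks)


def count_features_per_node(mask: np.ndarray, labels: NetworkLabels) -> np.ndarray:
    """Count selected edges per (network, network) block; symmetric K x K ints."""
    mask = np.asarray(mask, dtype=bool)
    idx = EdgeIndex(labels.r)
    if mask.shape != (idx.n_edges,):
        raise ValueError(
            f"mask length {mask.shape} does not match r(r-1)/2 = {idx.n_edges}"
        )
    codes = labels.roi_network_codes()
    K = labels.K
    counts = np.zeros((K, K), dtype=int)
    a = codes[idx.rows[mask]]
    b = codes[idx.cols[mask]]
    np.add.at(counts, (np.minimum(a, b), np.maximum(a, b)), 1)
    return counts + np.triu(counts, k=1).T  # symmetric report


def normalize_by_total(counts: np.ndarray) -> np.ndarray:
    """Divide each node count by the sub-model's total selected-feature count."""
    counts = np.asarray(counts, dtype=float)
    total = np.triu(counts).sum()
    if total == 0:
        logger.warning("no selected features; fraction_of_total is all zero")
        return np.zeros_like(counts)
    return counts / total


def normalize_by_node_size(counts: np.ndarray, labels: NetworkLabels) -> np.ndarray:
    """Divide each node count by the number of possible edges in that node."""
    counts = np.asarray(counts, dtype=float)
    sizes = labels.sizes()
    denom = np.outer(sizes, sizes).astype(float)
    np.fill_diagonal(denom, sizes * (sizes - 1) / 2.0)
    if (np.diag(denom) == 0).any():
        logger.warning("single-ROI network(s): diagonal per_size defined as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = counts / denom
    out[denom == 0] = 0.0
    return out


def node_contribution(
    mask: np.ndarray, labels: NetworkLabels, submodel: str
) -> NodeContribution:
    """Convenience wrapper returning counts plus both normalizations."""
    counts = count_features_per_node(mask, labels)
    return NodeContribution(
        counts=counts,
        fraction_of_total=normalize_by_total(counts),
        per_size=normalize_by_node_size(counts, labels),
        submodel=submodel,
        networks=list(labels.networks),
    )


def read_network_labels(path) -> NetworkLabels:
    """Read a CSV with header ``roi_index,network`` (0-based ROI indices)."""
    df = pd.read_csv(path)
    missing = {"roi_index", "network"} - set(df.columns)
    if missing:
        raise ValueError(f"labels file missing columns {sorted(missing)}")
    df = df.sort_values("roi_index")
    if not np.array_equal(df.roi_index.to_numpy(), np.arange(len(df))):
        raise ValueError("roi_index must cover 0..r-1 with no gaps")
    return NetworkLabels(roi_to_network=[str(x) for x in df.network])
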