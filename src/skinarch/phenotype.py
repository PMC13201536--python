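"""Cell-type assignment: marker gating, graph clustering, label transfer.

The gating hierarchy mirrors a mass-cytometry panel: epithelial cells are
called first on E-cadherin, then immune (CD45), endothelial (CD31) and
vascular smooth muscle (SM22/aSMA high) among the E-cadherin-negative
cells; fibroblasts are the residual.  Thresholds apply to z-scored
intensities (``+`` means z > 0, ``high`` means z > 1 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .preprocess import NormalizedMatrix

__all__ = [
    "GatingRule",
    "LabelTransferResult",
    "default_gating_rules",
    "gate_cells",
    "cluster_cells",
    "knn_label_transfer",
    "filter_correspondence",
    "FIBROBLAST_CLUSTERING_MARKERS",
    "IMMUNE_CLUSTERING_MARKERS",
]

# marker subsets used for subpopulation clustering
FIBROBLAST_CLUSTERING_MARKERS = [
    "PU.1", "TFAM", "PDGFRa", "GLI2", "aSMA", "PDGFRb", "GLI1", "S1PR",
    "CD90", "Collagen", "ADRP", "ADAM12", "PI16", "P4Hb", "FAP",
]
IMMUNE_CLUSTERING_MARKERS = ["CD20", "CD29", "CD45", "CD4", "LYVE1", "CD8", "CD3", "CD68"]

_DEFAULT_THRESHOLDS = {"+": 0.0, "high": 1.0, "-": 0.0, "low/-": 1.0}


@dataclass(frozen=True)
class GatingRule:
    """One node of the gating tree.

    ``conditions`` is a list of ``(marker, relation, threshold)`` where the
    relation is one of ``+``, ``-``, ``high``, ``low/-`` and the threshold
    (on z-scored intensity) may be None to use the relation's default.
    """

    label: str
    conditions: list[tuple[str, str, float | None]] = field(default_factory=list)
    parent: str | None = None


def default_gating_rules() -> list[GatingRule]:
    """Top-level skin gating hierarchy; fibroblast is the residual leaf."""
    return [
        GatingRule("epithelial", [("E-cadherin", "+", None)]),
        GatingRule("immune", [("CD45", "+", None), ("E-cadherin", "-", None)]),
        GatingRule("endothelial", [("CD31", "+", None), ("E-cadherin", "-", None)]),
        GatingRule(
            "vascular smooth muscle",
            [("SM22", "high", None), ("aSMA", "high", None), ("E-cadherin", "-", None)],
        ),
        GatingRule("fibroblast", []),  # residual: everything not yet labelled
    ]


def _condition_mask(values: np.ndarray, col: int, relation: str, threshold):
    if threshold is None:
        threshold = _DEFAULT_THRESHOLDS[relation]
    x = values[:, col]
    if relation in ("+", "high"):
        return x > threshold
    if relation in ("-", "low/-"):
        return x <= threshold
    raise ValueError(f"unknown relation {relation!r}")


def gate_cells(norm: NormalizedMatrix, rules: list[GatingRule]) -> pd.Series:
    """Assign exactly one label per cell by sequential gating.

    Rules are evaluated in order; the first rule whose conditions all hold
    claims the cell.  A rule with no conditions acts as the residual and
    makes the gating total.
    """
    col = {m: j for j, m in enumerate(norm.features)}
    n = norm.values.shape[0]
    labels = np.array([None] * n, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for rule in rules:
        mask = unassigned.copy()
        for marker, relation, threshold in rule.conditions:
            if marker not in col:
                raise ValueError(f"marker {marker!r} not in panel")
            mask &= _condition_mask(norm.values, col[marker], relation, threshold)
        labels[mask] = rule.label
        unassigned &= ~mask
    if unassigned.any():
        raise ValueError(
            f"{int(unassigned.sum())} cells matched no gating rule; add a "
            "residual rule with no conditions"
        )
    return pd.Series(labels, index=norm.cell_ids, name="label")


def cluster_cells(
    features: np.ndarray,
    k_neighbors: int,
    seed: int,
    resolution: float = 1.0,
) -> np.ndarray:
    """Graph community detection on an exact Euclidean knn graph.

    Builds the undirected union knn graph and partitions it by modularity
    (RB-configuration) optimization.  Deterministic for a given seed.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n <= k_neighbors:
        raise ValueError(f"need more than k_neighbors={k_neighbors} cells, got {n}")
    if np.all(x == x[0]):
        # degenerate: every cell identical; knn ties are arbitrary
        return np.zeros(n, dtype=int)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(x)
    _, idx = nn.kneighbors(x)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    graph = ig.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


@dataclass
class LabelTransferResult:
    labels: pd.Series  # per-query majority label
    vote_fraction: pd.Series  # in [1/k, 1]
    tie: pd.Series  # True where the majority was not unique
    k: int


def knn_label_transfer(
    ref_features: np.ndarray,
    ref_labels,
    query_features: np.ndarray,
    k: int = 10,
    query_ids=None,
) -> LabelTransferResult:
    """Majority vote over the k nearest reference cells (Euclidean).

    Ties are broken towards the lexicographically smallest label and
    flagged.
    """
    ref = np.asarray(ref_features, dtype=float)
    query = np.asarray(query_features, dtype=float)
    ref_labels = np.asarray(ref_labels)
    if k > ref.shape[0]:
        raise ValueError(f"k={k} exceeds reference size {ref.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    _, idx = nn.kneighbors(query)
    labels, fracs, ties = [], [], []
    for row in idx:
        votes = pd.Series(ref_labels[row]).value_counts()
        top = votes.max()
        winners = sorted(votes[votes == top].index)
        labels.append(winners[0])
        fracs.append(top / k)
        ties.append(len(winners) > 1)
    if query_ids is None:
        query_ids = range(len(labels))
    index = pd.Index(query_ids)
    return LabelTransferResult(
        labels=pd.Series(labels, index=index, name="label"),
        vote_fraction=pd.Series(fracs, index=index, name="vote_fraction"),
        tie=pd.Series(ties, index=index, name="tie"),
        k=k,
    )


def filter_correspondence(
    mapping_counts: dict[tuple[str, str], int],
    min_cells: int = 50,
    min_fraction: float = 0.10,
) -> dict[tuple[str, str], int]:
    """Drop spurious label correspondences.

    Keeps pairs with at least ``min_cells`` cells AND representing at least
    ``min_fraction`` of their source label's total.
    """
    totals: dict[str, int] = {}
    for (src, _dst), n in mapping_counts.items():
        if n < 0:
            raise ValueError("correspondence counts must be >= 0")
        totals[src] = totals.get(src, 0) + n
    return {
        pair: n
        for pair, n in mapping_counts.items()
        if n >= min_cells and totals[pair[0]] > 0 and n / totals[pair[0]] >= min_fraction
    }
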