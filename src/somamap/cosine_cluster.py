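"""Postsynaptic connectivity profiles, cosine similarity and Ward clustering.

Focal neurons are compared by the synapse weights of their outputs onto
non-focal partners. Focal-to-focal edges are dropped before thresholding;
edges below the synapse threshold are zeroed; rows left all-zero are
excluded from clustering (and recorded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import AnnotationTable
from .errors import SomamapError
from .morphology import ClusterResult, SimilarityMatrix, cut_clusters, ward_cluster

__all__ = [
    "EDGE_MIN_PRESETS",
    "ConnectivityProfile",
    "CompositionReport",
    "build_profiles",
    "cosine_matrix",
    "cluster_connectivity",
    "composition",
]

logger = logging.getLogger(__name__)

# per-edge synapse thresholds: low for sparse high-count types, main for the
# rest, figure for the plotted variant
EDGE_MIN_PRESETS = {"low": 3, "main": 7, "figure": 6}


@dataclass
class ConnectivityProfile:
    """Focal-neuron × partner weight matrix after thresholding.

    ``weights`` rows are focal neurons with at least one retained edge;
    ``excluded`` lists focal neurons whose rows were all-zero.
    """

    weights: pd.DataFrame  # index: focal ids, columns: partner ids
    excluded: list[str] = field(default_factory=list)
    edge_min: int = 1
    threshold_mode: str = "per_edge"

    @property
    def focal_ids(self) -> list[str]:
        return self.weights.index.tolist()

    @property
    def partner_ids(self) -> list[str]:
        return self.weights.columns.tolist()


@dataclass
class CompositionReport:
    """Cluster composition: per-type cluster fractions and per-cluster makeup."""

    by_type: pd.DataFrame  # columns: type, cluster, count, fraction, minor
    by_cluster: pd.DataFrame  # columns: cluster, type, count, fraction
    min_fraction: float = 0.20


def build_profiles(edges: dict[tuple[str, str], int],
                   ann: AnnotationTable,
                   focal: set[str] | list[str],
                   edge_min: int = 1,
                   threshold_mode: str = "per_edge") -> ConnectivityProfile:
    """Postsynaptic weight profiles of focal-type neurons onto non-focal partners.

    ``focal`` is a set of type labels; a neuron is focal when its annotated
    type is in the set. Focal-to-focal edges are dropped before
    thresholding. ``threshold_mode='per_edge'`` zeroes individual cells
    below ``edge_min``; ``'per_partner'`` instead drops whole partner
    columns whose total is below it.
    """
    focal = set(focal)
    if not focal:
        raise ValueError("focal type set must not be empty")
    if edge_min < 1:
        raise ValueError("edge_min must be >= 1")
    if threshold_mode not in ("per_edge", "per_partner"):
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    focal_ids = sorted(
        i for i in ann.neuron_ids if ann.type_of(i) in focal
    )
    focal_set = set(focal_ids)
    # all BMN-type neurons are excluded as partners, not just the focal subset
    bmn_ids = {i for i in ann.neuron_ids}

    cells: dict[tuple[str, str], int] = {}
    for (pre, post), w in edges.items():
        if pre not in focal_set:
            continue
        if post in bmn_ids:
            continue  # focal/annotated-to-annotated edge: excluded
        cells[(pre, post)] = w

    partners = sorted({post for (_, post) in cells})
    weights = pd.DataFrame(
        0, index=pd.Index(focal_ids, name="neuron_id"),
        columns=pd.Index(partners, name="partner_id"), dtype=int,
    )
    for (pre, post), w in cells.items():
        weights.at[pre, post] = w

    if threshold_mode == "per_edge":
        weights = weights.where(weights >= edge_min, 0)
    else:
        col_ok = weights.sum(axis=0) >= edge_min
        weights = weights.loc[:, col_ok]

    row_sums = weights.sum(axis=1)
    excluded = row_sums.index[row_sums == 0].tolist()
    weights = weights.loc[row_sums > 0]
    weights = weights.loc[:, weights.sum(axis=0) > 0]
    if excluded:
        logger.info("excluded %d all-zero focal rows: %s",
                    len(excluded), excluded[:10])
    return ConnectivityProfile(weights=weights, excluded=excluded,
                               edge_min=edge_min, threshold_mode=threshold_mode)


def cosine_matrix(profile: ConnectivityProfile) -> SimilarityMatrix:
    """Pairwise cosine similarity of profile rows; values in [0, 1]."""
    w = profile.weights.to_numpy(dtype=float)
    if len(w) < 2:
        raise ValueError("need at least two non-excluded rows")
    norms = np.linalg.norm(w, axis=1)
    if np.any(norms == 0):
        raise SomamapError("zero-norm row reached cosine_matrix; "
                           "all-zero rows must be excluded upstream")
    unit = w / norms[:, None]
    values = unit @ unit.T
    values = np.clip(values, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    values = 0.5 * (values + values.T)
    return SimilarityMatrix(ids=profile.focal_ids, values=values)


def cluster_connectivity(sim: SimilarityMatrix,
                         height: float | None = None,
                         k: int | None = None) -> ClusterResult:
    """Ward clustering of the cosine similarity, cut at a height or into k."""
    result = ward_cluster(sim)
    result.labels = cut_clusters(result, height=height, k=k)
    return result


def composition(labels: dict[str, int],
                ann: AnnotationTable,
                min_fraction: float = 0.20) -> CompositionReport:
    """Cluster composition per type and per cluster.

    For each annotated type, the fraction of its members in each cluster
    (fractions sum to 1 over clusters); clusters holding less than
    ``min_fraction`` of a type are flagged minor. Also reports each
    cluster's type makeup.
    """
    missing = sorted(i for i in labels if i not in ann)
    if missing:
        raise SomamapError(
            f"labeled neurons missing annotations: {missing[:10]}"
        )
    rows = [
        {"neuron_id": i, "type": ann.type_of(i), "cluster": c}
        for i, c in labels.items()
    ]
    df = pd.DataFrame(rows)

    by_type = (
        df.groupby(["type", "cluster"], sort=True).size().rename("count").reset_index()
    )
    type_totals = df.groupby("type").size()
    by_type["fraction"] = by_type.apply(
        lambda r: r["count"] / type_totals[r["type"]], axis=1
    )
    by_type["minor"] = by_type["fraction"] < min_fraction

    by_cluster = (
        df.groupby(["cluster", "type"], sort=True).size().rename("count").reset_index()
    )
    cluster_totals = df.groupby("cluster").size()
    by_cluster["fraction"] = by_cluster.apply(
        lambda r: r["count"] / cluster_totals[r["cluster"]], axis=1
    )
    return CompositionReport(by_type=by_type, by_cluster=by_cluster,
                             min_fraction=min_fraction)
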