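"""Morphological similarity: dotprops, pairwise scoring, Ward clustering.

Neurons are reduced to point clouds with locally fitted unit tangent
vectors. A pair is scored by matching every query point to its single
nearest target point and summing ``score_fn(distance, |tangent dot|)``
contributions; the default kernel is ``exp(-d/sigma) * |u.v|``. All-by-all
scores are self-normalized and symmetrized, then clustered with Ward on
``1 - similarity``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .errors import SomamapError
from .skeletons import Skeleton

__all__ = [
    "Dotprops",
    "SimilarityMatrix",
    "ClusterResult",
    "make_dotprops",
    "default_score_fn",
    "nblast_raw",
    "nblast_matrix",
    "ward_cluster",
    "cut_clusters",
]

DEFAULT_SIGMA_UM = 3.0
DEFAULT_K = 5

ScoreFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass
class Dotprops:
    """Point cloud with unit tangents and colinearity weights for one neuron."""

    neuron_id: str
    points: np.ndarray  # N×3, µm
    tangents: np.ndarray  # N×3, unit norm
    alpha: np.ndarray  # N, first-eigenvalue fraction in [0, 1]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.tangents = np.asarray(self.tangents, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be N×3")
        if len(self.points) < 1:
            raise ValueError("dotprops needs at least one point")
        if not np.isfinite(self.points).all():
            raise ValueError("points must be finite")
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("tangents must be unit vectors")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SimilarityMatrix:
    """Symmetric normalized similarity with unit diagonal over neuron ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be n×n matching ids")

    def check(self, atol: float = 1e-9) -> None:
        if not np.allclose(self.values, self.values.T, atol=atol):
            raise SomamapError("similarity matrix not symmetric within tolerance")
        if not np.allclose(np.diag(self.values), 1.0, atol=atol):
            raise SomamapError("similarity matrix diagonal must be 1")


@dataclass
class ClusterResult:
    """Ward linkage over neuron ids plus (optional) flat labels at a cut."""

    ids: list[str]
    linkage: np.ndarray  # scipy (n-1)×4: left, right, height, size
    labels: dict[str, int] = field(default_factory=dict)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


# ---------------------------------------------------------------------------
# Dotprops construction
# ---------------------------------------------------------------------------

def make_dotprops(skeleton_or_points: Skeleton | np.ndarray,
                  k: int = DEFAULT_K,
                  neuron_id: str | None = None) -> Dotprops:
    """Fit a tangent per point from the PCA of its ``k`` nearest points.

    The tangent is the dominant eigenvector of the covariance of the k
    nearest points (including the point itself); ``alpha`` is the dominant
    eigenvalue's fraction of the total. ``k`` is clamped to the number of
    points. Tangent signs are canonicalized so the first nonzero component
    is positive.
    """
    if isinstance(skeleton_or_points, Skeleton):
        points = skeleton_or_points.coords
        if neuron_id is None:
            neuron_id = skeleton_or_points.neuron_id
    else:
        points = np.atleast_2d(np.asarray(skeleton_or_points, dtype=float))
        if neuron_id is None:
            neuron_id = "points"
    n = len(points)
    if n == 0:
        raise ValueError("cannot build dotprops from zero points")
    k_eff = min(k, n)

    tangents = np.zeros((n, 3))
    alpha = np.ones(n)
    if n == 1 or k_eff == 1:
        tangents[:] = (1.0, 0.0, 0.0)  # canonical default for degenerate input
        return Dotprops(neuron_id, points, tangents, alpha)

    tree = cKDTree(points)
    _, idx = tree.query(points, k=k_eff)
    if k_eff == 1:
        idx = idx[:, None]
    for i in range(n):
        nbrs = points[idx[i]]
        centered = nbrs - nbrs.mean(axis=0)
        cov = centered.T @ centered / len(nbrs)
        evals, evecs = np.linalg.eigh(cov)  # ascending
        total = evals.sum()
        if total <= 0:
            tangents[i] = (1.0, 0.0, 0.0)
            alpha[i] = 1.0
            continue
        t = evecs[:, -1]
        nz = np.nonzero(np.abs(t) > 1e-12)[0]
        if len(nz) and t[nz[0]] < 0:
            t = -t
        tangents[i] = t / np.linalg.norm(t)
        alpha[i] = evals[-1] / total
    return Dotprops(neuron_id, points, tangents, alpha)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def default_score_fn(dist: np.ndarray, dotp: np.ndarray,
                     sigma: float = DEFAULT_SIGMA_UM) -> np.ndarray:
    """Per-point contribution ``exp(-d/sigma) * |u.v|``."""
    return np.exp(-np.asarray(dist, dtype=float) / sigma) * np.abs(dotp)


def nblast_raw(query: Dotprops, target: Dotprops,
               score_fn: ScoreFn | None = None) -> float:
    """Raw directed score: sum of kernel contributions over query points.

    Each query point is matched to its single nearest target point.
    """
    if score_fn is None:
        score_fn = default_score_fn
    tree = cKDTree(target.points)
    dist, idx = tree.query(query.points, k=1)
    dotp = np.einsum("ij,ij->i", query.tangents, target.tangents[idx])
    return float(np.sum(score_fn(dist, dotp)))


def nblast_matrix(neurons: Sequence[Dotprops],
                  score_fn: ScoreFn | None = None) -> SimilarityMatrix:
    """All-by-all normalized similarity.

    ``S_ij = (raw(i,j)/raw(i,i) + raw(j,i)/raw(j,j)) / 2`` — the mean of
    forward and reverse self-normalized scores; ``S_ii = 1`` exactly.
    """
    if len(neurons) < 2:
        raise ValueError("need at least two neurons")
    n = len(neurons)
    self_scores = np.array([nblast_raw(d, d, score_fn) for d in neurons])
    if np.any(self_scores <= 0):
        bad = [neurons[i].neuron_id for i in np.nonzero(self_scores <= 0)[0]]
        raise SomamapError(f"zero self-score for neurons: {bad}")
    raw = np.empty((n, n))
    for i in range(n):
        raw[i, i] = self_scores[i]
        for j in range(n):
            if i != j:
                raw[i, j] = nblast_raw(neurons[i], neurons[j], score_fn)
    norm = raw / self_scores[:, None]
    values = 0.5 * (norm + norm.T)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=[d.neuron_id for d in neurons], values=values)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def ward_cluster(sim: SimilarityMatrix, atol: float = 1e-9) -> ClusterResult:
    """Ward linkage on the dissimilarity ``d = 1 - similarity``."""
    values = np.asarray(sim.values, dtype=float)
    if not np.allclose(values, values.T, atol=max(atol, 1e-8)):
        raise SomamapError("similarity matrix not symmetric; cannot cluster")
    dist = 1.0 - 0.5 * (values + values.T)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="ward")
    return ClusterResult(ids=list(sim.ids), linkage=linkage)


def cut_clusters(result: ClusterResult, height: float | None = None,
                 k: int | None = None) -> dict[str, int]:
    """Flat labels from a linkage cut.

    Exactly one of ``height`` / ``k`` must be given. Cutting at ``height``
    applies merges with merge height strictly below it; ``k`` applies the
    first ``n - k`` merges. Labels are renumbered 1.. in order of first
    member appearance.
    """
    if (height is None) == (k is None):
        raise ValueError("give exactly one of height or k")
    n = len(result.ids)
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        n_merges = n - k
    else:
        n_merges = int(np.sum(result.linkage[:, 2] < height))

    # union-find over the first n_merges linkage rows
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for row in range(n_merges):
        left, right = int(result.linkage[row, 0]), int(result.linkage[row, 1])
        new = n + row
        parent[find(left)] = new
        parent[find(right)] = new

    raw_labels = [find(i) for i in range(n)]
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for nid, lab in zip(result.ids, raw_labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[nid] = remap[lab]
    return labels


def to_newick(result: ClusterResult) -> str:
    """Dendrogram as a Newick string with merge heights as branch lengths."""
    n = len(result.ids)
    height = {i: 0.0 for i in range(n)}
    text = {i: result.ids[i].replace(" ", "_") for i in range(n)}
    for row in range(len(result.linkage)):
        left, right, h = (int(result.linkage[row, 0]),
                          int(result.linkage[row, 1]),
                          float(result.linkage[row, 2]))
        node = n + row
        bl_l = h - height[left]
        bl_r = h - height[right]
        text[node] = f"({text[left]}:{bl_l:.6g},{text[right]}:{bl_r:.6g})"
        height[node] = h
    return text[2 * n - 2] + ";"
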