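"""Neuron skeletons: SWC I/O, validation, box pruning and edge resampling.

A skeleton is a rooted tree of 3-D nodes in micrometres. Nodes keep their
SWC integer ids; parent links define the tree (parent ``-1`` marks a root).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    EmptyResultError,
    SkeletonValidationError,
    SwcParseError,
)

__all__ = [
    "SkeletonNode",
    "Skeleton",
    "RegionBox",
    "read_swc",
    "write_swc",
    "prune_to_region",
    "resample",
    "cable_length",
]


@dataclass(frozen=True)
class SkeletonNode:
    """One SWC row: id, structure label, position (µm), radius (µm), parent."""

    node_id: int
    x: float
    y: float
    z: float
    radius: float = 0.0
    parent_id: int = -1
    label: int = 0


@dataclass
class Skeleton:
    """A rooted tree of :class:`SkeletonNode` belonging to one neuron.

    ``fragmented`` is set when the node set holds more than one connected
    component (allowed only when explicitly flagged, e.g. after pruning with
    ``keep='all'``).
    """

    neuron_id: str
    nodes: list[SkeletonNode] = field(default_factory=list)
    fragmented: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def node_ids(self) -> np.ndarray:
        return np.array([n.node_id for n in self.nodes], dtype=np.int64)

    @property
    def coords(self) -> np.ndarray:
        """N×3 array of node coordinates in µm, in node order."""
        return np.array([[n.x, n.y, n.z] for n in self.nodes], dtype=float)

    @property
    def roots(self) -> list[int]:
        return [n.node_id for n in self.nodes if n.parent_id == -1]

    def node_map(self) -> dict[int, SkeletonNode]:
        return {n.node_id: n for n in self.nodes}

    def validate(self) -> None:
        if not self.nodes:
            raise SkeletonValidationError(f"skeleton {self.neuron_id!r} has no nodes")
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise SkeletonValidationError(
                f"skeleton {self.neuron_id!r}: duplicate node_id {dup}"
            )
        id_set = set(ids)
        for n in self.nodes:
            if n.parent_id == n.node_id:
                raise SkeletonValidationError(
                    f"skeleton {self.neuron_id!r}: node {n.node_id} is its own parent"
                )
            if n.parent_id != -1 and n.parent_id not in id_set:
                raise SkeletonValidationError(
                    f"skeleton {self.neuron_id!r}: node {n.node_id} has dangling "
                    f"parent {n.parent_id}"
                )
        self._check_acyclic()
        n_components = self._count_components()
        if n_components > 1 and not self.fragmented:
            raise SkeletonValidationError(
                f"skeleton {self.neuron_id!r} has {n_components} connected "
                "components but is not flagged fragmented"
            )

    def _check_acyclic(self) -> None:
        parent = {n.node_id: n.parent_id for n in self.nodes}
        state: dict[int, int] = {}  # 0 visiting chain member, 1 cleared
        for start in parent:
            chain = []
            cur = start
            while cur != -1 and state.get(cur) is None:
                state[cur] = 0
                chain.append(cur)
                cur = parent[cur]
            if cur != -1 and state.get(cur) == 0:
                raise SkeletonValidationError(
                    f"skeleton {self.neuron_id!r}: cycle through node {cur}"
                )
            for c in chain:
                state[c] = 1

    def _count_components(self) -> int:
        return sum(1 for n in self.nodes if n.parent_id == -1)

    def path_depth(self) -> dict[int, int]:
        """Steps from each node to its component root, along parent links."""
        parent = {n.node_id: n.parent_id for n in self.nodes}
        depth: dict[int, int] = {}
        for start in parent:
            chain = []
            cur = start
            while cur not in depth and parent[cur] != -1:
                chain.append(cur)
                cur = parent[cur]
            if cur not in depth:  # reached a root
                depth[cur] = 0
            for c in reversed(chain):
                depth[c] = depth[parent[c]] + 1
        return depth


@dataclass(frozen=True)
class RegionBox:
    """Closed axis-aligned box in µm; stands in for a synapse-hull volume."""

    min_corner: tuple[float, float, float]
    max_corner: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo = np.asarray(self.min_corner, dtype=float)
        hi = np.asarray(self.max_corner, dtype=float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("corners must be 3-D")
        if np.any(lo > hi):
            raise ValueError("min_corner must be <= max_corner componentwise")

    def contains(self, coords: np.ndarray) -> np.ndarray:
        """Boolean membership for an N×3 coordinate array (closed box)."""
        pts = np.atleast_2d(np.asarray(coords, dtype=float))
        lo = np.asarray(self.min_corner, dtype=float)
        hi = np.asarray(self.max_corner, dtype=float)
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    @classmethod
    def from_points(cls, points: np.ndarray, pad: float = 0.0) -> "RegionBox":
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.size == 0:
            raise ValueError("cannot build a RegionBox from zero points")
        return cls(
            tuple(pts.min(axis=0) - pad),
            tuple(pts.max(axis=0) + pad),
        )


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path: str | os.PathLike, neuron_id: str | None = None,
             units_scale: float = 1.0) -> Skeleton:
    """Read a 7-column whitespace-delimited SWC file into a :class:`Skeleton`.

    ``units_scale`` multiplies coordinates and radii on read (e.g. 1e-3 for
    nm-native files). Node order is preserved.
    """
    nodes: list[SkeletonNode] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcParseError(
                    f"expected 7 columns, got {len(parts)}", lineno
                )
            try:
                nodes.append(
                    SkeletonNode(
                        node_id=int(parts[0]),
                        label=int(parts[1]),
                        x=float(parts[2]) * units_scale,
                        y=float(parts[3]) * units_scale,
                        z=float(parts[4]) * units_scale,
                        radius=float(parts[5]) * units_scale,
                        parent_id=int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise SwcParseError(str(exc), lineno) from exc
    if neuron_id is None:
        neuron_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return Skeleton(neuron_id=neuron_id, nodes=nodes)


def write_swc(skeleton: Skeleton, path: str | os.PathLike) -> str:
    """Write a standard 7-column SWC file; inverse of :func:`read_swc`."""
    skeleton.validate()
    with open(path, "w") as fh:
        fh.write(f"# neuron_id {skeleton.neuron_id}\n")
        fh.write("# id type x y z radius parent\n")
        for n in skeleton.nodes:
            fh.write(
                f"{n.node_id} {n.label} {n.x:.9g} {n.y:.9g} {n.z:.9g} "
                f"{n.radius:.9g} {n.parent_id}\n"
            )
    return os.fspath(path)


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def prune_to_region(skeleton: Skeleton, region: RegionBox,
                    keep: str = "largest") -> Skeleton:
    """Keep exactly the nodes inside ``region`` (closed box membership).

    Each surviving connected fragment is re-rooted at its node closest to
    the old root along the tree (fewest parent-link steps in the original
    skeleton). With ``keep='largest'`` only the biggest fragment is
    retained; ``keep='all'`` keeps every fragment and flags the result
    fragmented.
    """
    if keep not in ("largest", "all"):
        raise ValueError(f"keep must be 'largest' or 'all', got {keep!r}")
    inside = region.contains(skeleton.coords)
    if not inside.any():
        raise EmptyResultError(
            f"skeleton {skeleton.neuron_id!r} has no nodes inside the region"
        )
    kept = {n.node_id for n, flag in zip(skeleton.nodes, inside) if flag}
    parent = {n.node_id: n.parent_id for n in skeleton.nodes}
    depth = skeleton.path_depth()

    # fragments = connected components of the induced subgraph
    adj: dict[int, list[int]] = {i: [] for i in kept}
    for i in kept:
        p = parent[i]
        if p != -1 and p in kept:
            adj[i].append(p)
            adj[p].append(i)
    fragments: list[set[int]] = []
    unseen = set(kept)
    while unseen:
        start = min(unseen)
        comp = {start}
        stack = [start]
        unseen.discard(start)
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb in unseen:
                    unseen.discard(nb)
                    comp.add(nb)
                    stack.append(nb)
        fragments.append(comp)

    if keep == "largest":
        fragments = [max(fragments, key=lambda c: (len(c), -min(c)))]

    # re-root each fragment at its minimum-depth node, re-orient parents
    node_map = skeleton.node_map()
    new_parent: dict[int, int] = {}
    for comp in fragments:
        root = min(comp, key=lambda i: (depth[i], i))
        new_parent[root] = -1
        stack = [root]
        seen = {root}
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    new_parent[nb] = cur
                    stack.append(nb)

    new_nodes = [
        replace(node_map[i], parent_id=new_parent[i])
        for i in (n.node_id for n in skeleton.nodes)
        if i in new_parent
    ]
    return Skeleton(
        neuron_id=skeleton.neuron_id,
        nodes=new_nodes,
        fragmented=len(fragments) > 1,
    )


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(skeleton: Skeleton, step: float) -> Skeleton:
    """Subdivide parent-child edges so inter-node spacing is <= ``step`` µm.

    Inserted nodes are linearly interpolated; original nodes (branch and end
    points included) keep their exact coordinates. Node ids are renumbered
    1..N in traversal order.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    node_map = skeleton.node_map()
    new_nodes: list[SkeletonNode] = []
    id_of: dict[int, int] = {}  # old id -> new id
    next_id = 1

    def _emit(x: float, y: float, z: float, radius: float, label: int,
              parent_new: int) -> int:
        nonlocal next_id
        new_nodes.append(
            SkeletonNode(node_id=next_id, x=x, y=y, z=z, radius=radius,
                         parent_id=parent_new, label=label)
        )
        next_id += 1
        return next_id - 1

    for n in skeleton.nodes:
        if n.parent_id == -1:
            id_of[n.node_id] = _emit(n.x, n.y, n.z, n.radius, n.label, -1)
            continue
        p = node_map[n.parent_id]
        a = np.array([p.x, p.y, p.z])
        b = np.array([n.x, n.y, n.z])
        length = float(np.linalg.norm(b - a))
        parent_new = id_of[n.parent_id]
        if length > step:
            n_seg = int(np.ceil(length / step - 1e-12))
            for j in range(1, n_seg):
                t = j / n_seg
                q = a + t * (b - a)
                r = p.radius + t * (n.radius - p.radius)
                parent_new = _emit(q[0], q[1], q[2], r, n.label, parent_new)
        id_of[n.node_id] = _emit(n.x, n.y, n.z, n.radius, n.label, parent_new)

    return Skeleton(neuron_id=skeleton.neuron_id, nodes=new_nodes,
                    fragmented=skeleton.fragmented)


def cable_length(skeleton: Skeleton) -> float:
    """Total parent-child edge length in µm."""
    node_map = skeleton.node_map()
    total = 0.0
    for n in skeleton.nodes:
        if n.parent_id == -1:
            continue
        p = node_map[n.parent_id]
        total += float(
            np.sqrt((n.x - p.x) ** 2 + (n.y - p.y) ** 2 + (n.z - p.z) ** 2)
        )
    return total
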