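"""Seeded generator of a ground-truthed somatotopic connectome.

The head is a unit hemisphere; each sensory type owns a patch of bristles
around a type centroid. Brain projection zones are placed by a fixed
monotone map of the head surface (chord distance of the centroid unit
vectors, scaled), so neurons of neighboring types arborize in overlapping
zones and distant types in disjoint ones. Partners are owned by one type
each; connection probability depends only on the focal/owner type relation
(same / neighbor / distant). Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import AnnotationTable
from .errors import ConfigError
from .skeletons import Skeleton, SkeletonNode

__all__ = [
    "TypeSpec",
    "HeadLayout",
    "GroundTruth",
    "default_roster",
    "generate_layout",
    "generate_skeletons",
    "generate_synapses",
]

AXON_LABEL = 2  # SWC structure label for the smooth entry axon
ARBOR_LABEL = 5  # SWC structure label for arbor nodes (synapse-bearing)

NERVE_ENTRY_UM = {
    "AntNv": (90.0, 30.0, -30.0),
    "EyeNv": (90.0, -30.0, -10.0),
    "OcciNv": (90.0, 0.0, 40.0),
    "LabNv": (90.0, -50.0, -50.0),
}


@dataclass(frozen=True)
class TypeSpec:
    """Roster entry: one sensory type and its generation parameters."""

    label: str
    n_neurons: int
    nerve: str = "AntNv"
    side: str = "right"
    crossing: bool = False
    n_partners: int = 25

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ConfigError(f"type {self.label!r}: n_neurons must be >= 1")
        if self.n_partners < 0:
            raise ConfigError(f"type {self.label!r}: n_partners must be >= 0")


@dataclass
class HeadLayout:
    """Type roster with head-surface centroids and brain zone centers."""

    types: list[TypeSpec]
    centroids: dict[str, np.ndarray]  # label -> unit vector on hemisphere
    zone_centers: dict[str, np.ndarray]  # label -> µm brain position
    bristles: dict[str, np.ndarray]  # neuron_id -> unit vector
    neuron_types: dict[str, str]  # neuron_id -> type label
    neighbors: dict[str, list[str]]  # label -> k nearest other type labels
    zone_scale: float = 30.0
    zone_offset: tuple[float, float, float] = (60.0, 0.0, 0.0)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.types]

    @property
    def neuron_ids(self) -> list[str]:
        return list(self.neuron_types)

    def spec_of(self, label: str) -> TypeSpec:
        return next(t for t in self.types if t.label == label)

    def head_distance(self, a: str, b: str) -> float:
        """Great-circle distance between two type centroids (radians)."""
        cosang = float(np.clip(self.centroids[a] @ self.centroids[b], -1, 1))
        return float(np.arccos(cosang))

    def annotations(self) -> AnnotationTable:
        records = {}
        for nid, label in self.neuron_types.items():
            spec = self.spec_of(label)
            records[nid] = (label, spec.nerve, spec.side)
        return AnnotationTable.from_records(records)


@dataclass
class GroundTruth:
    """Generation truth: neuron typing/laterality, partner ownership, params."""

    neurons: dict[str, dict] = field(default_factory=dict)
    partners: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0

    def type_labels(self, neuron_ids: list[str]) -> list[str]:
        return [self.neurons[i]["type"] for i in neuron_ids]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"neurons": self.neurons, "partners": self.partners,
                 "params": self.params, "seed": self.seed},
                fh, indent=1, sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(neurons=d["neurons"], partners=d["partners"],
                   params=d["params"], seed=d["seed"])


def default_roster(inom_n: int = 60) -> list[TypeSpec]:
    """A 15-type roster: small per-type counts plus one large eye-bristle-like
    type with many small neurons, analyzed separately downstream."""
    return [
        TypeSpec("Ant", 20, "AntNv", crossing=True),
        TypeSpec("Fr", 6, "AntNv", crossing=True),
        TypeSpec("InOc", 3, "AntNv", crossing=True),
        TypeSpec("Oc", 1, "AntNv", crossing=True),
        TypeSpec("Or", 3, "AntNv"),
        TypeSpec("FrOr", 6, "AntNv"),
        TypeSpec("Vib", 18, "EyeNv"),
        TypeSpec("MaPa", 15, "EyeNv"),
        TypeSpec("Taste", 8, "LabNv"),
        TypeSpec("Hau", 5, "LabNv", crossing=True),
        TypeSpec("VtPoOc", 5, "OcciNv", crossing=True),
        TypeSpec("dPoOr", 8, "OcciNv"),
        TypeSpec("dOcci", 3, "OcciNv"),
        TypeSpec("vOcci", 26, "EyeNv"),
        TypeSpec("InOm", inom_n, "EyeNv", n_partners=40),
    ]


def _hemisphere_lattice(n: int) -> np.ndarray:
    """n well-spread unit vectors with non-negative x (right head surface)."""
    pts = []
    golden = (1 + 5 ** 0.5) / 2
    i = 0
    while len(pts) < n:
        z = 1 - 2 * (i + 0.5) / (2 * n)  # sample a full sphere, keep x >= 0
        r = np.sqrt(max(0.0, 1 - z * z))
        theta = 2 * np.pi * i / golden
        p = np.array([r * np.cos(theta), r * np.sin(theta), z])
        if p[0] >= 0:
            pts.append(p)
        i += 1
    return np.array(pts[:n])


def generate_layout(types: list[TypeSpec] | None = None,
                    seed: int = 0,
                    zone_scale: float = 30.0,
                    zone_offset: tuple[float, float, float] = (60.0, 0.0, 0.0),
                    bristle_spread: float = 0.06,
                    n_neighbors: int = 2) -> HeadLayout:
    """Place type centroids on the head hemisphere and map them to brain zones.

    Zone centers are ``offset + scale * centroid``; because chord distance
    is strictly increasing in great-circle distance, inter-zone distance
    increases monotonically with head-surface distance between centroids.
    Bristle positions are sampled around each type centroid with tangent-
    plane Gaussian spread (radians) and renormalized to the sphere.
    """
    if types is None:
        types = default_roster()
    if len(types) < 2:
        raise ConfigError("need at least 2 types")
    labels = [t.label for t in types]
    if len(set(labels)) != len(labels):
        raise ConfigError("duplicate type labels")
    rng = np.random.default_rng(seed)

    lattice = _hemisphere_lattice(len(types))
    centroids = {t.label: lattice[i] for i, t in enumerate(types)}
    offset = np.asarray(zone_offset, dtype=float)
    zone_centers = {
        lab: offset + zone_scale * vec for lab, vec in centroids.items()
    }

    bristles: dict[str, np.ndarray] = {}
    neuron_types: dict[str, str] = {}
    for t in types:
        c = centroids[t.label]
        for j in range(t.n_neurons):
            nid = f"{t.label}-{j:03d}"
            jittered = c + rng.normal(0.0, bristle_spread, size=3)
            bristles[nid] = jittered / np.linalg.norm(jittered)
            neuron_types[nid] = t.label

    neighbors: dict[str, list[str]] = {}
    for t in types:
        others = sorted(
            (lab for lab in labels if lab != t.label),
            key=lambda lab: (
                float(np.arccos(np.clip(centroids[t.label] @ centroids[lab], -1, 1))),
                lab,
            ),
        )
        neighbors[t.label] = others[:n_neighbors]

    return HeadLayout(types=list(types), centroids=centroids,
                      zone_centers=zone_centers, bristles=bristles,
                      neuron_types=neuron_types, neighbors=neighbors,
                      zone_scale=zone_scale, zone_offset=tuple(zone_offset))


def _build_arbor_tree(points: np.ndarray, attach_to: int,
                      start_id: int, radius: float = 0.1) -> list[SkeletonNode]:
    """Greedy nearest-neighbor attachment: yields a branched tree over points."""
    nodes: list[SkeletonNode] = []
    placed: list[int] = []  # node ids, aligned with placed_xyz rows
    placed_xyz: list[np.ndarray] = []
    for i, p in enumerate(points):
        nid = start_id + i
        if i == 0:
            parent = attach_to
        else:
            d = np.linalg.norm(np.array(placed_xyz) - p, axis=1)
            parent = placed[int(np.argmin(d))]
        nodes.append(SkeletonNode(node_id=nid, x=float(p[0]), y=float(p[1]),
                                  z=float(p[2]), radius=radius,
                                  parent_id=parent, label=ARBOR_LABEL))
        placed.append(nid)
        placed_xyz.append(p)
    return nodes


def generate_skeletons(layout: HeadLayout,
                       jitter: float = 2.0,
                       n_points: int = 60,
                       seed: int = 0,
                       axon_nodes: int = 8,
                       contra_points: int = 12,
                       contra_x: float = -5.0,
                       midline_x: float = 0.0,
                       ) -> tuple[list[Skeleton], GroundTruth]:
    """Build one skeleton per neuron: entry axon plus jittered zone arbor.

    Each neuron's arbor center is the monotone brain-space image of its own
    bristle position, so within-type arbors overlap most, neighbor types
    partially, distant types not at all (for zone separations >> jitter).
    Types flagged ``crossing`` receive an extra contralateral branch with
    nodes strictly past the midline.
    """
    if jitter < 0:
        raise ConfigError("jitter must be >= 0")
    skeletons: list[Skeleton] = []
    truth = GroundTruth(seed=seed, params={
        "jitter": jitter, "n_points": n_points, "axon_nodes": axon_nodes,
        "contra_points": contra_points, "contra_x": contra_x,
    })
    offset = np.asarray(layout.zone_offset, dtype=float)
    for nid in layout.neuron_ids:
        label = layout.neuron_types[nid]
        spec = layout.spec_of(label)
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, zlib.crc32(nid.encode())])
        )
        center = offset + layout.zone_scale * layout.bristles[nid]
        entry = np.asarray(NERVE_ENTRY_UM.get(spec.nerve, (90.0, 0.0, 0.0)))

        nodes: list[SkeletonNode] = []
        # smooth entry axon: straight chain, pruned away downstream
        for i in range(axon_nodes):
            t = i / axon_nodes
            p = entry + t * (center - entry)
            nodes.append(SkeletonNode(
                node_id=i + 1, x=float(p[0]), y=float(p[1]), z=float(p[2]),
                radius=0.2, parent_id=-1 if i == 0 else i, label=AXON_LABEL,
            ))
        arbor_pts = center + rng.normal(0.0, jitter, size=(n_points, 3))
        nodes.extend(_build_arbor_tree(arbor_pts, attach_to=axon_nodes,
                                       start_id=axon_nodes + 1))
        if spec.crossing:
            contra_center = np.array([contra_x, center[1], center[2]])
            contra_pts = contra_center + rng.normal(
                0.0, max(jitter * 0.5, 0.1), size=(contra_points, 3)
            )
            # clamp to the contralateral side so crossing truth is exact
            limit = midline_x - 0.5
            contra_pts[:, 0] = np.minimum(contra_pts[:, 0], limit)
            nodes.extend(_build_arbor_tree(
                contra_pts, attach_to=axon_nodes + 1,
                start_id=axon_nodes + n_points + 1,
            ))
        skeletons.append(Skeleton(neuron_id=nid, nodes=nodes))
        truth.neurons[nid] = {
            "type": label, "side": spec.side, "crossing": bool(spec.crossing),
        }
    return skeletons, truth


def generate_synapses(layout: HeadLayout,
                      skeletons: list[Skeleton],
                      p_same: float = 0.9,
                      p_neighbor: float = 0.4,
                      p_distant: float = 0.0,
                      mean_syn: float = 5.0,
                      cleft_params: tuple[float, float] = (70.0, 25.0),
                      seed: int = 0,
                      p_bmn: float = 0.03,
                      truth: GroundTruth | None = None,
                      ) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample the synapse table and partner ground truth.

    Each type owns ``n_partners`` partners. A focal neuron connects to a
    partner with probability ``p_same`` / ``p_neighbor`` / ``p_distant``
    according to the relation between its type and the partner's owner
    type. Realized edges carry ``1 + Poisson(mean_syn - 1)`` synapses, one
    table row each; cleft scores are rounded clipped normals so a tunable
    fraction falls below the downstream threshold. Sparse focal-to-focal
    rows are added between same- and neighbor-type neurons only. Synapse
    positions sit on arbor nodes of the presynaptic neuron.
    """
    for name, p in (("p_same", p_same), ("p_neighbor", p_neighbor),
                    ("p_distant", p_distant), ("p_bmn", p_bmn)):
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"{name} must be in [0, 1], got {p}")
    if mean_syn < 1.0:
        raise ConfigError("mean_syn must be >= 1")
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = GroundTruth(seed=seed)
    truth.params.update({
        "p_same": p_same, "p_neighbor": p_neighbor, "p_distant": p_distant,
        "mean_syn": mean_syn, "cleft_mu": cleft_params[0],
        "cleft_sigma": cleft_params[1], "p_bmn": p_bmn,
    })

    partners: list[tuple[str, str]] = []  # (partner_id, owner type)
    counter = 0
    for t in layout.types:
        for _ in range(t.n_partners):
            counter += 1
            pid = f"P{counter:04d}"
            partners.append((pid, t.label))
            truth.partners[pid] = t.label

    arbor_xyz: dict[str, np.ndarray] = {}
    for sk in skeletons:
        pts = np.array([[n.x, n.y, n.z] for n in sk.nodes
                        if n.label == ARBOR_LABEL])
        if len(pts) == 0:
            pts = sk.coords
        arbor_xyz[sk.neuron_id] = pts

    mu, sigma_c = cleft_params
    rows: list[tuple] = []

    def _emit(pre: str, post: str, count: int) -> None:
        pts = arbor_xyz[pre]
        idx = rng.integers(0, len(pts), size=count)
        scores = np.maximum(np.rint(rng.normal(mu, sigma_c, size=count)), 0)
        for i in range(count):
            p = pts[idx[i]]
            rows.append((pre, post, int(scores[i]),
                         float(p[0]), float(p[1]), float(p[2])))

    for nid in layout.neuron_ids:
        label = layout.neuron_types[nid]
        nbrs = set(layout.neighbors[label])
        for pid, owner in partners:
            if owner == label:
                p = p_same
            elif owner in nbrs:
                p = p_neighbor
            else:
                p = p_distant
            if p > 0 and rng.random() < p:
                count = 1 + int(rng.poisson(mean_syn - 1.0))
                _emit(nid, pid, count)

    if p_bmn > 0:
        ids = layout.neuron_ids
        for pre in ids:
            t_pre = layout.neuron_types[pre]
            allowed = {t_pre} | set(layout.neighbors[t_pre])
            for post in ids:
                if post == pre or layout.neuron_types[post] not in allowed:
                    continue
                if rng.random() < p_bmn:
                    count = 1 + int(rng.poisson(mean_syn - 1.0))
                    _emit(pre, post, count)

    table = pd.DataFrame(
        rows, columns=["pre_id", "post_id", "cleft_score", "x", "y", "z"]
    )
    return table, truth
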