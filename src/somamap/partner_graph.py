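"""Dominant-input partner assignment and the thresholded type→group graph.

Each postsynaptic partner is assigned to the annotated type contributing
the most synaptic input to it; the output graph connects each type to the
partner groups so formed, keeping only edges exceeding a fraction of the
type's total assigned output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .connectivity import AnnotationTable

__all__ = [
    "PartnerAssignment",
    "TypePartnerGraph",
    "assign_partners",
    "build_graph",
]

logger = logging.getLogger(__name__)

DEFAULT_FRACTION_MIN = 0.05


@dataclass
class PartnerAssignment:
    """partner_id -> dominant-input type, with the per-type input sums."""

    assigned: dict[str, str]
    input_by_type: dict[str, dict[str, int]]
    ties: set[str] = field(default_factory=set)

    def group_of(self, partner_id: str) -> str:
        """Partner-group label, e.g. ``Ant_post`` for an Ant-dominated partner."""
        return f"{self.assigned[partner_id]}_post"


@dataclass
class TypePartnerGraph:
    """Thresholded bipartite type → partner-group graph."""

    edges: pd.DataFrame  # columns: type, partner_group, weight, fraction
    type_totals: dict[str, int]
    fraction_min: float = DEFAULT_FRACTION_MIN
    dropped: pd.DataFrame | None = None

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for t, total in self.type_totals.items():
            g.add_node(t, kind="type", total_output=total)
        for row in self.edges.itertuples(index=False):
            g.add_node(row.partner_group, kind="partner_group")
            g.add_edge(row.type, row.partner_group,
                       weight=int(row.weight), fraction=float(row.fraction))
        return g


def assign_partners(edges: dict[tuple[str, str], int],
                    ann: AnnotationTable) -> PartnerAssignment:
    """Assign each non-annotated postsynaptic partner to its argmax input type.

    Input from all annotated (typed) presynaptic neurons is summed by type;
    the partner is assigned to the type with the highest sum. Ties break to
    the lexicographically smallest label and are flagged. Partners with no
    annotated input do not appear.
    """
    input_by_type: dict[str, dict[str, int]] = {}
    for (pre, post), w in edges.items():
        if pre not in ann or post in ann:
            continue  # only typed → untyped-partner edges count
        per_type = input_by_type.setdefault(post, {})
        t = ann.type_of(pre)
        per_type[t] = per_type.get(t, 0) + w

    assigned: dict[str, str] = {}
    ties: set[str] = set()
    for partner, per_type in input_by_type.items():
        best = max(per_type.values())
        winners = sorted(t for t, v in per_type.items() if v == best)
        assigned[partner] = winners[0]
        if len(winners) > 1:
            ties.add(partner)
    return PartnerAssignment(assigned=assigned, input_by_type=input_by_type,
                             ties=ties)


def build_graph(edges: dict[tuple[str, str], int],
                assignment: PartnerAssignment,
                ann: AnnotationTable,
                fraction_min: float = DEFAULT_FRACTION_MIN) -> TypePartnerGraph:
    """Sum type → partner-group weights and keep edges above ``fraction_min``.

    Edge fraction = weight / total output of the type onto assigned
    partners; edges with fraction <= ``fraction_min`` are dropped (strict
    'greater than' retention).
    """
    if not 0 <= fraction_min < 1:
        raise ValueError("fraction_min must be in [0, 1)")
    weight: dict[tuple[str, str], int] = {}
    type_totals: dict[str, int] = {}
    for (pre, post), w in edges.items():
        if pre not in ann or post not in assignment.assigned:
            continue
        t = ann.type_of(pre)
        g = assignment.group_of(post)
        weight[(t, g)] = weight.get((t, g), 0) + w
        type_totals[t] = type_totals.get(t, 0) + w

    rows = []
    for (t, g), w in sorted(weight.items()):
        fraction = w / type_totals[t]
        rows.append({"type": t, "partner_group": g,
                     "weight": w, "fraction": fraction})
    df = pd.DataFrame(rows, columns=["type", "partner_group", "weight", "fraction"])
    kept = df[df["fraction"] > fraction_min].reset_index(drop=True)
    dropped = df[df["fraction"] <= fraction_min].reset_index(drop=True)
    for t in ann.types:
        if t not in type_totals:
            logger.info("type %s has zero assigned output; no edges", t)
    return TypePartnerGraph(edges=kept, type_totals=type_totals,
                            fraction_min=fraction_min, dropped=dropped)
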