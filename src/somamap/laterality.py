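"""Midline-crossing classification and per-type percent summaries.

The midline is a plane of constant x in a left/right-symmetric space. A
neuron crosses when any skeleton node lies strictly on the contralateral
side of that plane; a node exactly on the midline does not count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import AnnotationTable
from .skeletons import Skeleton

__all__ = ["LateralityReport", "classify_crossing", "percent_crossing"]

# convention: the left hemisphere is x < midline_x, right is x > midline_x
_SIGN = {"left": 1.0, "right": -1.0}


@dataclass
class LateralityReport:
    """Per-neuron crossing flags plus a per-type percent summary."""

    per_neuron: pd.DataFrame  # columns: neuron_id, type, crossing, excursion_um
    per_type: pd.DataFrame  # columns: type, n_crossing, n_total, percent


def classify_crossing(skeleton: Skeleton, midline_x: float,
                      origin_side: str) -> tuple[bool, float]:
    """Whether any node lies strictly past the midline, and how far.

    ``origin_side`` is the hemisphere of the neuron's origin ('left' =
    x < midline). Returns ``(crossing, excursion)`` where excursion is the
    maximum distance past the midline in µm (0 when not crossing).
    """
    if not np.isfinite(midline_x):
        raise ValueError("midline_x must be finite")
    side = str(origin_side).lower()
    if side not in _SIGN:
        raise ValueError(f"unknown origin side {origin_side!r}")
    # signed distance past the midline, positive on the contralateral side
    signed = _SIGN[side] * (skeleton.coords[:, 0] - midline_x)
    excursion = float(max(signed.max(), 0.0))
    crossing = bool(signed.max() > 0.0)  # strict: on-midline nodes don't count
    return crossing, excursion


def percent_crossing(skeletons: list[Skeleton], ann: AnnotationTable,
                     midline_x: float = 0.0) -> LateralityReport:
    """Classify every skeleton and summarize percent crossing per type."""
    rows = []
    for sk in skeletons:
        crossing, excursion = classify_crossing(
            sk, midline_x, ann.side_of(sk.neuron_id)
        )
        rows.append({
            "neuron_id": sk.neuron_id,
            "type": ann.type_of(sk.neuron_id),
            "crossing": crossing,
            "excursion_um": excursion,
        })
    per_neuron = pd.DataFrame(
        rows, columns=["neuron_id", "type", "crossing", "excursion_um"]
    )
    if len(per_neuron):
        grouped = per_neuron.groupby("type", sort=True)
        per_type = grouped.agg(
            n_crossing=("crossing", "sum"), n_total=("crossing", "size")
        ).reset_index()
        per_type["n_crossing"] = per_type["n_crossing"].astype(int)
        per_type["percent"] = 100.0 * per_type["n_crossing"] / per_type["n_total"]
    else:
        per_type = pd.DataFrame(columns=["type", "n_crossing", "n_total", "percent"])
    return LateralityReport(per_neuron=per_neuron, per_type=per_type)
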