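"""Synapse-table filtering, connection counts and type-level connectivity.

The synapse table has one row per predicted synapse:
``pre_id, post_id, cleft_score, x, y, z``. Neuron ids are treated as
opaque strings throughout (64-bit segmentation root ids overflow float
round-trips in CSV).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnnotationError, SchemaError

__all__ = [
    "SYNAPSE_COLUMNS",
    "AnnotationTable",
    "read_synapse_table",
    "write_synapse_table",
    "filter_synapses",
    "connection_counts",
    "aggregate_edges",
    "type_connectivity",
]

logger = logging.getLogger(__name__)

SYNAPSE_COLUMNS = ["pre_id", "post_id", "cleft_score", "x", "y", "z"]
DEFAULT_CLEFT_MIN = 50


@dataclass
class AnnotationTable:
    """Map neuron_id -> (type label, nerve group, side, optional bristle xy)."""

    table: pd.DataFrame  # index: neuron_id; columns: type, nerve, side[, bx, by]

    def __post_init__(self) -> None:
        required = {"type", "nerve", "side"}
        missing = required - set(self.table.columns)
        if missing:
            raise SchemaError(f"annotation table missing columns: {sorted(missing)}")
        if not self.table.index.is_unique:
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise SchemaError(f"duplicate neuron ids in annotations: {dupes[:5]}")
        if (self.table["type"].astype(str) == "").any():
            raise SchemaError("empty type labels in annotation table")
        self.table.index = self.table.index.astype(str)

    @classmethod
    def from_records(cls, records: dict[str, tuple]) -> "AnnotationTable":
        """Build from ``{neuron_id: (type, nerve, side)}`` mappings."""
        df = pd.DataFrame.from_dict(
            records, orient="index", columns=["type", "nerve", "side"]
        )
        df.index.name = "neuron_id"
        return cls(df)

    @classmethod
    def read_csv(cls, path: str | os.PathLike) -> "AnnotationTable":
        df = pd.read_csv(path, dtype={"neuron_id": str})
        if "neuron_id" not in df.columns:
            raise SchemaError("annotation CSV must have a neuron_id column")
        return cls(df.set_index("neuron_id"))

    def write_csv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, index_label="neuron_id")

    def type_of(self, neuron_id: str) -> str:
        return str(self.table.at[str(neuron_id), "type"])

    def side_of(self, neuron_id: str) -> str:
        return str(self.table.at[str(neuron_id), "side"])

    def ids_of_type(self, type_label: str) -> list[str]:
        return self.table.index[self.table["type"] == type_label].tolist()

    @property
    def neuron_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def types(self) -> list[str]:
        return sorted(self.table["type"].unique())

    def __contains__(self, neuron_id: str) -> bool:
        return str(neuron_id) in self.table.index

    def __len__(self) -> int:
        return len(self.table)


def _check_schema(table: pd.DataFrame) -> None:
    missing = [c for c in SYNAPSE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"synapse table missing columns: {missing}")


def read_synapse_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a synapse CSV/TSV; ids as strings, delimiter sniffed from suffix."""
    sep = "\t" if os.fspath(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"pre_id": str, "post_id": str})
    _check_schema(df)
    return df


def write_synapse_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    _check_schema(table)
    sep = "\t" if os.fspath(path).endswith((".tsv", ".tab")) else ","
    table.to_csv(path, sep=sep, index=False)


def filter_synapses(table: pd.DataFrame,
                    cleft_min: float = DEFAULT_CLEFT_MIN) -> pd.DataFrame:
    """Drop rows with cleft_score below ``cleft_min``; scores equal to the
    threshold are kept. Row order is preserved."""
    if "cleft_score" not in table.columns:
        raise SchemaError("synapse table missing cleft_score column")
    if cleft_min < 0:
        raise ValueError("cleft_min must be >= 0")
    out = table[table["cleft_score"] >= cleft_min]
    logger.info(
        "cleft filter (>= %s): kept %d / %d rows (removed %d)",
        cleft_min, len(out), len(table), len(table) - len(out),
    )
    return out.copy()


def connection_counts(table: pd.DataFrame,
                      ids: list[str]) -> pd.DataFrame:
    """Per-neuron row counts as presynaptic and postsynaptic partner.

    Counts table rows (individual synapses), not distinct presynaptic
    sites. Returns a DataFrame indexed by neuron_id with columns
    ``pre_count`` and ``post_count``; absent neurons get zeros.
    """
    _check_schema(table)
    ids = [str(i) for i in ids]
    pre = table["pre_id"].value_counts()
    post = table["post_id"].value_counts()
    out = pd.DataFrame(
        {
            "pre_count": [int(pre.get(i, 0)) for i in ids],
            "post_count": [int(post.get(i, 0)) for i in ids],
        },
        index=pd.Index(ids, name="neuron_id"),
    )
    return out


def aggregate_edges(table: pd.DataFrame) -> dict[tuple[str, str], int]:
    """Collapse synapse rows into ``(pre_id, post_id) -> synapse count``."""
    _check_schema(table)
    if len(table) == 0:
        return {}
    grouped = table.groupby(["pre_id", "post_id"], sort=True).size()
    return {(str(p), str(q)): int(c) for (p, q), c in grouped.items()}


def type_connectivity(edges: dict[tuple[str, str], int],
                      ann: AnnotationTable,
                      types: list[str] | None = None) -> pd.DataFrame:
    """Summed synaptic weight between types per possible directed edge.

    ``M[a, b] = total synapses from type-a to type-b neurons / P(a, b)``
    with ``P(a, b) = n_a * n_b`` off-diagonal and ``n_a * (n_a - 1)`` on
    the diagonal (directed pairs, autapses excluded). A singleton type's
    diagonal is undefined and reported as NaN. Autaptic edges are ignored.
    """
    if types is None:
        types = ann.types
    missing = sorted(
        {i for e in edges for i in e if i not in ann}
    )
    if missing:
        raise AnnotationError("edge endpoints missing annotations", missing)

    n_per_type = {t: len(ann.ids_of_type(t)) for t in types}
    type_index = {t: i for i, t in enumerate(types)}
    sums = np.zeros((len(types), len(types)))
    for (pre, post), w in edges.items():
        if pre == post:
            continue  # autapse
        ta, tb = ann.type_of(pre), ann.type_of(post)
        if ta in type_index and tb in type_index:
            sums[type_index[ta], type_index[tb]] += w

    values = np.zeros_like(sums)
    for a in types:
        for b in types:
            ia, ib = type_index[a], type_index[b]
            if a == b:
                possible = n_per_type[a] * (n_per_type[a] - 1)
            else:
                possible = n_per_type[a] * n_per_type[b]
            values[ia, ib] = sums[ia, ib] / possible if possible > 0 else np.nan
    return pd.DataFrame(values, index=types, columns=types)
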