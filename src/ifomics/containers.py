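"""In-memory containers shared across the pipeline.

`AbundanceMatrix` is a thin wrapper around a features x samples pandas
DataFrame that also carries the group design, the optional TMT plex
assignment, and an explicit value scale so every transform can assert what
it is operating on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

VALUE_SCALES = {"raw_intensity", "log2_intensity", "log2_ratio", "fpkm", "log_fpkm"}


@dataclass
class AbundanceMatrix:
    """Features x samples numeric table with group/plex metadata.

    values: DataFrame indexed by feature id with sample-id columns; NaN is
    the in-memory missing sentinel. sample_groups maps every sample to its
    dietary group; sample_plex (optional) maps samples to TMT set ids.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]
    value_scale: str
    sample_plex: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        if self.value_scale not in VALUE_SCALES:
            raise ValueError(f"unknown value_scale {self.value_scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order over the sample columns."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_groups[s], None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]

    def with_values(self, values: pd.DataFrame, value_scale: str | None = None) -> "AbundanceMatrix":
        """Return a copy carrying new values but the same metadata."""
        groups = {s: self.sample_groups[s] for s in values.columns}
        plex = None
        if self.sample_plex is not None:
            plex = {s: self.sample_plex[s] for s in values.columns if s in self.sample_plex}
        return AbundanceMatrix(
            values=values,
            sample_groups=groups,
            value_scale=value_scale or self.value_scale,
            sample_plex=plex,
        )

    def group_values(self, feature: str) -> dict[str, np.ndarray]:
        """Per-group value arrays (NaN retained) for one feature."""
        row = self.values.loc[feature]
        return {g: row[self.samples_in_group(g)].to_numpy(dtype=float) for g in self.groups}


@dataclass
class AnnotationCollection:
    """Mapping of annotation term -> (description, member feature-id set)."""

    terms: dict[str, tuple[str, frozenset]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_desc, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {term!r} has no members")

    def members(self, term: str) -> frozenset:
        return self.terms[term][1]

    def restricted(self, universe: Iterable[str]) -> "AnnotationCollection":
        """Drop members outside ``universe`` and then empty terms."""
        uni = frozenset(universe)
        kept = {}
        for term, (desc, members) in self.terms.items():
            inter = members & uni
            if inter:
                kept[term] = (desc, inter)
        return AnnotationCollection(terms=kept)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Lexicographically ordered node pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class EdgeList:
    """Undirected edges with optional relation labels/weights + node attributes.

    Self-loops are rejected; duplicate unordered pairs collapse to one edge
    (first relation/weight wins).
    """

    edges: dict[tuple[str, str], dict] = field(default_factory=dict)
    node_attributes: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        relation: str = "pp",
        weights: Optional[Mapping[tuple[str, str], float]] = None,
    ) -> "EdgeList":
        el = cls()
        for a, b in pairs:
            attrs = {"relation": relation}
            if weights is not None:
                w = weights.get((a, b), weights.get((b, a)))
                if w is not None:
                    attrs["weight"] = w
            el.add_edge(a, b, **attrs)
        return el

    def add_edge(self, a: str, b: str, **attrs) -> None:
        if a == b:
            raise ValueError(f"self-loop on node {a!r}")
        key = canonical_edge(a, b)
        if key not in self.edges:
            self.edges[key] = dict(attrs)

    def nodes(self) -> list[str]:
        out: dict[str, None] = {}
        for a, b in self.edges:
            out.setdefault(a, None)
            out.setdefault(b, None)
        for n in self.node_attributes:
            out.setdefault(n, None)
        return sorted(out)

    def __len__(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes())
        for (a, b), attrs in self.edges.items():
            g.add_edge(a, b, **attrs)
        for n, attrs in self.node_attributes.items():
            g.nodes[n].update(attrs)
        return g
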