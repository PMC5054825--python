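"""Directed acyclic networks: validation, topology weights, and two-group merging.

A directed biological network (gene regulation, cell signalling, ...) is
modelled as a labelled DAG.  Comparing two groups requires a *merged
structure*: the union of the two node sets (size ``K``) and the union of the
two directed edge sets (size ``M``), with per-group presence flags so that
elements absent from one group can be zero-filled downstream.  Node weights
reward nodes sitting upstream of many others: the relative weight of a node
is its descendant count divided by the total descendant count, and the
default weight family maps a childless node to weight exactly 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .errors import ConfigurationError, NetworkStructureError

Edge = tuple[str, str]

_WEIGHT_FAMILIES = ("unit", "additive", "power")
_COUNT_MODES = ("descendants", "children")


class DirectedNetwork:
    """A labelled directed acyclic graph for one group.

    Parameters
    ----------
    node_labels:
        Ordered iterable of unique node labels (strings).
    edges:
        Iterable of ``(parent, child)`` label pairs.  Duplicates collapse;
        self-loops and cycles raise :class:`NetworkStructureError`.
    """

    __slots__ = ("node_labels", "edges", "_graph", "_order")

    def __init__(self, node_labels: Iterable[str], edges: Iterable[Edge]):
        labels = tuple(str(l) for l in node_labels)
        if len(labels) != len(set(labels)):
            raise NetworkStructureError("duplicate node labels")
        edge_set = frozenset((str(p), str(c)) for p, c in edges)
        known = set(labels)
        for p, c in edge_set:
            if p == c:
                raise NetworkStructureError(f"self-loop on node {p!r}")
            if p not in known or c not in known:
                raise NetworkStructureError(f"edge ({p!r}, {c!r}) references unknown node")
        self.node_labels = labels
        self.edges = edge_set
        g = nx.DiGraph()
        g.add_nodes_from(labels)
        g.add_edges_from(edge_set)
        self._graph = g
        self._order = validate_and_order(self)

    @classmethod
    def from_edges(cls, edges: Iterable[Edge], extra_nodes: Iterable[str] = ()) -> "DirectedNetwork":
        """Build a network whose node set is the edge endpoints plus ``extra_nodes``."""
        edges = [(str(p), str(c)) for p, c in edges]
        seen: dict[str, None] = {}
        for p, c in edges:
            seen.setdefault(p)
            seen.setdefault(c)
        for l in extra_nodes:
            seen.setdefault(str(l))
        return cls(seen.keys(), edges)

    def graph(self) -> nx.DiGraph:
        return self._graph

    @property
    def topological_order(self) -> tuple[str, ...]:
        return self._order

    def parents(self, label: str) -> tuple[str, ...]:
        return tuple(sorted(self._graph.predecessors(label)))

    def children(self, label: str) -> tuple[str, ...]:
        return tuple(sorted(self._graph.successors(label)))

    def reverse_edge(self, edge: Edge) -> "DirectedNetwork":
        """Return a copy with one edge reversed (re-validated for acyclicity)."""
        edge = (str(edge[0]), str(edge[1]))
        if edge not in self.edges:
            raise NetworkStructureError(f"edge {edge!r} not in network")
        new_edges = (self.edges - {edge}) | {(edge[1], edge[0])}
        return DirectedNetwork(self.node_labels, new_edges)

    def relabel(self, mapping: Mapping[str, str]) -> "DirectedNetwork":
        return DirectedNetwork(
            [mapping.get(l, l) for l in self.node_labels],
            [(mapping.get(p, p), mapping.get(c, c)) for p, c in self.edges],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedNetwork):
            return NotImplemented
        return self.node_labels == other.node_labels and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((self.node_labels, self.edges))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DirectedNetwork({len(self.node_labels)} nodes, {len(self.edges)} edges)"


def validate_and_order(network: DirectedNetwork) -> tuple[str, ...]:
    """Topological order of a validated DAG; every parent precedes its children.

    Raises :class:`NetworkStructureError` naming one cycle if the graph is
    cyclic.  Self-loops are rejected at construction time.
    """
    g = nx.DiGraph()
    g.add_nodes_from(network.node_labels)
    g.add_edges_from(network.edges)
    try:
        return tuple(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        path = " -> ".join([cycle[0][0]] + [e[1] for e in cycle])
        raise NetworkStructureError(f"network contains a cycle: {path}") from None


def descendant_counts(network: DirectedNetwork, mode: str = "descendants") -> dict[str, int]:
    """Per-node count ``c_k`` used by the topology weights.

    ``mode="descendants"`` (default) counts all distinct nodes reachable by
    directed paths of length >= 1; ``mode="children"`` counts direct children
    only.
    """
    if mode not in _COUNT_MODES:
        raise ConfigurationError(f"count mode must be one of {_COUNT_MODES}, got {mode!r}")
    g = network.graph()
    if mode == "children":
        return {l: g.out_degree(l) for l in network.node_labels}
    return {l: len(nx.descendants(g, l)) for l in network.node_labels}


def relative_weights(counts: Mapping[str, int]) -> dict[str, float]:
    """``r_k = c_k / sum_j c_j``; an edgeless graph (all counts 0) gives all zeros."""
    total = float(sum(counts.values()))
    if total == 0.0:
        return {l: 0.0 for l in counts}
    return {l: c / total for l, c in counts.items()}


@dataclass(frozen=True)
class WeightScheme:
    """Node-weight family mapping relative weight r_k to a multiplier w_k >= 1.

    Families
    --------
    unit:     w_k = 1 (reduces WNES to NES)
    additive: w_k = 1 + K * r_k / a            (default, a = tuning)
    power:    w_k = (1 + K * r_k) ** (1 / b)   (b = tuning)

    Smaller tuning constants inflate the topological contribution.  In every
    family a childless node (r_k = 0) has weight exactly 1.
    """

    family: str = "additive"
    tuning: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _WEIGHT_FAMILIES:
            raise ConfigurationError(
                f"weight family must be one of {_WEIGHT_FAMILIES}, got {self.family!r}"
            )
        if not self.tuning > 0:
            raise ConfigurationError(f"weight tuning must be positive, got {self.tuning}")

    def apply(self, r: np.ndarray, K: int) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if self.family == "unit":
            return np.ones_like(r)
        if self.family == "additive":
            return 1.0 + K * r / self.tuning
        return np.power(1.0 + K * r, 1.0 / self.tuning)


def node_weights(r: Mapping[str, float], K: int, scheme: WeightScheme) -> dict[str, float]:
    """Apply a :class:`WeightScheme` to a relative-weight mapping."""
    labels = list(r)
    vals = scheme.apply(np.array([r[l] for l in labels], dtype=float), K)
    return dict(zip(labels, (float(v) for v in vals)))


@dataclass(frozen=True)
class EdgeSlot:
    """One union-edge slot: the concrete directed edge it holds in each group.

    Without reversed-pair collapsing every slot is a single ordered pair
    (possibly absent from one group).  With collapsing, an edge i->j in one
    group and j->i in the other share a slot and are compared directly.
    """

    in_D: Optional[Edge]
    in_C: Optional[Edge]

    def edge_for(self, group: str) -> Optional[Edge]:
        return self.in_D if group == "D" else self.in_C

    @property
    def representative(self) -> Edge:
        e = self.in_D if self.in_D is not None else self.in_C
        assert e is not None
        return e

    @property
    def is_reversed_pair(self) -> bool:
        return (
            self.in_D is not None
            and self.in_C is not None
            and self.in_D == (self.in_C[1], self.in_C[0])
        )


@dataclass(frozen=True)
class MergedStructure:
    """Union bookkeeping for a two-group comparison.

    ``K`` = number of union nodes, ``M`` = number of union edge slots.
    Presence flags record which group contributes each node/slot; absent
    elements are zero-filled by the group summaries.
    """

    union_nodes: tuple[str, ...]
    slots: tuple[EdgeSlot, ...]
    node_in_D: tuple[bool, ...]
    node_in_C: tuple[bool, ...]
    collapse_reversed: bool

    @property
    def K(self) -> int:
        return len(self.union_nodes)

    @property
    def M(self) -> int:
        return len(self.slots)

    @property
    def union_edges(self) -> tuple[Edge, ...]:
        return tuple(s.representative for s in self.slots)

    def node_index(self, label: str) -> int:
        return self.union_nodes.index(label)

    def node_presence(self, group: str) -> tuple[bool, ...]:
        return self.node_in_D if group == "D" else self.node_in_C

    def edge_presence(self, group: str) -> tuple[bool, ...]:
        return tuple(s.edge_for(group) is not None for s in self.slots)


def merge_structures(
    net_D: DirectedNetwork, net_C: DirectedNetwork, collapse_reversed: bool = False
) -> MergedStructure:
    """Merge the two group structures into union nodes and union edge slots.

    Ordered pairs i->j and j->i are distinct union edges unless
    ``collapse_reversed`` is set, in which case a pair reversed between the
    two groups occupies one shared slot whose per-group coefficient estimates
    are compared directly.  Labels are case-sensitive exact-match strings; a
    cross-group collision differing only in case is rejected as a likely
    harmonization mistake.
    """
    labels_D = set(net_D.node_labels)
    union_nodes = tuple(net_D.node_labels) + tuple(
        l for l in net_C.node_labels if l not in labels_D
    )
    by_case: dict[str, str] = {}
    for l in union_nodes:
        prev = by_case.setdefault(l.casefold(), l)
        if prev != l:
            raise NetworkStructureError(
                f"node labels {prev!r} and {l!r} differ only in case; labels are exact-match"
            )
    edges_D = sorted(net_D.edges)
    edges_C = sorted(net_C.edges)
    slots: list[EdgeSlot] = []
    if not collapse_reversed:
        for e in edges_D:
            slots.append(EdgeSlot(in_D=e, in_C=e if e in net_C.edges else None))
        for e in edges_C:
            if e not in net_D.edges:
                slots.append(EdgeSlot(in_D=None, in_C=e))
    else:
        for e in edges_D:
            rev = (e[1], e[0])
            if e in net_C.edges:
                slots.append(EdgeSlot(in_D=e, in_C=e))
            elif rev in net_C.edges:
                slots.append(EdgeSlot(in_D=e, in_C=rev))
            else:
                slots.append(EdgeSlot(in_D=e, in_C=None))
        for e in edges_C:
            if e not in net_D.edges and (e[1], e[0]) not in net_D.edges:
                slots.append(EdgeSlot(in_D=None, in_C=e))
    return MergedStructure(
        union_nodes=union_nodes,
        slots=tuple(slots),
        node_in_D=tuple(l in labels_D for l in union_nodes),
        node_in_C=tuple(l in set(net_C.node_labels) for l in union_nodes),
        collapse_reversed=collapse_reversed,
    )


def merged_node_weights(
    merged: MergedStructure,
    net_D: DirectedNetwork,
    net_C: DirectedNetwork,
    scheme: WeightScheme,
    count_mode: str = "descendants",
) -> np.ndarray:
    """Weight vector over the union nodes for a two-group comparison.

    Each group's relative weights are computed on its own structure (nodes
    absent from a group contribute 0 there); the two vectors are averaged so
    the result is symmetric under group exchange, then the weight family is
    applied with the union node count K.  When both groups share one
    structure this reduces to the single-network weights.
    """
    r_bar = np.zeros(merged.K)
    for net in (net_D, net_C):
        r = relative_weights(descendant_counts(net, mode=count_mode))
        r_bar += np.array([r.get(l, 0.0) for l in merged.union_nodes])
    r_bar /= 2.0
    return scheme.apply(r_bar, merged.K)
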