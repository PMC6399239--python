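"""Decompose a network data set into unambiguously testable simple graphs.

Real network data sets carry properties — direction, weights, layers,
timestamps, bipartite structure, parallel edges — under which "the" degree
distribution is not well defined.  Each non-simple property is removed by a
transformation that may multiply the number of graphs:

* weighted — weights discarded
* multigraph — parallel edges collapsed; self-loops always dropped
* directed — three views: in-degree, out-degree, undirected collapse
* bipartite — two views, one degree sequence per node class (no projection)
* multiplex — one graph per layer plus the union of layers
* temporal — one graph per time slice plus the time-aggregated union

Transformations compose (layers/slices are split first, then direction and
node-class views).  Graphs that are too sparse (mean degree <= 2) or too
dense (mean degree >= sqrt(n)) are excluded from analysis by
:func:`density_filter`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "ValidationError",
    "Edge",
    "NetworkDataset",
    "SimpleGraph",
    "DegreeSequence",
    "simplify_dataset",
    "degree_sequence",
    "density_filter",
]

FLAGS = {"directed", "weighted", "bipartite", "multiplex", "temporal", "multigraph"}


class ValidationError(ValueError):
    """Dataset flags inconsistent with its edge records."""


@dataclass(frozen=True)
class Edge:
    source: object
    target: object
    weight: Optional[float] = None
    layer: Optional[object] = None
    timestamp: Optional[float] = None


@dataclass
class NetworkDataset:
    """A raw network plus its declared graph-property flags."""

    identifier: str
    edges: list
    flags: frozenset = frozenset()
    node_partition: Optional[dict] = None
    nodes: Optional[set] = None

    def __post_init__(self):
        self.flags = frozenset(self.flags)
        unknown = self.flags - FLAGS
        if unknown:
            raise ValidationError(f"unknown flags {sorted(unknown)}")
        self.edges = [e if isinstance(e, Edge) else Edge(*e) for e in self.edges]
        self._validate()
        if self.nodes is None:
            nodes = {e.source for e in self.edges} | {e.target for e in self.edges}
            if self.node_partition:
                nodes |= set(self.node_partition)
            self.nodes = nodes

    def _validate(self):
        if "bipartite" in self.flags and not self.node_partition:
            raise ValidationError("bipartite flag requires a node partition")
        if self.node_partition and len(set(self.node_partition.values())) != 2:
            raise ValidationError("node partition must have exactly two classes")
        has_layer = any(e.layer is not None for e in self.edges)
        if ("multiplex" in self.flags) != has_layer and self.edges:
            raise ValidationError("layer labels present iff multiplex flag set")
        has_time = any(e.timestamp is not None for e in self.edges)
        if ("temporal" in self.flags) != has_time and self.edges:
            raise ValidationError("timestamps present iff temporal flag set")
        if "bipartite" in self.flags:
            part = self.node_partition
            for e in self.edges:
                if e.source in part and e.target in part and part[e.source] == part[e.target]:
                    raise ValidationError("bipartite edge within one node class")


@dataclass(frozen=True)
class SimpleGraph:
    """An undirected simple graph, possibly annotated with a degree view.

    ``degree_mode`` selects which degree sequence the graph contributes
    ("undirected", "in", or "out"; the latter two require the retained
    ``directed_edges``).  ``degree_nodes`` optionally restricts the sequence
    to one node class of a bipartite graph.
    """

    nodes: frozenset
    edges: frozenset  # of frozenset pairs {u, v}
    provenance: str
    degree_mode: str = "undirected"
    directed_edges: Optional[frozenset] = None  # of (u, v) ordered pairs
    degree_nodes: Optional[frozenset] = None

    def __post_init__(self):
        for e in self.edges:
            if len(e) != 2:
                raise ValueError("self-loops are not allowed in a SimpleGraph")
            if not e <= self.nodes:
                raise ValueError("edge endpoint outside node set")
        if self.degree_mode not in ("undirected", "in", "out"):
            raise ValueError(f"bad degree mode {self.degree_mode!r}")
        if self.degree_mode != "undirected" and self.directed_edges is None:
            raise ValueError("in/out view requires directed edges")

    @property
    def n(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class DegreeSequence:
    """An ordered multiset of node degrees (stored sorted ascending)."""

    degrees: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        d = np.sort(np.asarray(self.degrees, dtype=np.int64))
        if d.size == 0:
            raise ValidationError("empty degree sequence")
        if np.any(d < 0):
            raise ValidationError("degrees must be non-negative")
        object.__setattr__(self, "degrees", d)

    @property
    def n(self) -> int:
        return int(self.degrees.size)

    @property
    def mean_degree(self) -> float:
        return float(self.degrees.mean())


# ---------------------------------------------------------------------------


def _simple_undirected(edges: Iterable[Edge]) -> frozenset:
    out = set()
    for e in edges:
        if e.source != e.target:
            out.add(frozenset((e.source, e.target)))
    return frozenset(out)


def _simple_directed(edges: Iterable[Edge]) -> frozenset:
    return frozenset(
        (e.source, e.target) for e in edges if e.source != e.target
    )


def _edge_groups(dataset: NetworkDataset):
    """Split edges by temporal slice then by layer; yield (edges, provenance, nodes)."""
    groups = [(dataset.edges, "", dataset.nodes)]
    if "temporal" in dataset.flags:
        new = []
        times = sorted({e.timestamp for e in dataset.edges})
        for t in times:
            sub = [e for e in dataset.edges if e.timestamp == t]
            nodes = {e.source for e in sub} | {e.target for e in sub}
            new.append((sub, f"slice t={t}", nodes))
        new.append((dataset.edges, "time-aggregated union", dataset.nodes))
        groups = new
    if "multiplex" in dataset.flags:
        new = []
        for sub, prov, nodes in groups:
            layers = sorted({e.layer for e in sub}, key=repr)
            for lay in layers:
                lsub = [e for e in sub if e.layer == lay]
                lnodes = {e.source for e in lsub} | {e.target for e in lsub}
                new.append((lsub, _join(prov, f"layer {lay}"), lnodes))
            new.append((sub, _join(prov, "layer union"), nodes))
        groups = new
    return groups


def _join(*parts: str) -> str:
    return " / ".join(p for p in parts if p)


def simplify_dataset(dataset: NetworkDataset) -> list[SimpleGraph]:
    """All simple-graph views of a data set under the transformation table.

    The number of outputs is deterministic in the flag set: slices and
    layers each contribute their parts plus a union, a directed data set
    contributes three degree views per group, and a bipartite one two
    class views per view.
    """
    directed = "directed" in dataset.flags
    bipartite = "bipartite" in dataset.flags
    views: list[SimpleGraph] = []
    for sub, prov, nodes in _edge_groups(dataset):
        und = _simple_undirected(sub)
        nodeset = frozenset(nodes)
        base_prov = _join(dataset.identifier, prov)
        if directed:
            dedges = _simple_directed(sub)
            mode_views = [
                ("in", "in-degree view"),
                ("out", "out-degree view"),
                ("undirected", "undirected collapse"),
            ]
            graphs = [
                SimpleGraph(nodeset, und, _join(base_prov, label),
                            degree_mode=mode, directed_edges=dedges)
                for mode, label in mode_views
            ]
        else:
            graphs = [SimpleGraph(nodeset, und, _join(base_prov, "simplified"))]
        if bipartite:
            part = dataset.node_partition
            classes = sorted(set(part.values()), key=repr)
            split = []
            for g in graphs:
                for cls in classes:
                    members = frozenset(v for v in g.nodes if part.get(v) == cls)
                    split.append(SimpleGraph(
                        g.nodes, g.edges,
                        _join(g.provenance, f"class {cls}"),
                        degree_mode=g.degree_mode,
                        directed_edges=g.directed_edges,
                        degree_nodes=members,
                    ))
            graphs = split
        views.extend(graphs)
    return views


def degree_sequence(graph: SimpleGraph, mode: str | None = None) -> DegreeSequence:
    """Extract the degree sequence of one simple-graph view.

    ``mode`` defaults to the view's own ``degree_mode``; in/out modes are
    only valid when the view retains a directed edge set.
    """
    mode = mode or graph.degree_mode
    if graph.n == 0:
        raise ValidationError("empty graph has no degree sequence")
    nodes = sorted(graph.nodes, key=repr)
    deg = dict.fromkeys(nodes, 0)
    if mode == "undirected":
        for e in graph.edges:
            u, v = tuple(e)
            deg[u] += 1
            deg[v] += 1
    else:
        if graph.directed_edges is None:
            raise ValidationError("in/out degrees require a directed origin")
        idx = 1 if mode == "in" else 0
        for pair in graph.directed_edges:
            deg[pair[idx]] += 1
    if graph.degree_nodes is not None:
        values = [deg[v] for v in nodes if v in graph.degree_nodes]
    else:
        values = list(deg.values())
    if not values:
        raise ValidationError("degree view selects no nodes")
    prov = graph.provenance if mode == graph.degree_mode else _join(
        graph.provenance, f"{mode}-degree")
    return DegreeSequence(np.array(values, dtype=np.int64), prov)


def density_filter(seq: DegreeSequence) -> str:
    """Classify a sequence as ``retain``, ``too_sparse`` or ``too_dense``.

    Retained iff ``2 < <k> < sqrt(n)`` with strict inequalities.
    """
    mean = seq.mean_degree
    if mean <= 2.0:
        return "too_sparse"
    if mean >= math.sqrt(seq.n):
        return "too_dense"
    return "retain"
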