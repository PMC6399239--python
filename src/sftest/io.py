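"""Readers and writers for network and degree-sequence files.

Supported inputs: whitespace- or comma-delimited edge lists with optional
``weight``, ``layer`` and ``timestamp`` columns ('#' comments and an
optional header are tolerated); GML via networkx; and raw degree sequences
(one non-negative integer per line).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .simplify import Edge, NetworkDataset, DegreeSequence

__all__ = [
    "read_edge_list",
    "read_gml",
    "read_degree_sequence",
    "write_degree_sequence",
    "read_network",
]

_HEADER_WORDS = {"source", "target", "from", "to", "src", "dst", "weight",
                 "layer", "timestamp", "time"}


def _tokenize(line: str) -> list[str]:
    line = line.strip()
    if "," in line:
        return [t.strip() for t in line.split(",") if t.strip() != ""]
    return line.split()


def _coerce(tok: str):
    try:
        f = float(tok)
    except ValueError:
        return tok
    return int(f) if f.is_integer() else f


def read_edge_list(path, identifier: str | None = None,
                   flags=frozenset(), node_partition=None) -> NetworkDataset:
    """Parse an edge-list file into a :class:`NetworkDataset`.

    Columns: ``source target [weight] [layer] [timestamp]``; the optional
    columns are taken in that order for the declared flags.
    """
    path = Path(path)
    flags = frozenset(flags)
    rows = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = _tokenize(line)
        if rows == [] and any(t.lower() in _HEADER_WORDS for t in toks[:2]):
            continue  # header
        rows.append(toks)
    edges = []
    for toks in rows:
        if len(toks) < 2:
            raise ValueError(f"edge line needs >= 2 columns: {toks}")
        src, dst = _coerce(toks[0]), _coerce(toks[1])
        extra = [_coerce(t) for t in toks[2:]]
        kwargs = {}
        order = [f for f in ("weighted", "multiplex", "temporal") if f in flags]
        names = {"weighted": "weight", "multiplex": "layer", "temporal": "timestamp"}
        for flag, value in zip(order, extra):
            kwargs[names[flag]] = value
        edges.append(Edge(src, dst, **kwargs))
    return NetworkDataset(identifier or path.stem, edges, flags=flags,
                          node_partition=node_partition)


def read_gml(path, identifier: str | None = None, flags=None) -> NetworkDataset:
    """Read a GML file; direction and bipartite structure are taken from the
    file unless ``flags`` overrides them."""
    path = Path(path)
    g = nx.read_gml(path, label="id")
    inferred = set()
    if g.is_directed():
        inferred.add("directed")
    if g.is_multigraph():
        inferred.add("multigraph")
    partition = None
    bip = nx.get_node_attributes(g, "bipartite")
    if bip and len(set(bip.values())) == 2 and len(bip) == g.number_of_nodes():
        inferred.add("bipartite")
        partition = bip
    if flags is not None:
        inferred = set(flags)
    edges = [Edge(u, v) for u, v in g.edges()]
    return NetworkDataset(identifier or path.stem, edges,
                          flags=frozenset(inferred),
                          node_partition=partition,
                          nodes=set(g.nodes()))


def read_degree_sequence(path, provenance: str | None = None) -> DegreeSequence:
    """One non-negative integer per line; '#' comments ignored."""
    path = Path(path)
    values = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        values.append(int(line))
    return DegreeSequence(np.array(values, dtype=np.int64),
                          provenance=provenance or path.stem)


def write_degree_sequence(seq: DegreeSequence, path) -> None:
    Path(path).write_text("\n".join(str(int(k)) for k in seq.degrees) + "\n")


def read_network(path, flags=frozenset(), node_partition=None,
                 identifier=None) -> NetworkDataset:
    """Dispatch on extension: ``.gml`` to the GML reader, else edge list."""
    path = Path(path)
    if path.suffix.lower() == ".gml":
        return read_gml(path, identifier=identifier,
                        flags=flags or None)
    return read_edge_list(path, identifier=identifier, flags=flags,
                          node_partition=node_partition)
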