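"""GraphML serialisation and dataset layout.

Graphs are exchanged as standard GraphML
(http://graphml.graphdrawing.org/): node attribute ``label``; edge
attributes ``weight`` (double, weighted graphs only), ``enzymes`` and
``reactions`` (``;``-joined id lists — GraphML has no native list type);
graph-level attributes ``graph_id``, ``node_kind`` and ``weighted``.

Output is byte-deterministic: UTF-8, LF line endings, nodes and edges
emitted in lexicographic order, attribute keys assigned fixed ids in
encounter order. A write -> read round trip reproduces the in-memory
graph exactly, and rewriting a read graph reproduces the file
byte-for-byte.

:func:`write_dataset` mirrors the repository layout used for cohort
releases: one ``<sample>.graphml`` per graph next to a
``Sample sheet.tsv`` with per-sample metadata.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .exceptions import EmptyGraphError
from .graph_build import validate_structure

__all__ = ["write_graphml", "read_graphml", "write_dataset"]

_HEADER_COMMENT = (
    "<!-- metnet GraphML: edge attributes 'enzymes' and 'reactions' are "
    "';'-joined id lists -->"
)

_GRAPH_KEYS = {"graph_id", "node_kind", "weighted", "source_model"}
_NODE_KEYS = {"label"}
_EDGE_KEYS = {"weight", "enzymes", "reactions"}
_LIST_EDGE_KEYS = ("enzymes", "reactions")


def _canonical_copy(graph: nx.Graph) -> nx.Graph:
    """Rebuild the graph with sorted node/edge insertion and
    GraphML-typed attribute values."""
    out = nx.DiGraph() if graph.is_directed() else nx.Graph()
    for key in sorted(_GRAPH_KEYS & set(graph.graph)):
        out.graph[key] = graph.graph[key]
    weighted = bool(graph.graph.get("weighted", False))
    for node in sorted(graph.nodes):
        out.add_node(node, label=str(graph.nodes[node].get("label", node)))
    edges = graph.edges(data=True)
    for u, v, data in sorted(edges, key=lambda e: (e[0], e[1])):
        attrs: dict = {}
        if weighted:
            attrs["weight"] = float(data.get("weight", 0.0))
        for key in _LIST_EDGE_KEYS:
            attrs[key] = ";".join(data.get(key, ()))
        out.add_edge(u, v, **attrs)
    return out


def write_graphml(graph: nx.Graph, path: str | Path) -> Path:
    """Write a MetGraph to a GraphML file (see module docstring).

    The graph must be structurally clean (no self-loops, duplicate
    edges or isolated nodes); violations raise ``ValueError``.
    """
    violations = validate_structure(graph)
    if violations:
        summary = "; ".join(f"{v.kind}: {v.detail}" for v in violations[:5])
        raise ValueError(f"graph fails structural validation: {summary}")
    out = _canonical_copy(graph)
    lines = list(nx.generate_graphml(out, prettyprint=True))
    text = "\n".join(lines)
    # place the format comment right after the root element opens
    marker = "\n"
    first_break = text.find(marker)
    if first_break != -1:
        text = text[:first_break] + "\n" + _HEADER_COMMENT + text[first_break:]
    path = Path(path)
    path.write_bytes((text + "\n").encode("utf-8"))
    return path


def read_graphml(path: str | Path, expect_directed: bool | None = None) -> nx.Graph:
    """Read a GraphML file back into a MetGraph.

    Files written by other tools are tolerated: unknown attributes are
    dropped with a warning, a missing ``label`` defaults to the node id.
    An empty graph element is an error; a directedness mismatch against
    ``expect_directed`` is a warning and the file is loaded as-is.
    """
    path = Path(path)
    graph = nx.read_graphml(str(path))
    if graph.number_of_nodes() == 0:
        raise EmptyGraphError(f"{path.name}: GraphML file contains no nodes")
    if expect_directed is not None and graph.is_directed() != expect_directed:
        warnings.warn(
            f"{path.name}: expected "
            f"{'directed' if expect_directed else 'undirected'} graph, "
            f"found the opposite; loaded as-is",
            UserWarning,
            stacklevel=2,
        )

    unknown: set[str] = set()
    for key in list(graph.graph):
        if key not in _GRAPH_KEYS:
            if key not in ("node_default", "edge_default"):  # networkx bookkeeping
                unknown.add(key)
            del graph.graph[key]
    graph.graph["weighted"] = bool(graph.graph.get("weighted", False))
    for node, data in graph.nodes(data=True):
        for key in list(data):
            if key not in _NODE_KEYS:
                unknown.add(key)
                del data[key]
        data.setdefault("label", str(node))
    for _, _, data in graph.edges(data=True):
        for key in list(data):
            if key not in _EDGE_KEYS:
                unknown.add(key)
                del data[key]
        for key in _LIST_EDGE_KEYS:
            raw = data.get(key, "")
            data[key] = tuple(part for part in raw.split(";") if part) if raw else ()
        if graph.graph["weighted"]:
            data["weight"] = float(data.get("weight", 0.0))
        else:
            data.pop("weight", None)
    if unknown:
        warnings.warn(
            f"{path.name}: ignored unknown GraphML attributes: "
            f"{', '.join(sorted(unknown))}",
            UserWarning,
            stacklevel=2,
        )
    return graph


def write_dataset(
    graphs: Sequence[nx.Graph],
    metadata: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write one GraphML per graph plus a ``Sample sheet.tsv``.

    ``metadata`` must be indexed by graph id and cover every graph;
    graph-id collisions are an error. Re-running produces identical
    bytes.
    """
    ids = [str(g.graph.get("graph_id", "")) for g in graphs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate graph ids: {dupes}")
    missing = [i for i in ids if i not in metadata.index]
    if missing:
        raise ValueError(f"metadata missing for graphs: {missing[:5]}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for graph, gid in zip(graphs, ids):
        write_graphml(graph, out_dir / f"{gid}.graphml")
    sheet = metadata.loc[ids]
    sheet.to_csv(out_dir / "Sample sheet.tsv", sep="\t", lineterminator="\n")
    return out_dir
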