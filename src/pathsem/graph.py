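"""Typed directed pathway graphs and shortest-path module extraction.

A pathway is represented as a mixed graph: gene nodes joined by typed
directed edges (activation, inhibition, ...) and, optionally, bi-directed
edges that stand for error covariances in the downstream path model.
The central mining operation is :func:`extract_module`, which connects a
set of differentially expressed genes (DEGs) by geodesic (minimum-hop)
directed paths and fuses those paths into a single sub-network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .errors import ParseError

#: Canonical interaction-type vocabulary. Anything else maps to "other".
INTERACTION_TYPES = (
    "activation",
    "inhibition",
    "binding",
    "indirect",
    "phosphorylation",
    "other",
)

_TYPE_ALIASES = {
    "binding/association": "binding",
    "association": "binding",
    "indirect effect": "indirect",
    "expression": "activation",
    "repression": "inhibition",
}


def normalize_interaction(kind: str) -> str:
    """Map a raw interaction label onto the canonical vocabulary."""
    k = kind.strip().lower()
    k = _TYPE_ALIASES.get(k, k)
    return k if k in INTERACTION_TYPES else "other"


class PathwayGraph:
    """A typed directed pathway graph with optional bi-directed edges.

    Node identifiers are opaque strings (Entrez-style IDs in the synthetic
    fixtures).  At most one directed edge per ordered pair is kept; cycles
    and reciprocal edges are permitted.
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()
        self._bidirected: set[frozenset] = set()

    # -- construction -------------------------------------------------
    def add_node(self, name: str) -> None:
        self._g.add_node(str(name))

    def add_edge(self, source: str, target: str, interaction: str = "other") -> bool:
        """Add a typed directed edge; returns False if the pair already exists."""
        source, target = str(source), str(target)
        if self._g.has_edge(source, target):
            return False
        self._g.add_edge(source, target, interaction=normalize_interaction(interaction))
        return True

    def add_bidirected(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError("bi-directed self-pair is not allowed")
        self._bidirected.add(frozenset((str(a), str(b))))

    def copy(self) -> "PathwayGraph":
        out = PathwayGraph()
        out._g = self._g.copy()
        out._bidirected = set(self._bidirected)
        return out

    # -- queries -------------------------------------------------------
    @property
    def nodes(self) -> set:
        return set(self._g.nodes)

    @property
    def directed_edges(self) -> list:
        """Edges as (source, target, interaction) triples in sorted order."""
        return sorted(
            (u, v, d["interaction"]) for u, v, d in self._g.edges(data=True)
        )

    @property
    def bidirected_edges(self) -> list:
        return sorted(tuple(sorted(p)) for p in self._bidirected)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_edge(self, source: str, target: str) -> bool:
        return self._g.has_edge(source, target)

    def interaction(self, source: str, target: str) -> str:
        return self._g.edges[source, target]["interaction"]

    def to_networkx(self) -> nx.DiGraph:
        return self._g.copy()

    def __contains__(self, node) -> bool:
        return node in self._g

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PathwayGraph({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass(frozen=True)
class GraphStats:
    """Size summary of a pathway graph.

    ``mean_degree`` follows the total-degree convention 2*|E|/|V| (in-degree
    plus out-degree averaged over nodes); rounding happens only at display.
    """

    n_nodes: int
    n_edges: int
    mean_degree: float


@dataclass
class ShortestPathModule:
    """The fused shortest-path subgraph G* connecting DEGs.

    ``paths`` holds one geodesic node sequence per connectable ordered DEG
    pair; ``edge_paths`` the corresponding edge triples.  ``skipped_pairs``
    lists ordered DEG pairs with no directed route.
    """

    subgraph: PathwayGraph
    paths: list = field(default_factory=list)
    edge_paths: list = field(default_factory=list)
    connected_degs: set = field(default_factory=set)
    connector_ndegs: set = field(default_factory=set)
    skipped_pairs: list = field(default_factory=list)


def read_pathway_table(path, dialect: str = "tsv3col") -> PathwayGraph:
    """Read a 3-column interaction table (source, interaction, target).

    ``dialect`` is ``"tsv3col"`` (tab-separated) or ``"sif"`` (any
    whitespace).  Lines starting with ``#`` and blank lines are skipped.
    Duplicate (source, target) rows are collapsed with a warning and
    interaction labels outside the vocabulary map to ``"other"``.
    """
    if dialect not in ("tsv3col", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    g = PathwayGraph()
    n_rows = 0
    n_dups = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if dialect == "tsv3col" else line.split()
            if len(fields) != 3:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 3 fields, got {len(fields)}"
                )
            src, kind, dst = (f.strip() for f in fields)
            if not src or not dst:
                raise ParseError(f"{path.name}:{lineno}: empty node identifier")
            n_rows += 1
            if not g.add_edge(src, dst, interaction=kind):
                n_dups += 1
    if n_rows == 0:
        raise ParseError(f"{path.name}: no interaction rows found")
    if n_dups:
        warnings.warn(f"{path.name}: collapsed {n_dups} duplicate edge row(s)")
    return g


def write_pathway_table(g: PathwayGraph, path) -> None:
    """Write the directed edges as a 3-column TSV (source, interaction, target)."""
    with open(path, "w") as fh:
        for u, v, kind in g.directed_edges:
            fh.write(f"{u}\t{kind}\t{v}\n")


def to_dot(
    g: PathwayGraph,
    node_colors: dict | None = None,
    edge_colors: dict | None = None,
) -> str:
    """Render the graph as Graphviz DOT text.

    ``node_colors`` maps node -> color name; ``edge_colors`` maps
    (source, target) -> color name.  Inhibition edges get tee arrowheads.
    """
    node_colors = node_colors or {}
    edge_colors = edge_colors or {}
    lines = ["digraph pathway {", "  node [shape=ellipse, style=filled, fillcolor=white];"]
    for node in sorted(g.nodes):
        color = node_colors.get(node)
        attr = f' [fillcolor="{color}"]' if color else ""
        lines.append(f'  "{node}"{attr};')
    for u, v, kind in g.directed_edges:
        attrs = [f'label="{kind}"']
        if kind == "inhibition":
            attrs.append("arrowhead=tee")
        color = edge_colors.get((u, v))
        if color:
            attrs.append(f'color="{color}"')
        lines.append(f'  "{u}" -> "{v}" [{", ".join(attrs)}];')
    for a, b in g.bidirected_edges:
        lines.append(f'  "{a}" -> "{b}" [dir=both, style=dashed];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def graph_stats(g: PathwayGraph) -> GraphStats:
    """Node/edge counts and total mean degree 2*|E|/|V| of a nonempty graph."""
    if g.n_nodes == 0:
        raise ValueError("cannot summarize an empty graph")
    return GraphStats(g.n_nodes, g.n_edges, 2.0 * g.n_edges / g.n_nodes)


def directed_path_exists(g: PathwayGraph, u: str, v: str) -> bool:
    """True iff a directed path of length >= 1 leads from ``u`` to ``v``."""
    if u not in g or v not in g:
        missing = u if u not in g else v
        raise KeyError(f"unknown node {missing!r}")
    G = g._g
    if u == v:
        return any(nx.has_path(G, w, u) for w in G.successors(u))
    return nx.has_path(G, u, v)


def _lex_min_shortest_path(G: nx.DiGraph, a: str, b: str) -> list | None:
    """One geodesic a->b, the lexicographically smallest among ties."""
    try:
        return min(nx.all_shortest_paths(G, a, b))
    except nx.NetworkXNoPath:
        return None


def extract_module(g: PathwayGraph, degs: Iterable[str]) -> ShortestPathModule:
    """Connect DEGs by geodesic directed paths and fuse them into one module.

    For every ordered pair of distinct DEGs present in the graph, one
    minimum-hop directed path is computed (ties broken lexicographically by
    node ID so the result is reproducible); unreachable pairs are recorded,
    not an error.  The fused subgraph keeps each node and edge once,
    inherits interaction types, drops nothing else: cycles and reciprocal
    edges survive, self-loops cannot occur on a geodesic.
    """
    degs = {str(d) for d in degs}
    present = sorted(degs & g.nodes)
    strays = sorted(degs - g.nodes)
    if strays:
        warnings.warn(f"dropping {len(strays)} DEG(s) absent from the graph: {strays}")
    if len(present) < 2:
        raise ValueError("nothing to connect: fewer than 2 DEGs present in the graph")

    G = g._g
    sub = PathwayGraph()
    paths: list[tuple] = []
    edge_paths: list[tuple] = []
    connected: set = set()
    skipped: list[tuple] = []
    for a in present:
        for b in present:
            if a == b:
                continue
            path = _lex_min_shortest_path(G, a, b)
            if path is None:
                skipped.append((a, b))
                continue
            paths.append(tuple(path))
            triples = tuple(
                (u, v, g.interaction(u, v)) for u, v in zip(path[:-1], path[1:])
            )
            edge_paths.append(triples)
            connected.update((a, b))
            for node in path:
                sub.add_node(node)
            for u, v, kind in triples:
                if u != v:
                    sub.add_edge(u, v, interaction=kind)
    connectors = sub.nodes - degs
    return ShortestPathModule(
        subgraph=sub,
        paths=paths,
        edge_paths=edge_paths,
        connected_degs=connected,
        connector_ndegs=connectors,
        skipped_pairs=skipped,
    )
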