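"""Protein-interaction network container and operations.

Reads STRING protein-links flat files, validates the simple-graph
invariants, restricts a network to a gene universe shared with expression
data, and randomizes edges while exactly preserving vertex degrees
(repeated double-edge swaps with rejection).
"""

from __future__ import annotations

from collections.abc import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "NetworkError",
    "InteractionNetwork",
    "read_string_links",
    "write_string_links",
    "rewire_preserving_degrees",
    "restrict_to_common_genes",
]


class NetworkError(ValueError):
    """Raised for malformed network files or invalid network operations."""


class InteractionNetwork:
    """Undirected simple graph over opaque gene identifiers.

    Thin wrapper around :class:`networkx.Graph` enforcing the invariants the
    scoring model relies on: no self-loops, unique undirected edges, and a
    consistent degree map (``sum(k) == 2 * M``).  Edges may carry an integer
    confidence ``score`` attribute in [0, 999].

    Parameters
    ----------
    graph
        An undirected networkx graph.  A defensive copy is *not* made; do not
        mutate the graph after wrapping.
    """

    def __init__(self, graph: nx.Graph):
        if graph.is_directed() or graph.is_multigraph():
            raise NetworkError("expected an undirected simple graph")
        loops = list(nx.selfloop_edges(graph))
        if loops:
            raise NetworkError(f"self-loops are not allowed: {loops[:5]}")
        self._graph = graph
        self._vertices = tuple(sorted(graph.nodes))

    # -- basic accessors -------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def vertices(self) -> tuple[str, ...]:
        """All vertex identifiers, sorted ascending."""
        return self._vertices

    @property
    def n_vertices(self) -> int:
        return len(self._vertices)

    @property
    def m(self) -> int:
        """Total number of interactions M in the network."""
        return self._graph.number_of_edges()

    def degree(self, vertex: str) -> int:
        return self._graph.degree(vertex)

    def degrees(self) -> dict[str, int]:
        return dict(self._graph.degree())

    def neighbors(self, vertex: str) -> list[str]:
        return sorted(self._graph.neighbors(vertex))

    def has_edge(self, u: str, v: str) -> bool:
        return self._graph.has_edge(u, v)

    def edge_set(self) -> set[tuple[str, str]]:
        """Edges as canonically ordered (min, max) identifier pairs."""
        return {(u, v) if u <= v else (v, u) for u, v in self._graph.edges}

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return (
            set(self._vertices) == set(other._vertices)
            and self.edge_set() == other.edge_set()
        )

    def __hash__(self):  # edge sets are mutable views; identity hash
        return id(self)

    def __repr__(self) -> str:
        return f"InteractionNetwork(n={self.n_vertices}, M={self.m})"

    # -- construction ----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        vertices: Iterable[str] = (),
        scores: dict[tuple[str, str], int] | None = None,
    ) -> "InteractionNetwork":
        """Build a network from an edge list, plus optional isolated vertices."""
        g = nx.Graph()
        g.add_nodes_from(vertices)
        for u, v in edges:
            if u == v:
                raise NetworkError(f"self-loop edge ({u!r}, {u!r})")
            g.add_edge(u, v)
        if scores:
            for (u, v), s in scores.items():
                if g.has_edge(u, v):
                    g[u][v]["score"] = int(s)
        return cls(g)


def read_string_links(path, min_confidence: float = 0.7) -> InteractionNetwork:
    """Read a STRING protein-links flat file, filtered by confidence.

    The file is whitespace-delimited with a header line containing the
    columns ``protein1 protein2 combined_score`` (combined_score an integer
    in [0, 999]).  STRING lists each interaction twice (once per direction);
    symmetric duplicates are collapsed to one undirected edge, resolving any
    score conflict to the maximum.  Self-loops are dropped silently.

    Parameters
    ----------
    path
        Path of the links file.
    min_confidence
        Confidence threshold on [0, 1]; edges with
        ``combined_score >= round(1000 * min_confidence)`` are retained.
        The conventional STRING "high confidence" cutoff is 0.7 (score 700).

    Raises
    ------
    NetworkError
        On malformed lines (naming the line number) or when no edge survives
        the confidence filter.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence must be in [0, 1], got {min_confidence}")
    threshold = round(1000 * min_confidence)

    best: dict[tuple[str, str], int] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().split()
        required = ("protein1", "protein2", "combined_score")
        try:
            cols = [header.index(name) for name in required]
        except ValueError:
            raise NetworkError(
                f"line 1: header must contain columns {required}, got {header}"
            ) from None
        ncols = len(header)
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != ncols:
                raise NetworkError(
                    f"line {lineno}: expected {ncols} fields, got {len(parts)}"
                )
            u, v, raw = (parts[c] for c in cols)
            try:
                score = int(raw)
            except ValueError:
                raise NetworkError(
                    f"line {lineno}: combined_score {raw!r} is not an integer"
                ) from None
            if not 0 <= score <= 999:
                raise NetworkError(
                    f"line {lineno}: combined_score {score} outside [0, 999]"
                )
            if u == v:
                continue  # self-loop, dropped
            key = (u, v) if u <= v else (v, u)
            prev = best.get(key)
            if prev is None or score > prev:
                best[key] = score

    kept = {e: s for e, s in best.items() if s >= threshold}
    if not kept:
        raise NetworkError(
            f"empty network: no edge has combined_score >= {threshold}"
        )
    return InteractionNetwork.from_edges(kept, scores=kept)


def write_string_links(network: InteractionNetwork, path, default_score: int = 999) -> None:
    """Write a network in STRING protein-links format (one row per edge)."""
    g = network.graph
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for u, v in sorted(network.edge_set()):
            score = g[u][v].get("score", default_score)
            fh.write(f"{u} {v} {score}\n")


def rewire_preserving_degrees(
    network: InteractionNetwork, n_swaps: int | None = None, seed: int = 0
) -> InteractionNetwork:
    """Randomize edges with attempted double-edge swaps, preserving degrees.

    Each attempt draws two distinct edges (u, v), (x, y) and proposes the
    rewiring (u, x), (v, y) after a random orientation flip of the second
    edge; the attempt is rejected if it would create a self-loop or a
    duplicate edge.  The vertex set and the degree of every vertex are
    preserved exactly.  Edge confidence scores are dropped (they are not
    meaningful after rewiring).

    Parameters
    ----------
    n_swaps
        Number of attempted swaps; defaults to ``10 * M``, a standard mixing
        heuristic.
    seed
        Seed for the pseudo-random generator; output is deterministic given
        the seed.
    """
    m = network.m
    if m < 2:
        raise NetworkError("rewiring requires a network with at least 2 edges")
    if n_swaps is None:
        n_swaps = 10 * m
    if n_swaps <= 0:
        raise ValueError(f"n_swaps must be positive, got {n_swaps}")

    rng = np.random.default_rng(seed)
    edges = [list(e) for e in sorted(network.edge_set())]
    edge_set = {tuple(e) for e in network.edge_set()}

    def _key(a, b):
        return (a, b) if a <= b else (b, a)

    for _ in range(n_swaps):
        a, b = rng.integers(0, m, size=2)
        if a == b:
            continue
        u, v = edges[a]
        x, y = edges[b]
        if rng.random() < 0.5:
            x, y = y, x
        # proposed new edges: (u, x) and (v, y)
        if u == x or v == y:
            continue  # self-loop
        new1, new2 = _key(u, x), _key(v, y)
        if new1 == new2 or new1 in edge_set or new2 in edge_set:
            continue  # duplicate edge
        edge_set.discard(_key(u, v))
        edge_set.discard(_key(x, y))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[a] = list(new1)
        edges[b] = list(new2)

    return InteractionNetwork.from_edges(edge_set, vertices=network.vertices)


def restrict_to_common_genes(
    network: InteractionNetwork, gene_ids: Iterable[str]
) -> InteractionNetwork:
    """Induced subgraph on the intersection of network vertices and ``gene_ids``.

    Vertices in the intersection are kept even if all their edges are lost
    (degree-0 vertices remain part of the gene universe so that network and
    expression scores rank the same genes).

    Raises
    ------
    NetworkError
        If the intersection is empty.
    """
    common = set(network.vertices) & set(gene_ids)
    if not common:
        raise NetworkError(
            "empty intersection between network vertices and the given gene set"
        )
    sub = network.graph.subgraph(common).copy()
    return InteractionNetwork(sub)
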