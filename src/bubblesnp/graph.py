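"""Two-colour De Bruijn graph: construction, cleaning, undirected transform.

The directed coloured graph (:class:`ColouredGraph`) keeps one vertex per
canonical k-mer with per-colour coverage and one edge per canonical
(k+1)-mer with per-colour observation counts. Cleaning removes vertices of
low summed coverage and short dead-end tips. For bubble search the graph is
transformed to an undirected labelled graph (:class:`UndirectedBubbleGraph`)
whose edges carry the appended base for each traversal direction and a
colour in {colour0, colour1, mixed}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

from .kmers import N_COLOURS, canonical, complement_base, reverse_complement

COLOUR_NAMES = ("colour0", "colour1")
MIXED = "mixed"


class GraphError(ValueError):
    """Inconsistent graph construction input (e.g. mismatched k)."""


@dataclass(frozen=True)
class CleaningConfig:
    """Graph cleaning parameters.

    min_vertex_coverage: vertices whose coverage (summed over colours by
        default) is at or below this value are removed, with their edges.
    min_tip_length_nt: dead-end tips shorter than this many nucleotides
        (path vertices + k - 1) are clipped.
    per_colour: apply the coverage rule to each colour separately (a vertex
        survives only if some single colour exceeds the threshold).
    """

    min_vertex_coverage: int = 2
    min_tip_length_nt: int = 100
    per_colour: bool = False

    def __post_init__(self) -> None:
        if self.min_vertex_coverage < 0 or self.min_tip_length_nt < 0:
            raise ValueError("cleaning thresholds must be non-negative")


@dataclass
class ColouredGraph:
    """Directed canonical-k-mer graph with per-colour vertex/edge counts."""

    k: int
    vertices: dict[str, tuple[int, ...]] = field(default_factory=dict)
    edges: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def edge_endpoints(self, kmer1: str) -> tuple[str, str]:
        """Canonical endpoint k-mers of a (k+1)-mer edge."""
        return canonical(kmer1[:-1]), canonical(kmer1[1:])

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_graph(counts) -> ColouredGraph:
    """Assemble the coloured graph from :func:`bubblesnp.kmers.count_kmers` output."""
    k = counts.k
    graph = ColouredGraph(k=k)
    for kmer, cov in counts.vertex_counts.items():
        if len(kmer) != k:
            raise GraphError(f"vertex {kmer!r} does not match k={k}")
        graph.vertices[kmer] = tuple(cov)
    for edge, cov in counts.edge_counts.items():
        if len(edge) != k + 1:
            raise GraphError(f"edge {edge!r} does not match k+1={k + 1}")
        u, v = graph.edge_endpoints(edge)
        if u not in graph.vertices or v not in graph.vertices:
            raise GraphError(f"edge {edge!r} references missing vertex")
        graph.edges[edge] = tuple(cov)
    return graph


# ---------------------------------------------------------------------------
# degree bookkeeping shared by the directed and undirected representations
# ---------------------------------------------------------------------------


def side_out_degrees(vertex: str, incident_edge_kmers) -> tuple[int, int]:
    """Out-degrees of a canonical vertex in its two orientations.

    An edge (k+1)-mer x departs the vertex's forward orientation when the
    vertex reads as the prefix of x or of reverse_complement(x); it departs
    the reverse orientation when the vertex reads as the suffix of either.
    """
    fwd = rev = 0
    for x in incident_edge_kmers:
        pre, suf = x[:-1], x[1:]
        if vertex == pre:
            fwd += 1
        if vertex == reverse_complement(suf):
            fwd += 1
        if vertex == suf:
            rev += 1
        if vertex == reverse_complement(pre):
            rev += 1
    return fwd, rev


def is_branching_degrees(fwd: int, rev: int) -> bool:
    """Branching rule: at least two edges depart in some orientation."""
    return fwd >= 2 or rev >= 2


def _adjacency(edges) -> dict[str, list[tuple[str, str]]]:
    adj: dict[str, list[tuple[str, str]]] = {}
    for x in edges:
        u, v = canonical(x[:-1]), canonical(x[1:])
        adj.setdefault(u, []).append((v, x))
        if v != u:
            adj.setdefault(v, []).append((u, x))
    return adj


def _tip_vertices(vertices, adjacency, branching: set[str], k: int, min_len_nt: int) -> set[str]:
    """Vertices on dead-end tips shorter than ``min_len_nt`` nucleotides.

    A tip is a maximal unbranched path that starts at a degree-1 dead end and
    ends against a branching vertex (the anchor, which is never removed). A
    linear component that never meets a branching vertex is not a tip.
    """
    to_remove: set[str] = set()
    visited: set[str] = set()
    for start in vertices:
        edges_here = adjacency.get(start, [])
        if len(edges_here) != 1 or start in branching or start in visited:
            continue
        path = [start]
        prev = start
        cur = edges_here[0][0]
        is_tip = False
        while True:
            if cur in branching:
                is_tip = True
                break
            nbrs = [n for n, _ in adjacency.get(cur, [])]
            # unbranched continuation: exactly two incident edges
            if len(nbrs) != 2:
                break  # another dead end: isolated linear component
            path.append(cur)
            nxt = nbrs[0] if nbrs[0] != prev else nbrs[1]
            if nxt in path:
                break  # cycle back into the path; not a tip
            prev, cur = cur, nxt
        visited.update(path)
        if is_tip and len(path) + k - 1 < min_len_nt:
            to_remove.update(path)
    return to_remove


def _drop_vertices(graph: ColouredGraph, removed: set[str]) -> ColouredGraph:
    if not removed:
        return replace(
            graph, vertices=dict(graph.vertices), edges=dict(graph.edges)
        )
    vertices = {v: c for v, c in graph.vertices.items() if v not in removed}
    edges = {}
    for x, c in graph.edges.items():
        u, v = graph.edge_endpoints(x)
        if u in vertices and v in vertices:
            edges[x] = c
    return replace(graph, vertices=vertices, edges=edges)


def remove_low_coverage(graph: ColouredGraph, cfg: CleaningConfig) -> ColouredGraph:
    """Remove every vertex whose coverage is at or below the threshold.

    By default coverage is summed over both colours; with ``cfg.per_colour``
    a vertex is removed when no single colour exceeds the threshold.
    """
    thr = cfg.min_vertex_coverage
    if cfg.per_colour:
        removed = {v for v, c in graph.vertices.items() if max(c) <= thr}
    else:
        removed = {v for v, c in graph.vertices.items() if sum(c) <= thr}
    return _drop_vertices(graph, removed)


def clip_tips(graph: ColouredGraph, cfg: CleaningConfig) -> ColouredGraph:
    """Clip dead-end tips shorter than ``cfg.min_tip_length_nt`` nucleotides."""
    adj = _adjacency(graph.edges)
    incident: dict[str, list[str]] = {v: [] for v in graph.vertices}
    for x in graph.edges:
        u, v = graph.edge_endpoints(x)
        incident[u].append(x)
        if v != u:
            incident[v].append(x)
    branching = {
        v for v in graph.vertices if is_branching_degrees(*side_out_degrees(v, incident[v]))
    }
    removed = _tip_vertices(graph.vertices, adj, branching, graph.k, cfg.min_tip_length_nt)
    return _drop_vertices(graph, removed)


def clean_graph(graph: ColouredGraph, cfg: CleaningConfig) -> ColouredGraph:
    """Single cleaning pass: low-coverage removal, then tip clipping."""
    return clip_tips(remove_low_coverage(graph, cfg), cfg)


# ---------------------------------------------------------------------------
# undirected labelled graph
# ---------------------------------------------------------------------------


class UndirectedBubbleGraph:
    """Undirected transform of the coloured graph, as searched for bubbles.

    Wraps a :class:`networkx.MultiGraph`. Nodes carry ``cov`` (per-colour
    coverage tuple); each edge is keyed by its canonical (k+1)-mer and
    carries the ordered endpoints ``u``/``v`` (canonical prefix/suffix
    k-mers), the base appended in each traversal direction and a colour.
    """

    def __init__(self, k: int, g: nx.MultiGraph | None = None) -> None:
        self.k = k
        self.g = g if g is not None else nx.MultiGraph()

    # -- basic accessors ----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def vertices(self) -> list[str]:
        return sorted(self.g.nodes)

    def coverage(self, v: str) -> tuple[int, ...]:
        return self.g.nodes[v]["cov"]

    def has_vertex(self, v: str) -> bool:
        return v in self.g

    def edge_records(self) -> list[dict]:
        """All edge attribute dicts, sorted by (u, v, key)."""
        recs = [d for _, _, d in self.g.edges(data=True)]
        recs.sort(key=lambda d: (d["u"], d["v"], d["kmer"]))
        return recs

    def neighbours(self, v: str) -> list[tuple[str, str]]:
        """Sorted (neighbour, edge-key) pairs incident to ``v``."""
        out = []
        for nbr, keydict in self.g.adj[v].items():
            for key in keydict:
                out.append((nbr, key))
        out.sort()
        return out

    def colour(self, a: str, b: str, key: str) -> str:
        return self.g.edges[a, b, key]["colour"]

    def traversal_label(self, a: str, b: str, key: str) -> str:
        """Base appended when traversing the edge ``key`` from ``a`` to ``b``."""
        d = self.g.edges[a, b, key]
        if a == d["u"] and b == d["v"]:
            return d["label_fwd"]
        if a == d["v"] and b == d["u"]:
            return d["label_bwd"]
        raise GraphError(f"ambiguous traversal of self-loop edge {key!r}")

    # -- branching ----------------------------------------------------------

    def side_out_degrees(self, v: str) -> tuple[int, int]:
        keys = [key for _, keydict in self.g.adj[v].items() for key in keydict]
        return side_out_degrees(v, keys)

    def is_branching(self, v: str) -> bool:
        return is_branching_degrees(*self.side_out_degrees(v))

    def branching_vertices(self) -> list[str]:
        """All branching vertices in deterministic (lexicographic) order."""
        return [v for v in self.vertices() if self.is_branching(v)]

    # -- derived views ------------------------------------------------------

    def induced(self, nodes) -> "UndirectedBubbleGraph":
        """Frozen copy of the sub-graph induced by ``nodes``."""
        return UndirectedBubbleGraph(self.k, nx.MultiGraph(self.g.subgraph(nodes)))

    def __eq__(self, other) -> bool:
        if not isinstance(other, UndirectedBubbleGraph):
            return NotImplemented
        if self.k != other.k:
            return False
        nodes_a = {v: self.g.nodes[v]["cov"] for v in self.g.nodes}
        nodes_b = {v: other.g.nodes[v]["cov"] for v in other.g.nodes}
        if nodes_a != nodes_b:
            return False

        def edge_map(ug):
            return {
                d["kmer"]: (d["u"], d["v"], d["label_fwd"], d["label_bwd"], d["colour"])
                for _, _, d in ug.g.edges(data=True)
            }

        return edge_map(self) == edge_map(other)

    def __repr__(self) -> str:
        return (
            f"UndirectedBubbleGraph(k={self.k}, vertices={self.n_vertices}, "
            f"edges={self.n_edges})"
        )


def edge_colour(counts: tuple[int, ...]) -> str:
    if counts[0] > 0 and counts[1] > 0:
        return MIXED
    return COLOUR_NAMES[0] if counts[0] > 0 else COLOUR_NAMES[1]


def to_undirected(graph: ColouredGraph) -> UndirectedBubbleGraph:
    """Transform the coloured graph to the undirected labelled search graph.

    Each (k+1)-mer edge x becomes one undirected edge whose forward label is
    the last base of x and whose backward label is the complement of its
    first base; the colour records which read sets observed x.
    """
    ug = UndirectedBubbleGraph(graph.k)
    for v in sorted(graph.vertices):
        ug.g.add_node(v, cov=graph.vertices[v])
    for x in sorted(graph.edges):
        u, v = graph.edge_endpoints(x)
        ug.g.add_edge(
            u,
            v,
            key=x,
            kmer=x,
            u=u,
            v=v,
            label_fwd=x[-1],
            label_bwd=complement_base(x[0]),
            colour=edge_colour(graph.edges[x]),
        )
    return ug


def clean_undirected(ug: UndirectedBubbleGraph, cfg: CleaningConfig) -> UndirectedBubbleGraph:
    """Apply both cleaning rules directly to an undirected graph.

    Used when only the serialized undirected dialect is available (it keeps
    vertex coverages but not per-colour edge counts); the rules themselves
    are identical to the coloured-graph pass.
    """
    thr = cfg.min_vertex_coverage
    if cfg.per_colour:
        keep = [v for v in ug.g.nodes if max(ug.coverage(v)) > thr]
    else:
        keep = [v for v in ug.g.nodes if sum(ug.coverage(v)) > thr]
    out = ug.induced(keep)
    adj = {v: out.neighbours(v) for v in out.g.nodes}
    branching = set(out.branching_vertices())
    removed = _tip_vertices(sorted(out.g.nodes), adj, branching, ug.k, cfg.min_tip_length_nt)
    return out.induced([v for v in out.g.nodes if v not in removed])
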