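"""Bubble search: 2k+2 cycle enumeration and allele-contig extraction.

A SNP between two samples appears in the undirected two-colour graph as a
cycle of exactly 2k+2 edges whose two branches connect the same pair of
branching vertices by k+1 edges each ("equidistant"), with one branch per
colour. Walking each branch and collecting the appended edge labels yields
two nucleotide contigs of length k+1 that differ in their first base only:
the two alleles of the SNP.

The search mirrors the published procedure: branching vertices are visited
in seeded random order, a bounded sub-graph is grown around each seed by
breadth-first expansion, and bubbles are enumerated inside the sub-graph by
depth-(k+1) path enumeration from its branching vertices.
"""

from __future__ import annotations

import logging
import random
import time
import warnings
from dataclasses import dataclass
from itertools import combinations

from .graph import COLOUR_NAMES, MIXED, UndirectedBubbleGraph

logger = logging.getLogger(__name__)


class UsageError(ValueError):
    """Invalid arguments to a search operation."""


@dataclass(frozen=True)
class SearchConfig:
    """Bubble search parameters.

    max_subgraphs: maximum number of sub-graphs to create (the T of the
        search loop; large runs in the original study used up to 200 000).
    max_subgraph_size: vertex cap on each breadth-first sub-graph.
    time_limit_s: optional wall-clock limit; exceeding it ends the search
        normally with a logged termination reason.
    rng_seed: seed for the shuffle of the branching-vertex list.
    strict_colours: forbid mixed edges on bubble branches.
    emit_mixed_contig: also emit the label string of the mixed edges of each
        bubble (a third, variable-length contig).
    """

    max_subgraphs: int = 200_000
    max_subgraph_size: int = 100
    time_limit_s: float | None = None
    rng_seed: int = 0
    strict_colours: bool = False
    emit_mixed_contig: bool = False

    def __post_init__(self) -> None:
        if self.max_subgraphs < 1:
            raise UsageError("max_subgraphs must be >= 1")
        if self.max_subgraph_size < 2:
            raise UsageError("max_subgraph_size must be >= 2")
        if self.time_limit_s is not None and self.time_limit_s <= 0:
            raise UsageError("time_limit_s must be positive")


@dataclass(frozen=True)
class Branch:
    """One side of a bubble: a path of k+2 vertices / k+1 edges, one colour."""

    path: tuple[str, ...]
    edge_keys: tuple[str, ...]
    colour: int
    edge_colours: tuple[str, ...] = ()

    @property
    def internal(self) -> tuple[str, ...]:
        return self.path[1:-1]


@dataclass(frozen=True)
class BubbleCycle:
    """A 2k+2 cycle with equidistant branching endpoints, one branch per colour.

    Both branch paths are oriented from the lexicographically smaller
    endpoint to the larger; branches are ordered colour0 first.
    """

    k: int
    branches: tuple[Branch, Branch]

    @property
    def endpoints(self) -> tuple[str, str]:
        return self.branches[0].path[0], self.branches[0].path[-1]

    @property
    def key(self):
        """Deduplication key: unordered endpoints + unordered internal tuples."""
        return (self.endpoints, frozenset(b.internal for b in self.branches))

    @property
    def cycle_vertices(self) -> tuple[str, ...]:
        return self.endpoints + self.branches[0].internal + self.branches[1].internal

    @property
    def n_mixed_edges(self) -> int:
        return sum(1 for b in self.branches for c in b.edge_colours if c == MIXED)

    # filled in by the predicate so callers can count without a graph handle
    @property
    def edge_count(self) -> int:
        return sum(len(b.edge_keys) for b in self.branches)


@dataclass(frozen=True)
class AlleleContig:
    """A k+1 nucleotide sequence walked off one colour's branch of a bubble."""

    bubble_id: str | None
    colour: int
    sequence: str


@dataclass
class SubGraph:
    """Bounded breadth-first neighbourhood of a branching seed vertex."""

    seed: str
    graph: UndirectedBubbleGraph

    @property
    def n_vertices(self) -> int:
        return self.graph.n_vertices

    def branching_count(self) -> int:
        return len(self.graph.branching_vertices())


def branching_vertices(graph: UndirectedBubbleGraph) -> list[str]:
    """All branching vertices, in deterministic lexicographic order."""
    return graph.branching_vertices()


def build_subgraph(graph: UndirectedBubbleGraph, seed: str, cfg: SearchConfig) -> SubGraph:
    """Grow a sub-graph from ``seed`` by BFS in sorted neighbour order."""
    if not graph.has_vertex(seed) or not graph.is_branching(seed):
        raise UsageError(f"seed {seed!r} is not a branching vertex")
    cap = cfg.max_subgraph_size
    order = [seed]
    seen = {seed}
    queue = [seed]
    qi = 0
    while qi < len(queue) and len(order) < cap:
        v = queue[qi]
        qi += 1
        for nbr, _ in graph.neighbours(v):
            if nbr not in seen:
                seen.add(nbr)
                order.append(nbr)
                queue.append(nbr)
                if len(order) >= cap:
                    break
    return SubGraph(seed=seed, graph=graph.induced(order))


def _branch_colour(colours, strict: bool) -> int | None:
    """Colour index a branch's edge colours are compatible with, or None.

    Default rule: every edge is the branch colour or mixed, and at least one
    edge is strictly the branch colour. Strict rule: every edge is strictly
    the branch colour.
    """
    for i, name in enumerate(COLOUR_NAMES):
        if strict:
            if all(c == name for c in colours):
                return i
        else:
            if all(c in (name, MIXED) for c in colours) and any(c == name for c in colours):
                return i
    return None


def _walk_labels(graph: UndirectedBubbleGraph, path, keys) -> str:
    return "".join(
        graph.traversal_label(path[i], path[i + 1], keys[i]) for i in range(len(keys))
    )


def make_bubble(
    graph: UndirectedBubbleGraph,
    path_a: tuple[tuple[str, ...], tuple[str, ...]],
    path_b: tuple[tuple[str, ...], tuple[str, ...]],
    strict: bool = False,
    _branching: set[str] | None = None,
) -> BubbleCycle | None:
    """The bubble predicate: validate a candidate pair of k+1-edge paths.

    Both the sub-graph search and the brute-force cycle oracle funnel
    candidates through this single function. Checks, in order: path lengths
    (k+1 edges each), shared distinct branching endpoints, disjoint internal
    vertex sets, one distinct compatible colour per branch, and the allele
    contract (the two walked contigs have length k+1 and differ exactly at
    their first base).
    """
    k = graph.k
    (va, ka), (vb, kb) = path_a, path_b
    if len(ka) != k + 1 or len(kb) != k + 1:
        return None
    ends_a, ends_b = {va[0], va[-1]}, {vb[0], vb[-1]}
    if ends_a != ends_b or len(ends_a) != 2:
        return None
    if _branching is None:
        if not (graph.is_branching(va[0]) and graph.is_branching(va[-1])):
            return None
    elif not ends_a <= _branching:
        return None
    ia, ib = set(va[1:-1]), set(vb[1:-1])
    if ia & ib or ends_a & (ia | ib):
        return None
    # orient both paths from the smaller endpoint
    lo = min(ends_a)
    if va[0] != lo:
        va, ka = va[::-1], ka[::-1]
    if vb[0] != lo:
        vb, kb = vb[::-1], kb[::-1]
    cols_a = [graph.colour(va[i], va[i + 1], ka[i]) for i in range(len(ka))]
    cols_b = [graph.colour(vb[i], vb[i + 1], kb[i]) for i in range(len(kb))]
    ca, cb = _branch_colour(cols_a, strict), _branch_colour(cols_b, strict)
    if ca is None or cb is None or ca == cb:
        return None
    branches = [
        Branch(tuple(va), tuple(ka), ca, tuple(cols_a)),
        Branch(tuple(vb), tuple(kb), cb, tuple(cols_b)),
    ]
    branches.sort(key=lambda b: b.colour)
    bubble = BubbleCycle(k=k, branches=(branches[0], branches[1]))
    # allele contract: contigs of length k+1 differing at position 1 only
    c0, c1 = (c.sequence for c in extract_contigs(bubble, graph))
    if len(c0) != k + 1 or len(c1) != k + 1:
        return None
    if c0[0] == c1[0] or c0[1:] != c1[1:]:
        return None
    return bubble


def extract_contigs(
    bubble: BubbleCycle,
    graph: UndirectedBubbleGraph,
    start: str | None = None,
    emit_mixed: bool = False,
) -> tuple[AlleleContig, ...]:
    """Walk both branches of a bubble, collecting the appended edge labels.

    The walk direction is chosen so the colour0 contig is lexicographically
    smallest (the bubble is reachable from either endpoint, in either
    orientation, encoding the same SNP); pass ``start`` to force an endpoint.
    With ``emit_mixed`` a third contig collects the labels of mixed edges.
    """
    b0, b1 = bubble.branches
    lo, hi = bubble.endpoints

    def walk(branch: Branch, reverse: bool) -> str:
        path, keys = branch.path, branch.edge_keys
        if reverse:
            path, keys = path[::-1], keys[::-1]
        return _walk_labels(graph, path, keys)

    if start is not None:
        if start not in (lo, hi):
            raise UsageError(f"{start!r} is not an endpoint of the bubble")
        reverse = start == hi
    else:
        reverse = walk(b0, True) < walk(b0, False)
    contigs = [
        AlleleContig(bubble_id=None, colour=b0.colour, sequence=walk(b0, reverse)),
        AlleleContig(bubble_id=None, colour=b1.colour, sequence=walk(b1, reverse)),
    ]
    contigs.sort(key=lambda c: c.colour)
    if emit_mixed:
        mixed = "".join(
            lab
            for branch in (b0, b1)
            for lab, col in zip(walk(branch, reverse), _edge_colours(branch, reverse))
            if col == MIXED
        )
        contigs.append(AlleleContig(bubble_id=None, colour=-1, sequence=mixed))
    return tuple(contigs)


def _edge_colours(branch: Branch, reverse: bool):
    return branch.edge_colours[::-1] if reverse else branch.edge_colours


def _simple_paths(graph: UndirectedBubbleGraph, start: str, depth: int):
    """All simple paths of exactly ``depth`` edges from ``start``."""
    results: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    path = [start]
    keys: list[str] = []
    on_path = {start}

    def rec(v: str) -> None:
        if len(keys) == depth:
            results.append((tuple(path), tuple(keys)))
            return
        for nbr, key in graph.neighbours(v):
            if nbr in on_path:
                continue
            path.append(nbr)
            keys.append(key)
            on_path.add(nbr)
            rec(nbr)
            on_path.remove(nbr)
            path.pop()
            keys.pop()

    rec(start)
    return results


def find_bubbles(sub, k: int | None = None, strict: bool = False) -> list[BubbleCycle]:
    """Enumerate every bubble whose cycle lies within the given (sub-)graph.

    Accepts a :class:`SubGraph` or an :class:`UndirectedBubbleGraph`. Paths
    of exactly k+1 edges are enumerated from each branching vertex; paths
    meeting at a common branching endpoint are paired and validated by
    :func:`make_bubble`, with deduplication by endpoint pair and unordered
    internal-vertex tuples.
    """
    graph = sub.graph if isinstance(sub, SubGraph) else sub
    if k is not None and k != graph.k:
        raise UsageError(f"k={k} does not match graph k={graph.k}")
    k = graph.k
    branching = graph.branching_vertices()
    bset = set(branching)
    by_pair: dict[tuple[str, str], set] = {}
    for b in branching:
        for verts, keys in _simple_paths(graph, b, k + 1):
            w = verts[-1]
            if w in bset and w > b:
                by_pair.setdefault((b, w), set()).add((verts, keys))
    found: dict = {}
    for pair in sorted(by_pair):
        paths = sorted(by_pair[pair])
        for pa, pb in combinations(paths, 2):
            bubble = make_bubble(graph, pa, pb, strict=strict, _branching=bset)
            if bubble is not None and bubble.key not in found:
                found[bubble.key] = bubble
    return sorted(found.values(), key=lambda b: b.key[0] + tuple(sorted(b.key[1])))


@dataclass
class SearchResult:
    """Outcome of a full graph search."""

    bubbles: list[BubbleCycle]
    hosts: dict  # bubble key -> SubGraph in which it was first found
    n_subgraphs: int
    termination: str  # max_subgraphs | seeds_exhausted | time_limit

    def records(self, graph: UndirectedBubbleGraph, emit_mixed: bool = False):
        """(bubble_id, bubble, contigs, host sub-graph) in deterministic order."""
        out = []
        for i, bubble in enumerate(self.bubbles):
            bubble_id = f"b{i:05d}"
            contigs = tuple(
                AlleleContig(bubble_id, c.colour, c.sequence)
                for c in extract_contigs(bubble, graph, emit_mixed=emit_mixed)
            )
            out.append((bubble_id, bubble, contigs, self.hosts[bubble.key]))
        return out


def search(graph: UndirectedBubbleGraph, cfg: SearchConfig) -> SearchResult:
    """Run the full bubble search over a graph.

    Branching vertices are shuffled with ``cfg.rng_seed`` and processed
    until ``max_subgraphs`` sub-graphs have been searched, seeds are
    exhausted, or the time limit expires. Output is deduplicated across
    sub-graphs and deterministic for a fixed seed (absent a time limit).
    """
    if cfg.max_subgraph_size < 2 * graph.k + 2:
        warnings.warn(
            f"max_subgraph_size={cfg.max_subgraph_size} is below 2k+2={2 * graph.k + 2}; "
            "bubbles cannot fit in a sub-graph",
            stacklevel=2,
        )
    seeds = graph.branching_vertices()
    rng = random.Random(cfg.rng_seed)
    rng.shuffle(seeds)
    t0 = time.monotonic()
    found: dict = {}
    hosts: dict = {}
    n_sub = 0
    termination = "seeds_exhausted"
    for seed in seeds:
        if n_sub >= cfg.max_subgraphs:
            termination = "max_subgraphs"
            break
        if cfg.time_limit_s is not None and time.monotonic() - t0 > cfg.time_limit_s:
            termination = "time_limit"
            break
        sub = build_subgraph(graph, seed, cfg)
        n_sub += 1
        for bubble in find_bubbles(sub, graph.k, strict=cfg.strict_colours):
            if bubble.key not in found:
                found[bubble.key] = bubble
                hosts[bubble.key] = sub
    bubbles = sorted(found.values(), key=lambda b: b.key[0] + tuple(sorted(b.key[1])))
    logger.info(
        "bubble search: %d sub-graphs, %d bubbles, termination=%s",
        n_sub,
        len(bubbles),
        termination,
    )
    return SearchResult(bubbles=bubbles, hosts=hosts, n_subgraphs=n_sub, termination=termination)
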