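"""Independent brute-force oracle for bubble enumeration.

Enumerates every simple cycle of exactly 2k+2 edges in the undirected
multigraph by root-anchored DFS (no sub-graphs, no seeding, no path
pairing), then applies the bubble predicate to each equidistant split of
each cycle. Used to cross-check the sub-graph search.
"""

from __future__ import annotations

import random

from bubblesnp.bubbles import make_bubble
from bubblesnp.pipeline import build_undirected_graph


def enumerate_simple_cycles(graph, length: int):
    """All simple cycles with exactly ``length`` edges, deduplicated by edge set."""
    g = graph.g
    seen: set[frozenset] = set()
    cycles = []
    for root in sorted(g.nodes):
        path = [root]
        keys: list[str] = []
        on_path = {root}

        def rec(v):
            for nbr, keydict in sorted(g.adj[v].items()):
                for key in sorted(keydict):
                    if nbr == root and len(keys) == length - 1:
                        edge_set = frozenset(keys + [key])
                        if edge_set not in seen:
                            seen.add(edge_set)
                            cycles.append((tuple(path), tuple(keys) + (key,)))
                    elif nbr not in on_path and nbr > root and len(keys) < length - 1:
                        path.append(nbr)
                        keys.append(key)
                        on_path.add(nbr)
                        rec(nbr)
                        on_path.remove(nbr)
                        path.pop()
                        keys.pop()

        rec(root)
    return cycles


def brute_force_bubbles(graph, strict: bool = False):
    """Every valid bubble in the graph, keyed for set comparison."""
    k = graph.k
    m = 2 * k + 2
    found = {}
    for verts, keys in enumerate_simple_cycles(graph, m):
        for i in range(k + 1):
            j = i + k + 1
            idx_a = [(i + t) % m for t in range(k + 2)]
            idx_b = [(j + t) % m for t in range(k + 2)]
            path_a = (
                tuple(verts[t] for t in idx_a),
                tuple(keys[(i + t) % m] for t in range(k + 1)),
            )
            path_b = (
                tuple(verts[t] for t in idx_b),
                tuple(keys[(j + t) % m] for t in range(k + 1)),
            )
            bubble = make_bubble(graph, path_a, path_b, strict=strict)
            if bubble is not None:
                found[bubble.key] = bubble
    return found


def random_two_colour_graph(seed: int, k: int):
    """Small random two-colour graph built from short related or unrelated reads."""
    rng = random.Random(seed)
    mode = seed % 3
    # unrelated pairs share few k-mers, so halve the length to keep <= 60 vertices
    length = rng.randrange(18, 31) if mode == 2 else rng.randrange(25, 59)
    ref = "".join(rng.choice("ACGT") for _ in range(length))
    if mode == 2:
        other = "".join(rng.choice("ACGT") for _ in range(length))
    else:
        n_subs = 1 + (mode == 1)
        other = list(ref)
        for _ in range(n_subs):
            pos = rng.randrange(length)
            other[pos] = rng.choice([b for b in "ACGT" if b != other[pos]])
        other = "".join(other)
    return build_undirected_graph([ref], [other], k, cleaning=None)
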