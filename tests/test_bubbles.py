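import random

import pytest

from bubblesnp.bubbles import (
    SearchConfig,
    UsageError,
    branching_vertices,
    build_subgraph,
    extract_contigs,
    find_bubbles,
    search,
)
from bubblesnp.simulate import SimulationConfig, simulate_dataset
from bubblesnp.pipeline import build_undirected_graph

from conftest import TOY_K, build_ug


def test_branching_vertices_toy(toy_ug):
    assert branching_vertices(toy_ug) == ["GCC", "TAA"]


def test_branching_vertices_linear_path():
    ug = build_ug(["TTACCAGTC"], [], 5)
    assert branching_vertices(ug) == []


def test_branching_vertices_star():
    # three reads share the prefix AACGT and diverge after it: the 4-mer
    # AACG sits at the centre with three departing edges
    ug = build_ug(["AACGTT", "AACGAT", "AACGCT"], [], 4)
    assert "AACG" in branching_vertices(ug)
    fwd, rev = ug.side_out_degrees("AACG")
    assert max(fwd, rev) == 3


def test_build_subgraph_full_component(toy_ug):
    sub = build_subgraph(toy_ug, "TAA", SearchConfig(max_subgraph_size=100))
    assert sub.n_vertices == 9
    assert sub.seed == "TAA"


def test_build_subgraph_cap(toy_ug):
    sub = build_subgraph(toy_ug, "TAA", SearchConfig(max_subgraph_size=4))
    assert sub.n_vertices == 4
    assert sub.graph.has_vertex("TAA")


def test_build_subgraph_rejects_non_branching_seed(toy_ug):
    with pytest.raises(UsageError):
        build_subgraph(toy_ug, "AAC", SearchConfig())


def test_find_bubbles_toy(toy_bubble):
    assert set(toy_bubble.endpoints) == {"TAA", "GCC"}
    internals = {b.internal for b in toy_bubble.branches}
    assert {frozenset(i) for i in internals} == {
        frozenset({"AAC", "ACG", "CCG"}),
        frozenset({"AAT", "ATG", "CCA"}),
    }
    assert toy_bubble.edge_count == 2 * TOY_K + 2
    colours = {b.colour for b in toy_bubble.branches}
    assert colours == {0, 1}


def test_find_bubbles_monochrome_topology_rejected():
    # same two sequences both as colour0: bubble topology exists but the
    # branches are not colour-distinct
    ug = build_ug(["TAACGGCA", "TAATGGCA"], [], TOY_K)
    assert find_bubbles(ug) == []


def test_find_bubbles_rejects_unequal_branches():
    """A closed cycle whose branch lengths are k and k+2 is not a bubble."""
    # colour0 path TAAC..., colour1 takes a detour two bases longer between
    # the same flanks; total cycle length 2k+2 is required with k+1 each
    ref = "TTGACGGCATT"
    alt = "TTGATTCGGCATT"  # two extra bases on the variant branch
    ug = build_ug([ref], [alt], 4)
    assert find_bubbles(ug) == []


def test_extract_contigs_toy(toy_bubble, toy_ug):
    contigs = extract_contigs(toy_bubble, toy_ug)
    assert [c.sequence for c in contigs] == ["CGGC", "TGGC"]
    c0, c1 = contigs
    assert c0.sequence[0] != c1.sequence[0]
    assert c0.sequence[1:] == c1.sequence[1:]


def test_extract_contigs_opposite_endpoint(toy_bubble, toy_ug):
    # walking from the other endpoint yields the reverse-complement alleles
    contigs = extract_contigs(toy_bubble, toy_ug, start="GCC")
    assert [c.sequence for c in contigs] == ["GTTA", "ATTA"]


def test_extract_contigs_bad_start(toy_bubble, toy_ug):
    with pytest.raises(UsageError):
        extract_contigs(toy_bubble, toy_ug, start="AAC")


def test_search_toy(toy_ug):
    res = search(toy_ug, SearchConfig(max_subgraphs=10, rng_seed=3))
    assert len(res.bubbles) == 1
    assert res.termination == "seeds_exhausted"


def test_search_single_subgraph_finds_bubble(toy_ug):
    # the bubble is reachable from either branching endpoint
    for seed in (0, 1, 2):
        res = search(toy_ug, SearchConfig(max_subgraphs=1, rng_seed=seed))
        assert len(res.bubbles) == 1
        assert res.termination == "max_subgraphs"


def test_search_rejects_zero_subgraphs():
    with pytest.raises(UsageError):
        SearchConfig(max_subgraphs=0)


def test_search_deterministic_and_seed_order_invariant(toy_ug):
    a = search(toy_ug, SearchConfig(max_subgraphs=10, rng_seed=7))
    b = search(toy_ug, SearchConfig(max_subgraphs=10, rng_seed=7))
    assert [x.key for x in a.bubbles] == [x.key for x in b.bubbles]
    # with T >= #branching vertices the output set is seed-order invariant
    c = search(toy_ug, SearchConfig(max_subgraphs=10, rng_seed=99))
    assert {x.key for x in a.bubbles} == {x.key for x in c.bubbles}


def test_search_time_limit_terminates(toy_ug):
    res = search(toy_ug, SearchConfig(time_limit_s=1e-9, rng_seed=0))
    assert res.termination == "time_limit"
    assert res.n_subgraphs == 0


def test_subgraph_size_warning(toy_ug):
    with pytest.warns(UserWarning, match="2k\\+2"):
        search(toy_ug, SearchConfig(max_subgraph_size=4))


@pytest.mark.parametrize("seed", range(12))
def test_single_snp_recovers_alleles(seed):
    """One isolated substitution between clean sequences yields exactly one
    bubble whose first-base pair equals the two alleles."""
    rng = random.Random(1000 + seed)
    k = 7
    length = 80
    while True:
        ref = "".join(rng.choice("ACGT") for _ in range(length))
        pos = rng.randrange(k + 1, length - k - 1)  # keep a full window inside
        # precondition: no repeated or rc-colliding k-mers anywhere
        ug_ref = build_ug([ref], [], k)
        if ug_ref.n_vertices == length - k + 1 and not ug_ref.branching_vertices():
            break
    alt_base = rng.choice([b for b in "ACGT" if b != ref[pos]])
    alt = ref[:pos] + alt_base + ref[pos + 1 :]
    ug = build_ug([ref], [alt], k)
    bubbles = find_bubbles(ug)
    assert len(bubbles) == 1
    c0, c1 = extract_contigs(bubbles[0], ug)[:2]
    alleles = {c0.sequence[0], c1.sequence[0]}
    from bubblesnp.kmers import complement_base

    assert alleles in ({ref[pos], alt_base},
                       {complement_base(ref[pos]), complement_base(alt_base)})


def test_structural_invariants_on_noisy_simulation():
    """Every emitted bubble obeys the cycle and contig contracts."""
    cfg = SimulationConfig(
        genome_length=3000, n_snps=12, min_spacing=30, read_length=40,
        coverage=20.0, error_rate=0.01, rng_seed=5,
    )
    data = simulate_dataset(cfg)
    ug = build_undirected_graph(data.reads0, data.reads1, 15, cleaning=None)
    res = search(ug, SearchConfig(rng_seed=5))
    assert res.bubbles
    k = ug.k
    for bubble in res.bubbles:
        assert bubble.edge_count == 2 * k + 2
        assert all(len(b.edge_keys) == k + 1 for b in bubble.branches)
        i0, i1 = (set(b.internal) for b in bubble.branches)
        assert not i0 & i1
        c0, c1 = (c.sequence for c in extract_contigs(bubble, ug)[:2])
        assert len(c0) == len(c1) == k + 1
        assert c0[0] != c1[0] and c0[1:] == c1[1:]
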