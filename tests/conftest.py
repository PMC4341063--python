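import pytest

from bubblesnp import SearchConfig, find_bubbles, search
from bubblesnp.pipeline import build_undirected_graph
from bubblesnp.graph import build_graph
from bubblesnp.kmers import count_kmers

# Two 8 bp reads differing by one substitution at position 4 (C vs T); at
# k=3 their joint graph holds a single bubble between TAA and GCC.
TOY_READ0 = "TAACGGCA"
TOY_READ1 = "TAATGGCA"
TOY_K = 3
TOY_REFERENCE = TOY_READ0
TOY_TRUTH_POSITION = 4


@pytest.fixture(scope="session")
def toy_reads():
    return [TOY_READ0], [TOY_READ1]


@pytest.fixture(scope="session")
def toy_counts(toy_reads):
    return count_kmers(list(toy_reads), TOY_K)


@pytest.fixture(scope="session")
def toy_graph(toy_counts):
    return build_graph(toy_counts)


@pytest.fixture(scope="session")
def toy_ug(toy_reads):
    r0, r1 = toy_reads
    return build_undirected_graph(r0, r1, TOY_K, cleaning=None)


@pytest.fixture(scope="session")
def toy_bubble(toy_ug):
    bubbles = find_bubbles(toy_ug)
    assert len(bubbles) == 1
    return bubbles[0]


@pytest.fixture(scope="session")
def toy_search_result(toy_ug):
    return search(toy_ug, SearchConfig(max_subgraphs=10, rng_seed=0))


def build_ug(reads0, reads1, k, cleaning=None):
    return build_undirected_graph(reads0, reads1, k, cleaning)
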