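"""High-level chaining of the stages: reads -> graph -> bubbles -> calls."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import bubbles as bb
from . import classify as cf
from . import evaluate as ev
from .graph import CleaningConfig, UndirectedBubbleGraph, build_graph, clean_graph, to_undirected
from .kmers import count_kmers
from .simulate import SimulatedDataset

logger = logging.getLogger(__name__)


def build_undirected_graph(
    reads0,
    reads1,
    k: int,
    cleaning: CleaningConfig | None = None,
) -> UndirectedBubbleGraph:
    """Count k-mers, build the coloured graph, optionally clean, transform."""
    counts = count_kmers([reads0, reads1], k)
    graph = build_graph(counts)
    logger.info("built graph: %d vertices, %d edges", graph.n_vertices, graph.n_edges)
    if cleaning is not None:
        graph = clean_graph(graph, cleaning)
        logger.info(
            "cleaned graph: %d vertices, %d edges", graph.n_vertices, graph.n_edges
        )
    return to_undirected(graph)


@dataclass
class CallSet:
    """Bubbles, contigs, features and (optionally) placements of one run."""

    graph: UndirectedBubbleGraph
    result: bb.SearchResult
    records: list = field(default_factory=list)  # (id, bubble, contigs, host)
    features: list = field(default_factory=list)
    placements: list = field(default_factory=list)
    report: ev.EvaluationReport | None = None

    @property
    def contigs_by_bubble(self) -> dict[str, tuple[str, str]]:
        return {
            rid: (contigs[0].sequence, contigs[1].sequence)
            for rid, _, contigs, _ in self.records
        }


def call_snps(
    graph: UndirectedBubbleGraph,
    search_cfg: bb.SearchConfig | None = None,
) -> CallSet:
    """Search a graph for bubbles and extract contigs and feature vectors."""
    search_cfg = search_cfg or bb.SearchConfig()
    result = bb.search(graph, search_cfg)
    records = result.records(graph, emit_mixed=search_cfg.emit_mixed_contig)
    features = [
        cf.extract_features(bubble, host, graph, bubble_id=rid)
        for rid, bubble, _, host in records
    ]
    return CallSet(graph=graph, result=result, records=records, features=features)


def evaluate_callset(
    calls: CallSet,
    reference: str,
    truth,
    label_features: bool = True,
) -> CallSet:
    """Place every contig pair on the reference and score against truth."""
    calls.placements = [
        ev.place_contig(contigs[:2], reference, bubble_id=rid)
        for rid, _, contigs, _ in calls.records
    ]
    truth_positions = ev.truth_positions(truth)
    calls.report = ev.evaluate_calls(calls.placements, truth, len(reference))
    if label_features:
        placed = {
            p.bubble_id: p for p in calls.placements if p.status == ev.PLACED
        }
        for vec in calls.features:
            p = placed.get(vec.bubble_id)
            vec.label = (
                cf.REAL
                if p is not None and p.position in truth_positions
                else cf.FALSE_POSITIVE
            )
    return calls


def run_end_to_end(
    dataset: SimulatedDataset,
    k: int,
    cleaning: CleaningConfig | None,
    search_cfg: bb.SearchConfig | None = None,
) -> CallSet:
    """simulate -> build -> clean -> bubbles -> features -> evaluate."""
    graph = build_undirected_graph(dataset.reads0, dataset.reads1, k, cleaning)
    calls = call_snps(graph, search_cfg)
    return evaluate_callset(calls, dataset.reference, dataset.truth)


def write_contigs_fasta(records, path) -> None:
    """FASTA of allele contigs, headers ``>bubble<id>|<colour>|len=<n>``."""
    with open(path, "w") as fh:
        for rid, _, contigs, _ in records:
            for c in contigs:
                colour = "mixed" if c.colour == -1 else f"colour{c.colour}"
                fh.write(f">{rid}|{colour}|len={len(c.sequence)}\n{c.sequence}\n")


def write_manifest_tsv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "bubble_id\tendpoint1\tendpoint2\tcolour0_contig\tcolour1_contig\tn_mixed_edges\n"
        )
        for rid, bubble, contigs, _ in records:
            e1, e2 = bubble.endpoints
            fh.write(
                f"{rid}\t{e1}\t{e2}\t{contigs[0].sequence}\t{contigs[1].sequence}\t"
                f"{bubble.n_mixed_edges}\n"
            )
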