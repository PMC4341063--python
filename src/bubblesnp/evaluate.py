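"""Contig placement on a reference and sensitivity/specificity/accuracy.

Allele contigs are k+1-mers whose first base is the variant site, so on a
synthetic reference they can be placed losslessly by exact string matching
(forward or reverse complement); alignment with mismatches is unnecessary.
The predicted SNP position is the first base of a forward match or the last
base of a reverse-complement match, in 1-based forward-strand coordinates.

Metric definitions: sensitivity = TP/(TP+FN); specificity = TN/(TN+FP)
with TN counting non-SNP reference sites, so it sits near 100% whenever
false calls are rare; accuracy = TP/(TP+FP), the fraction of predicted
SNPs present in the known list.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .kmers import complement_base, reverse_complement

PLACED, UNPLACED, AMBIGUOUS = "placed", "unplaced", "ambiguous"


class EvaluationError(ValueError):
    """Inconsistent evaluation inputs."""


@dataclass(frozen=True)
class Placement:
    """Where a bubble's contig pair sits on the reference, if anywhere."""

    bubble_id: str
    status: str  # placed | unplaced | ambiguous
    position: int | None = None  # 1-based SNP coordinate
    strand: str | None = None  # forward | reverse
    matched_colour: int | None = None
    ref_allele: str | None = None
    alt_allele: str | None = None


def _occurrences(pattern: str, text: str) -> list[int]:
    out = []
    i = text.find(pattern)
    while i != -1:
        out.append(i)
        i = text.find(pattern, i + 1)
    return out


def place_contig(contigs, reference: str, bubble_id: str = "") -> Placement:
    """Place a bubble's two allele contigs on a reference by exact match.

    Exactly one occurrence of one contig (either strand) across the whole
    search yields a placement; none yields ``unplaced``; more than one
    total yields ``ambiguous``.
    """
    seqs = {}
    for c in contigs:
        colour = getattr(c, "colour", None)
        seq = getattr(c, "sequence", c)
        seqs[colour if colour is not None else len(seqs)] = seq
    hits = []  # (position, strand, colour)
    for colour, seq in seqs.items():
        for off in _occurrences(seq, reference):
            hits.append((off + 1, "forward", colour))
        for off in _occurrences(reverse_complement(seq), reference):
            hits.append((off + len(seq), "reverse", colour))
    if not hits:
        return Placement(bubble_id=bubble_id, status=UNPLACED)
    if len(hits) > 1:
        return Placement(bubble_id=bubble_id, status=AMBIGUOUS)
    pos, strand, colour = hits[0]
    other = next(seq for c, seq in seqs.items() if c != colour)
    matched = seqs[colour]
    if strand == "forward":
        ref_allele, alt_allele = matched[0], other[0]
    else:
        ref_allele, alt_allele = complement_base(matched[0]), complement_base(other[0])
    return Placement(
        bubble_id=bubble_id,
        status=PLACED,
        position=pos,
        strand=strand,
        matched_colour=colour,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
    )


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    tn: int
    n_unplaced: int
    n_ambiguous: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan

    @property
    def accuracy(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else math.nan

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "n_unplaced": self.n_unplaced,
            "n_ambiguous": self.n_ambiguous,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def truth_positions(truth) -> set[int]:
    return {t if isinstance(t, int) else t.position for t in truth}


def evaluate_calls(
    placements,
    truth,
    reference_length: int,
    count_unresolved_as_fp: bool = False,
) -> EvaluationReport:
    """Compare placed calls with the truth SNP list.

    Placed positions are deduplicated; unplaced/ambiguous calls are tallied
    separately (optionally folded into FP). TN counts the non-SNP reference
    sites not falsely called.
    """
    truth_pos = truth_positions(truth)
    if truth_pos and reference_length < max(truth_pos):
        raise EvaluationError("reference_length smaller than a truth position")
    called = {p.position for p in placements if p.status == PLACED}
    n_unplaced = sum(1 for p in placements if p.status == UNPLACED)
    n_ambiguous = sum(1 for p in placements if p.status == AMBIGUOUS)
    tp = len(called & truth_pos)
    fp = len(called - truth_pos)
    if count_unresolved_as_fp:
        fp += n_unplaced + n_ambiguous
    fn = len(truth_pos - called)
    tn = (reference_length - len(truth_pos)) - fp
    return EvaluationReport(
        tp=tp, fp=fp, fn=fn, tn=tn, n_unplaced=n_unplaced, n_ambiguous=n_ambiguous
    )


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------


def write_calls_tsv(placements, contigs_by_bubble, path) -> None:
    """Calls table: one row per bubble with its placement state and alleles."""
    with open(path, "w") as fh:
        fh.write(
            "bubble_id\tposition\tstrand\tcolour0_allele\tcolour1_allele\tstatus\n"
        )
        for p in placements:
            c0, c1 = contigs_by_bubble[p.bubble_id]
            fh.write(
                f"{p.bubble_id}\t{p.position if p.position is not None else '.'}\t"
                f"{p.strand or '.'}\t{c0[0]}\t{c1[0]}\t{p.status}\n"
            )


def write_vcf(placements, reference_name: str, path) -> None:
    """Minimal VCF of placed calls for interoperability."""
    placed = sorted(
        (p for p in placements if p.status == PLACED), key=lambda p: p.position
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=BUBBLE_ID,Number=1,Type=String,Description="Bubble id">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for p in placed:
            fh.write(
                f"{reference_name}\t{p.position}\t.\t{p.ref_allele}\t{p.alt_allele}\t"
                f".\t.\tBUBBLE_ID={p.bubble_id}\n"
            )


def write_report(report: EvaluationReport, path_txt=None, path_json=None) -> None:
    d = report.as_dict()
    if path_txt is not None:
        with open(path_txt, "w") as fh:
            for key, val in d.items():
                fh.write(f"{key}\t{val}\n")
    if path_json is not None:
        with open(path_json, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")
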