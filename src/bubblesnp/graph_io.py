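"""Read/write the tab-separated graph dialect, and read FASTA/FASTQ reads.

Graph dialect::

    H<TAB>k=<int>
    V<TAB><canonical-kmer><TAB><cov0><TAB><cov1>
    E<TAB><kmer1><TAB><kmer2><TAB><label_fwd><TAB><label_bwd><TAB><colour>

Vertex and edge lines are emitted in sorted order so that serialization is
byte-stable and a write/read roundtrip is the identity.
"""

from __future__ import annotations

import gzip
from pathlib import Path

from Bio import SeqIO

from .graph import COLOUR_NAMES, MIXED, UndirectedBubbleGraph
from .kmers import canonical, complement_base, reverse_complement

_VALID_COLOURS = {*COLOUR_NAMES, MIXED}


class GraphParseError(ValueError):
    """Malformed graph file; the message names the offending line."""


def write_graph(ug: UndirectedBubbleGraph, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"H\tk={ug.k}\n")
        for v in ug.vertices():
            cov = ug.coverage(v)
            fh.write(f"V\t{v}\t{cov[0]}\t{cov[1]}\n")
        for d in ug.edge_records():
            fh.write(
                f"E\t{d['u']}\t{d['v']}\t{d['label_fwd']}\t{d['label_bwd']}\t{d['colour']}\n"
            )


def _reconstruct_edge_kmer(k1: str, k2: str, fwd: str, bwd: str, k: int) -> str | None:
    """Recover the canonical (k+1)-mer from an edge record.

    The (k+1)-mer oriented k1->k2 starts with the complement of the backward
    label and ends with the forward label; its suffix reads as k2 in one of
    the two orientations and its prefix as k1 likewise.
    """
    first = complement_base(bwd)
    candidates = set()
    for s2 in {k2, reverse_complement(k2)}:
        if s2[-1] == fwd:
            x = first + s2
            if x[:k] in (k1, reverse_complement(k1)):
                candidates.add(canonical(x))
    return min(candidates) if candidates else None


def read_graph(path) -> UndirectedBubbleGraph:
    path = Path(path)
    ug: UndirectedBubbleGraph | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "H":
                if ug is not None or len(fields) != 2 or not fields[1].startswith("k="):
                    raise GraphParseError(f"{path}:{lineno}: malformed header")
                try:
                    k = int(fields[1][2:])
                except ValueError:
                    raise GraphParseError(f"{path}:{lineno}: malformed header") from None
                if k < 2:
                    raise GraphParseError(f"{path}:{lineno}: k must be >= 2")
                ug = UndirectedBubbleGraph(k)
            elif tag == "V":
                if ug is None:
                    raise GraphParseError(f"{path}:{lineno}: vertex before header")
                if len(fields) != 4:
                    raise GraphParseError(f"{path}:{lineno}: malformed vertex record")
                v = fields[1]
                if len(v) != ug.k:
                    raise GraphParseError(
                        f"{path}:{lineno}: vertex length {len(v)} does not match k={ug.k}"
                    )
                try:
                    cov = (int(fields[2]), int(fields[3]))
                except ValueError:
                    raise GraphParseError(f"{path}:{lineno}: non-integer coverage") from None
                ug.g.add_node(v, cov=cov)
            elif tag == "E":
                if ug is None:
                    raise GraphParseError(f"{path}:{lineno}: edge before header")
                if len(fields) != 6:
                    raise GraphParseError(f"{path}:{lineno}: malformed edge record")
                _, k1, k2, fwd, bwd, colour = fields
                if colour not in _VALID_COLOURS:
                    raise GraphParseError(f"{path}:{lineno}: unknown colour {colour!r}")
                if k1 not in ug.g or k2 not in ug.g:
                    raise GraphParseError(f"{path}:{lineno}: edge references missing vertex")
                x = _reconstruct_edge_kmer(k1, k2, fwd, bwd, ug.k)
                if x is None:
                    raise GraphParseError(f"{path}:{lineno}: inconsistent edge labels")
                u, v = canonical(x[: ug.k]), canonical(x[1:])
                if {u, v} != {k1, k2}:
                    raise GraphParseError(f"{path}:{lineno}: edge endpoints do not match")
                ug.g.add_edge(
                    u,
                    v,
                    key=x,
                    kmer=x,
                    u=u,
                    v=v,
                    label_fwd=x[-1],
                    label_bwd=complement_base(x[0]),
                    colour=colour,
                )
            else:
                raise GraphParseError(f"{path}:{lineno}: unknown record tag {tag!r}")
    if ug is None:
        raise GraphParseError(f"{path}: missing header")
    return ug


def roundtrip_graph(ug: UndirectedBubbleGraph, path) -> UndirectedBubbleGraph:
    """Write then re-read a graph; the result equals the input."""
    write_graph(ug, path)
    return read_graph(path)


# ---------------------------------------------------------------------------
# read input
# ---------------------------------------------------------------------------

_FASTA_EXT = {".fa", ".fasta", ".fna"}
_FASTQ_EXT = {".fq", ".fastq"}


def read_sequences(paths) -> list[str]:
    """Sequences from FASTA/FASTQ files (plain or gzip), as plain strings."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    out: list[str] = []
    for path in paths:
        path = Path(path)
        suffixes = [s.lower() for s in path.suffixes]
        gzipped = suffixes and suffixes[-1] == ".gz"
        stem_ext = suffixes[-2] if gzipped and len(suffixes) >= 2 else (suffixes[-1] if suffixes else "")
        if stem_ext in _FASTA_EXT:
            fmt = "fasta"
        elif stem_ext in _FASTQ_EXT:
            fmt = "fastq"
        else:
            opener = gzip.open if gzipped else open
            with opener(path, "rt") as fh:
                first = fh.read(1)
            fmt = "fastq" if first == "@" else "fasta"
        opener = gzip.open if gzipped else open
        with opener(path, "rt") as fh:
            out.extend(str(rec.seq) for rec in SeqIO.parse(fh, fmt))
    return out
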