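"""Canonical k-mer primitives and per-colour k-mer counting.

A vertex of the graph represents a k-mer together with its reverse
complement; the stored form is the lexicographic minimum of the two
("canonical"). Reads are counted per colour (sample), yielding canonical
k-mer coverages for vertices and canonical (k+1)-mer observation counts
for edges.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_SEGMENT_RE = re.compile(r"[^ACGT]+")

#: number of samples ("colours") supported throughout the package
N_COLOURS = 2


class InvalidKmerError(ValueError):
    """Raised for k-mers containing non-ACGT characters or of wrong length."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def canonical(raw: str, k: int | None = None) -> str:
    """Canonical form of ``raw``: min(raw, reverse_complement(raw)).

    Raises :class:`InvalidKmerError` on non-ACGT characters, empty input,
    or (when ``k`` is given) length mismatch.
    """
    if k is not None and len(raw) != k:
        raise InvalidKmerError(f"expected k-mer of length {k}, got {len(raw)!r}: {raw!r}")
    if not raw or _SEGMENT_RE.search(raw):
        raise InvalidKmerError(f"not an ACGT string: {raw!r}")
    rc = reverse_complement(raw)
    return raw if raw <= rc else rc


def segments(read: str) -> list[str]:
    """ACGT-only segments of a read; the read is split at every other character
    (N and ambiguity codes included) and only the clean stretches are kept."""
    return [s for s in _SEGMENT_RE.split(read.upper()) if s]


@dataclass
class KmerCounts:
    """Per-colour canonical k-mer and (k+1)-mer observation counts."""

    k: int
    vertex_counts: dict[str, list[int]] = field(default_factory=dict)
    edge_counts: dict[str, list[int]] = field(default_factory=dict)
    #: total k-mer observations per colour (before canonical dedup)
    n_observations: list[int] = field(default_factory=lambda: [0] * N_COLOURS)


def count_kmers(reads_by_colour: Sequence[Iterable[str]], k: int) -> KmerCounts:
    """Count canonical k-mers and (k+1)-mers in two read sets.

    A read of length L contributes max(0, L-k+1) k-mer observations and
    max(0, L-k) (k+1)-mer observations per clean segment. Reads shorter
    than k contribute nothing; an empty collection yields empty counts.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if len(reads_by_colour) != N_COLOURS:
        raise ValueError(f"expected {N_COLOURS} read collections, got {len(reads_by_colour)}")
    counts = KmerCounts(k=k)
    vc = counts.vertex_counts
    ec = counts.edge_counts
    k1 = k + 1
    for colour, reads in enumerate(reads_by_colour):
        n_obs = 0
        for read in reads:
            for seg in segments(read):
                n = len(seg)
                if n < k:
                    continue
                rc = reverse_complement(seg)
                last_edge_start = n - k1
                for i in range(n - k + 1):
                    f = seg[i : i + k]
                    r = rc[n - i - k : n - i]
                    key = f if f <= r else r
                    entry = vc.get(key)
                    if entry is None:
                        entry = vc[key] = [0] * N_COLOURS
                    entry[colour] += 1
                    if i <= last_edge_start:
                        f2 = seg[i : i + k1]
                        r2 = rc[n - i - k1 : n - i]
                        key2 = f2 if f2 <= r2 else r2
                        entry2 = ec.get(key2)
                        if entry2 is None:
                            entry2 = ec[key2] = [0] * N_COLOURS
                        entry2[colour] += 1
                n_obs += n - k + 1
        counts.n_observations[colour] += n_obs
    return counts
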