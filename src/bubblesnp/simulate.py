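"""Synthetic genomes, variant copies and read sets with known SNP truth.

The generator emulates the study conditions the caller targets: a random
reference sequence, a variant copy differing by isolated substitutions at a
controlled minimum spacing, and single-end substitution-error reads at a
stated fold coverage (one read set per sample/colour). All randomness runs
through integer draws from :class:`random.Random` so output is identical
across platforms for a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .kmers import reverse_complement

_BASES = "ACGT"
_PPM = 1_000_000
_PPB = 1_000_000_000


class SimulationError(ValueError):
    """Invalid or infeasible simulation configuration."""


@dataclass(frozen=True)
class TruthSNP:
    """A known substitution: 1-based reference position, ref and alt bases."""

    position: int
    ref_allele: str
    alt_allele: str


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 100_000
    gc_fraction: float = 0.5
    n_snps: int = 200
    min_spacing: int = 42
    read_length: int = 50
    coverage: float = 30.0
    error_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise SimulationError("genome_length must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise SimulationError("gc_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise SimulationError("error_rate must be in [0, 1]")
        if self.n_snps < 0 or self.min_spacing < 0:
            raise SimulationError("n_snps and min_spacing must be non-negative")


def _spawn(rng: random.Random) -> random.Random:
    return random.Random(rng.randrange(2**31))


def generate_reference(cfg: SimulationConfig, rng: random.Random | None = None) -> str:
    """I.i.d. reference sequence with P(G)+P(C) = gc_fraction, split evenly."""
    rng = rng or random.Random(cfg.rng_seed)
    w_gc = round(cfg.gc_fraction * (_PPM // 2))
    w_at = (_PPM - 2 * w_gc) // 2
    rem = _PPM - 2 * w_gc - 2 * w_at
    # cumulative thresholds over A, C, G, T (remainder, at most 1 ppm, on A)
    t_a = w_at + rem
    t_c = t_a + w_gc
    t_g = t_c + w_gc
    out = []
    for _ in range(cfg.genome_length):
        r = rng.randrange(_PPM)
        if r < t_a:
            out.append("A")
        elif r < t_c:
            out.append("C")
        elif r < t_g:
            out.append("G")
        else:
            out.append("T")
    return "".join(out)


def inject_snps(
    reference: str, cfg: SimulationConfig, rng: random.Random | None = None
) -> tuple[str, list[TruthSNP]]:
    """Variant copy of ``reference`` with n_snps substitutions, spacing kept.

    Positions are drawn without replacement with every pairwise distance at
    least ``min_spacing`` (sampled from a reduced range, then spread by
    cumulative spacing offsets, so feasibility is checked up front). The
    alternate base is uniform over the three non-reference bases.
    """
    rng = rng or random.Random(cfg.rng_seed)
    n, length = cfg.n_snps, len(reference)
    if n == 0:
        return reference, []
    gap = max(1, cfg.min_spacing)
    reduced = length - (n - 1) * (gap - 1)
    if reduced < n:
        raise SimulationError(
            f"cannot place {n} SNPs with spacing {cfg.min_spacing} in length {length}"
        )
    picks = sorted(rng.sample(range(1, reduced + 1), n))
    positions = [p + i * (gap - 1) for i, p in enumerate(picks)]
    variant = list(reference)
    truth = []
    for pos in positions:
        ref = reference[pos - 1]
        alts = [b for b in _BASES if b != ref]
        alt = alts[rng.randrange(3)]
        variant[pos - 1] = alt
        truth.append(TruthSNP(position=pos, ref_allele=ref, alt_allele=alt))
    return "".join(variant), truth


def simulate_reads(
    sequence: str, cfg: SimulationConfig, rng: random.Random | None = None
) -> list[str]:
    """Uniform single-end reads from either strand with substitution errors.

    The number of reads is round(coverage * length / read_length); each base
    is substituted with probability error_rate, the replacement drawn
    uniformly from the three other bases.
    """
    rng = rng or random.Random(cfg.rng_seed)
    length, rl = len(sequence), cfg.read_length
    if rl > length:
        raise SimulationError("read_length exceeds sequence length")
    n_reads = round(cfg.coverage * length / rl)
    err_thr = round(cfg.error_rate * _PPB)
    reads = []
    for _ in range(n_reads):
        start = rng.randrange(length - rl + 1)
        read = sequence[start : start + rl]
        if rng.randrange(2):
            read = reverse_complement(read)
        if err_thr:
            chars = list(read)
            for i, base in enumerate(chars):
                if rng.randrange(_PPB) < err_thr:
                    alts = [b for b in _BASES if b != base]
                    chars[i] = alts[rng.randrange(3)]
            read = "".join(chars)
        reads.append(read)
    return reads


@dataclass
class SimulatedDataset:
    """A full simulation: reference/variant pair, truth, and per-colour reads."""

    config: SimulationConfig
    reference: str
    variant: str
    truth: list[TruthSNP]
    reads0: list[str] = field(default_factory=list)  # from the reference
    reads1: list[str] = field(default_factory=list)  # from the variant


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate reference, variant and both read sets from one seed.

    Independent RNG streams are derived for each stage so that, e.g.,
    changing the error rate leaves the genome and SNP placement unchanged.
    """
    master = random.Random(cfg.rng_seed)
    rng_ref, rng_snp, rng_r0, rng_r1 = (_spawn(master) for _ in range(4))
    reference = generate_reference(cfg, rng_ref)
    variant, truth = inject_snps(reference, cfg, rng_snp)
    reads0 = simulate_reads(reference, cfg, rng_r0)
    reads1 = simulate_reads(variant, cfg, rng_r1)
    return SimulatedDataset(
        config=cfg, reference=reference, variant=variant, truth=truth,
        reads0=reads0, reads1=reads1,
    )


# ---------------------------------------------------------------------------
# plain-text outputs
# ---------------------------------------------------------------------------


def write_fasta(records, path, width: int = 70) -> None:
    """Write (name, sequence) pairs as FASTA."""
    with Path(path).open("w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads, path, prefix: str = "read", quality: str = "I") -> None:
    with Path(path).open("w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{quality * len(seq)}\n")


def write_truth_tsv(truth, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("position\tref\talt\n")
        for snp in truth:
            fh.write(f"{snp.position}\t{snp.ref_allele}\t{snp.alt_allele}\n")


def read_truth_tsv(path) -> list[TruthSNP]:
    out = []
    with Path(path).open() as fh:
        header = fh.readline()
        if header.strip() != "position\tref\talt":
            raise SimulationError(f"{path}: not a truth table")
        for line in fh:
            pos, ref, alt = line.rstrip("\n").split("\t")
            out.append(TruthSNP(position=int(pos), ref_allele=ref, alt_allele=alt))
    return out
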