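# Methods

## Graph model

Both read sets are decomposed into k-mers; a vertex of the graph is a
*canonical* k-mer, the lexicographic minimum of the string and its reverse
complement, so one vertex represents both orientations of a sequence
fragment. Vertices carry per-sample ("colour") coverage counts. An edge is
an observed canonical (k+1)-mer joining the canonical forms of its prefix
and suffix k-mers; it carries per-colour observation counts. Reads
containing characters outside {A,C,G,T} are split at those characters and
only complete k-mers from clean stretches are counted, so no base is ever
fabricated.

Parallel edges between one vertex pair (distinct (k+1)-mers with the same
canonical endpoints) are kept as a multigraph, and a reverse-complement
palindromic (k+1)-mer becomes a self-loop; both are rare but real
consequences of canonicalization. Self-loops can never participate in a
bubble (cycle enumeration uses vertex-simple paths) and are carried only
for bookkeeping.

For the search, the graph is transformed to an undirected labelled graph.
An edge derived from (k+1)-mer x₁…x_{k+1} oriented u→v stores
`label_forward = x_{k+1}` and `label_backward = complement(x₁)`: the base a
walk appends when traversing the edge in each direction. Its colour is
`colour0` or `colour1` when only one read set observed it, `mixed` when
both did.

**Branching rule.** A vertex is branching when at least two incident edges
depart it in one of its two orientations (the bidirected view). This is
deliberately not the undirected-degree rule: the opening vertex of a bubble
may have undirected degree 2 yet two edges leaving the same side — the toy
example in the test suite (reads `TAACGGCA`/`TAATGGCA`, k=3) contains
exactly this case at vertex `TAA`.

## Cleaning

Two rules, applied once each, low-coverage removal first:

- **Low coverage.** Every vertex whose coverage summed over both colours is
  ≤ `min_vertex_coverage` (default 2) is deleted with its incident edges.
  Whether the original tooling applied this per colour or jointly is not
  documented anywhere we could verify; the joint sum is the default because
  cleaning operates on the single joint graph, and a per-colour mode (a
  vertex survives only if some single colour exceeds the threshold) is
  exposed as an option.
- **Tips.** A tip is a maximal unbranched path starting at a degree-1 dead
  end and ending against a branching vertex (the anchor, which is kept). Its
  length in nucleotides is `path vertices + k − 1` — sequence length, not
  vertex count. Tips shorter than `min_tip_length_nt` (default 100) are
  deleted. Linear components that never meet a branching vertex are left
  alone; they are contigs, not artefacts.

The serialized graph dialect keeps vertex coverages but only an edge
colour, not per-colour edge counts, so the standalone `clean` subcommand
applies the same two rules directly to the undirected graph; the
library-level cleaning used by `build` runs on the full coloured graph
before the undirected transform. Both paths share one implementation of the
rules and a test asserts they agree.

## Bubble search

A SNP is called from a cycle of exactly 2k+2 edges between two branching
vertices connected by two internally disjoint branches of k+1 edges each,
one compatible with each colour. Candidate generation follows the
seed-and-bound strategy:

1. all branching vertices are listed in lexicographic order and shuffled
   with the run seed;
2. around each seed a sub-graph is grown breadth-first in sorted neighbour
   order up to `max_subgraph_size` vertices (default 100);
3. inside the sub-graph, every simple path of exactly k+1 edges is
   enumerated from each branching vertex; paths from two branching vertices
   meeting at their far ends are paired and validated;
4. the loop stops after `max_subgraphs` sub-graphs (the free parameter T),
   when seeds are exhausted, or when the optional time limit expires —
   always a logged, normal termination.

There is no algorithmic bound on sub-graph complexity in general; the work
per sub-graph here is bounded by the depth-(k+1) path enumeration from its
branching vertices, which is exponential in the worst case but small under
the default vertex cap.

**Colour predicate.** A branch is compatible with colour c when every edge
is c or mixed and at least one edge is strictly c; the two branches must
take distinct colours. Mixed edges are admitted because two SNPs within k
of each other share window k-mers, whose edges are observed by both
samples; a strict mode (no mixed edges) is available behind a flag.

**Allele contract as part of the predicate.** Walking both branches from
one endpoint collects two contigs of length k+1. For a genuine SNP they
differ at position 1 and agree elsewhere. In a canonical-k-mer graph a
2k+2 cycle can also arise from orientation-inconsistent traversals (a walk
that enters a vertex and leaves it on the same strand side) whose label
strings are not genomic sequence; such cycles satisfy the length, distance
and colour rules yet violate the first-base contract. The contract check is
therefore folded into the single bubble predicate used everywhere — by the
sub-graph search and by the brute-force cycle oracle in the tests — so the
emitted-contig invariant holds unconditionally.

**Canonical orientation and deduplication.** The same cycle is reachable
from both endpoints and in both directions, yielding allele pairs that are
reverse complements of each other. Output is made deterministic by emitting
from the endpoint/direction whose colour0 contig is lexicographically
smallest, and bubbles are deduplicated by the unordered endpoint pair plus
the unordered pair of internal-vertex tuples.

The published procedure's contig loop nominally iterates over a third,
`mixed` colour; the accompanying description defines exactly two k+1
contigs. The default here emits two contigs; an optional flag additionally
emits the concatenated labels of each bubble's mixed edges as a third,
variable-length record.

## Classifier

Each bubble is described by: `total_coverage`, the two-colour coverage
summed over all 2k+2 cycle vertices; `branch0_coverage`/`branch1_coverage`,
own-colour coverage summed over each branch's k internal vertices; and
`subgraph_branching`, the number of branching vertices of the host
sub-graph divided by its vertex count. "Mean number of branching vertices"
is undefined for a single sub-graph, so it is normalized to this fraction;
the raw count is also emitted.

The tree is C4.5-flavoured: binary splits on numeric attributes with
thresholds at midpoints between consecutive distinct values, chosen by gain
ratio among splits with positive gain and at least `min_leaf_size` (default
2) instances per side; ties route to the ≤ branch for determinism. Pruning
is error-based at confidence 0.25, using the exact binomial upper
confidence limit (a beta quantile) rather than the classic normal
approximation; subtree raising is not implemented. With these defaults a
perfectly separable table keeps its split, and pruning never increases node
count (asserted in tests). The evaluation protocol is ten independent
stratified splits, two-thirds training and one-third testing, with
per-class shuffles drawn from a seeded generator; metrics are sensitivity
TP/(TP+FN), specificity TN/(TN+FP) and accuracy TP/(TP+FP) (the fraction of
predicted-real bubbles that are real), averaged over runs ignoring
undefined values.

## Evaluation

Allele contigs are placed on the reference by exact string matching of each
contig and its reverse complement. The SNP coordinate is the first base of
a forward match or the last base of a reverse-complement match, 1-based on
the forward strand; both canonical orientations of the same bubble place at
the same coordinate (property-tested). Exactly one hit across both contigs
and strands gives a placement; zero hits is `unplaced`; multiple hits is
`ambiguous`. Unplaced and ambiguous calls are reported separately and not
counted as false positives by default (a flag folds them in), since the
multi-hit policy of alignment-based placement is not otherwise defined.
Exact matching replaces heuristic alignment deliberately: on synthetic
references it is lossless for k+1-mers and removes an external dependency.

True negatives count non-SNP reference sites, so specificity is near 100 %
whenever false calls are rare relative to genome length — with fewer false
positives than one per 1000 sites, specificity exceeds 0.999 by
construction.

## Synthetic data

The generator emulates the intended operating regime: an i.i.d. random
reference with adjustable GC fraction; a variant copy with `n_snps`
substitutions at pairwise distance ≥ `min_spacing` (alternate bases uniform
over the three non-reference bases); and single-end reads of fixed length
with uniform start positions, uniform strand, and i.i.d. substitution
errors replacing a base by one of the other three. Defaults (100 kb,
200 SNPs spaced ≥ 42 = 2k at the default k = 21, 50 bp reads at 30× per
sample) give a desk-scale analogue of resequencing data at the coverage
range the method targets; 30× sits inside the 27–60× regime of typical
short-read studies and keeps the full pipeline under a minute.

SNP positions are drawn by sampling n distinct values from a reduced range
and adding cumulative spacing offsets, which guarantees the spacing
exactly, is deterministic, and fails fast when placement is infeasible; the
distribution over position sets is slightly non-uniform (order-statistics
construction) which is immaterial for these experiments. All random draws
are integer draws from Python's Mersenne generator, with independent
derived streams per stage, so identical seeds give byte-identical outputs
across platforms; no floating-point comparisons enter any generation path.

What the generator does **not** model: paired ends and insert sizes (the
graph never uses pairing), indels (the method targets substitutions only),
quality scores (written as a constant), diploid heterozygosity, and repeat
families. Passing tests on this generator therefore demonstrate the
topological machinery and its bookkeeping, not robustness to the repeat
structure and coverage biases of real genomes, where k-mer repeats make
more bubbles ambiguous and coverage heterogeneity interacts with the
cleaning thresholds.

## Numerical and procedural choices

- k must be ≥ 2; the default k = 21 matches common practice for short
  reads. `max_subgraph_size` below 2k+2 cannot contain a bubble and
  triggers a warning.
- Cleaning order is fixed (coverage, then tips, once each); iterating the
  pass is deliberately avoided to keep the operation idempotent and cheap.
- All orderings that affect output (vertex lists, neighbour expansion,
  bubble ids, serialized lines) are lexicographic, so artifacts are
  byte-stable for a fixed seed.
- The graph text dialect reconstructs each edge's (k+1)-mer from its
  endpoint k-mers and two labels; records whose labels admit no consistent
  (k+1)-mer are rejected with the line number.
- Degenerate inputs: empty read sets give empty graphs; searches on graphs
  without branching vertices return empty results; an evaluation with no
  placed calls reports NaN precision rather than inventing a value.

## Limitations

Only two colours (samples) are supported, and only 2k+2 cycles are
recognized — indels, longer variants and unequal-arm bubbles are out of
scope by design. The k-mer counter is a plain Python dictionary, adequate
to tens of megabases but far from the succinct structures used by
production graph tooling. Cycle enumeration cost grows with sub-graph
density; the vertex cap, T and the time limit are the only brakes. The
classifier uses the three documented attributes only and is a filter, not a
genotyper: no likelihoods or quality scores are produced.
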