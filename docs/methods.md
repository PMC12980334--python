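# Methods

## Overview

`wgalign` is a seed–chain–extend pairwise genome aligner whose parallel
code paths are constrained, by construction and by test, to produce exactly
the output of their sequential counterparts. The pipeline per query
sequence is: minimizer seeding against a reference index → stable anchor
sort → partitioning by (reference sequence, strand) → per-partition
chaining DP → global score sort → primary/secondary marking → base-level
extension → PAF emission. All coordinates are 0-based half-open end to end.

## Seeding

K-mers are 2-bit encoded (A=0, C=1, G=2, T=3) and hashed with an invertible
64-bit mixing finalizer. Both orientations are hashed and the smaller hash
is the canonical key; a palindromic tie counts as forward. Invertibility
means equal keys imply equal canonical k-mers, so every anchor is an exact
sequence match — the extension stage relies on this and verifies it.

Minimizers use the closed-window scheme: each window of `w` consecutive
k-mer positions emits all positions attaining the minimal hash. K-mers
containing N are skipped; a window with no valid k-mer emits nothing;
sequences shorter than `k + w − 1` use a single window over whatever
k-mers exist. The implementation is vectorized (sliding-window minima,
then a max-filter to recover per-position window membership) and is tested
against a direct per-window scan on hundreds of random sequences.

Defaults `k = 15`, `w = 10`, `max_occ = 100` sit in the range used by
assembly-to-reference presets of minimizer-based aligners; keys occurring
more than `max_occ` times in the reference are dropped entirely.

## Chaining

Within a partition, anchors sorted by (tpos, qpos) are scored by

    f(i) = max( s_i, max_j f(j) + min(Δq, Δt, s_i) − cost(j, i) ),
    cost  = γ·s_i·g + ½·log₂(g + 1),   g = |Δq − Δt|

with Δq measured along the chain direction (reversed on strand 1) and
feasibility 0 < Δq, Δt ≤ max_gap (5000), g ≤ max_skew_bandwidth (500).
`γ = gap_open_scale = 0.01`. The spec of the cost leaves open whose span
multiplies the linear term; this implementation uses the current (later)
anchor's span, consistently in the kernel, the scalar API and the
reference implementation. Predecessors are drawn from a bounded lookback
window (default 50 candidates) rather than a range-tree; the partitioning
layer is orthogonal to the inner kernel, and the bounded window keeps the
kernel simple and exhaustively testable.

Determinism rules, all load-bearing for the parallel-equivalence contract:
ties among predecessors go to the largest j (closest); a tie between the
single-anchor base case and an extension keeps the base case; chains are
extracted best-first with ties on f going to the smallest anchor index;
extracted chains whose score or anchor count falls below threshold still
consume their anchors (minimap2-like greedy extraction). The global chain
list is ordered by descending score with the fixed tie-break
(qs, seqid, ts, strand) ascending.

The DP kernel is JIT-compiled (numba) with a no-op fallback decorator; the
unpartitioned sequential reference (`chain_reference`) is deliberately
plain Python and shares no kernel code. Its lookback counts
same-(seqid, strand) candidates only, which is what makes the partitioned
and unpartitioned formulations identical — partitions are contiguous runs
of the sorted array, so the window never spans a partition boundary in
either formulation.

## Primary/secondary marking

Chains are walked in descending score order; a chain is secondary when
some accepted primary overlaps it on the query by strictly more than
`mask_level` (default 0.5) of the shorter interval. "Strictly more"
follows the rule's wording; an exact 0.5 overlap keeps both primary. Both
the quadratic baseline (linear scan of the primary set) and the
interval-tree version implement this identical decision procedure; the
tree (backed by the `intervaltree` package) stores only primary intervals,
and both functions optionally count fraction tests so the work asymmetry
(Θ(n²) vs 0 on disjoint worst cases) is measurable deterministically
rather than through wall-clock timing alone.

Secondary chains are retained in the output with `tp:A:S` and mapq 0
(a `--no-secondary` flag drops them). Chains on different target sequences
still compete: masking uses query intervals only.

## Extension

Anchors contribute exact k-long `M` runs. Consecutive minimizer anchors
routinely overlap (spacing < k); the later anchor's run is shortened from
the left by the larger of the query/target overlaps, and anchors trimmed
to nothing are dropped. Inter-anchor gap pairs are aligned with a Gotoh
three-state global DP: match +2, mismatch −4, gap cost
`gap_open + gap_extend·len` = `4 + 2·len`. The row-wise implementation is
vectorized, with the within-row deletion recurrence solved by a running
maximum over `maxMI[i,k] + e·k`; run-level backpointers (predecessor state
for M, extend-vs-open for I, gap-source column for D) make the traceback
independent of floating-point re-derivation. Traceback ties prefer
diagonal > deletion > insertion. With integer-valued scoring parameters
every cell value is integer-exact in float64; non-integer parameters keep
correct scores but tie decisions may then depend on rounding.

Gap pairs whose length difference exceeds the band (default 500) are
emitted as a `D`-run plus `I`-run without DP — bounded worst-case cost, no
heuristics. There is no end extension beyond the terminal anchors and no
z-drop; the alignment spans exactly the chain extents, which keeps the
stage deterministic and oracle-testable. Strand-1 chains are extended
against the reverse-complemented query and reported with strand '-', the
query interval mapped back to the original orientation; the CIGAR reads
along the query in its aligned orientation.

mapq is artifact-defined: 60 for an unchallenged primary, else
`round(60·(1 − s2/s1))` where s2 is the best secondary overlapping that
primary above the mask level; secondaries get 0.

## Scheduling and determinism

Queries are processed in batches capped by total bases (default 5×10⁸;
an oversize sequence forms its own batch). Within a batch the unit of
parallel work is a (query sequence, partition) pair, pooled across the
whole batch and dispatched largest-first to a thread pool; results are
reassembled in task order. Because work units are pure functions and
reassembly ignores completion order, worker-count and batch-size
invariance are structural properties, verified byte-for-byte on the PAF.

## Synthetic data

The generator emulates assembly-vs-assembly comparisons at desk scale:
uniform-composition random genomes (no GC skew or repeat model) with
structural events applied at fixed, non-overlapping footprints (inversion
= in-place reverse complement; duplication = inserted copy; translocation
= cross-sequence cut-and-paste), then SNPs/indels scattered outside event
footprints (duplications inject exact repeats, which is how
secondary-chain masking is exercised). Because edits never cascade, truth
records carry exact coordinates in both systems, also serialized as BED.
Default study conditions used by the test suite and acceptance script: a
1-Mb genome of two 500-kb sequences, SNP rate 5×10⁻⁴, indel rate 2×10⁻⁵
(max 10 bp), one 10-kb inversion, one 6-kb duplication — sized so full
multi-worker determinism sweeps stay cheap while every pipeline stage,
both strands and secondary masking are exercised. What passing these tests
does not show: behavior on real repeat structure (satellites, segmental
duplications), biased composition, or diverged genome pairs beyond the
point-mutation regime.

## Numerical and degenerate-input choices

Chain scores are float64 sums of small integer gains minus `0.01·s·g`
and `½log₂(g+1)` terms; equality comparisons across code paths are exact
because both paths perform identical operations in identical order.
Empty anchor lists, N-only queries, and empty partitions yield empty
results (not errors); an empty FASTA or empty reference is an error.
PAF round-trips are exact; float tags serialize via shortest-repr.

## Known limitations

Single-threaded performance is secondary to contract clarity: thread-based
workers share the GIL, so parallel speedup is bounded (the JIT-compiled
kernel releases little GIL time); the design goal here is determinism of
the decomposition, not wall-clock scaling. No SAM output, no mapq-ratio
secondary pruning, no range-tree chaining kernel, no dual-affine gaps, no
spliced or overlap modes. The seed-occurrence filter is a hard cutoff
(`max_occ`), not a frequency fraction.
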