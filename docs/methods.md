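# Methods

## Pooling design

The shifted transversal design STD(P, L, Γ) assigns clone i, with base-P
digits (i₀ … i_Γ), to pool `j·P + (Σ_c i_c j^c mod P)` of layer
j = 0 … L−1. Pool numbering is layer-major: layer j owns global indices
[j·P, (j+1)·P). Two distinct degree-Γ polynomials over GF(P) agree on at
most Γ of the L ≤ P evaluation points, which yields every guarantee the
toolkit relies on:

* any two signatures share ≤ Γ pools, so the minimum symmetric-difference
  distance between signatures is ≥ 2(L−Γ);
* unions of up to d = ⌊(L−1)/Γ⌋ signatures are pairwise distinct
  (d-decodability), verified exhaustively on small designs by
  `verify_decodability`;
* at full capacity n = P^(Γ+1) every pool holds exactly P^Γ clones.

The optional extra (P+1)-th "special" layer of the general construction
is not implemented; L ≤ P is enforced. The triple collision statistic is
defined as the union deficit 3L − |sig(a) ∪ sig(b) ∪ sig(c)| (maximum
3Γ); the alternative — pools common to all three signatures, maximum Γ —
is deliberately not used, because the union deficit is what bounds
3-union ambiguity and its range matches the design's guarantees. Both
pairwise and triple distributions are reported as percentages to one
decimal. Triple sampling is sequential-rejection sampling of distinct
triples in draw order (truncating a sorted unique list would bias the
sample toward low clone indices — measurably, ~0.15 points on the
zero-collision share of the full design).

## k-mer counting

k-mers are counted under canonicalization (lexicographic minimum of a
k-mer and its reverse complement), packed 2 bits/base into uint64 codes
(k ≤ 31, default 26). Windows containing any non-ACGT symbol are
skipped. The table is column-sparse — sorted distinct codes plus
(pool, count) pairs per code — because with sequencing errors the number
of distinct k-mers far exceeds the number of (k-mer, pool) incidences;
a dense vector per k-mer would not fit the intended problem sizes.
Counts saturate at 2¹⁶−1; only positivity and relative order matter
downstream. No low-count pre-threshold is applied before classification.

The default k = 26 comes from a pigeonhole argument: placing m
mismatches in an o-base overlap leaves an exact run of at least
⌈(o−m)/(m+1)⌉ bases, which is 26 for o = 78, m = 2
(`guaranteed_exact_match_length`, cross-checked by brute force in the
tests).

## k-mer and read classification

With L layers and collision bound Γ, a k-mer support of size w is
handled as:

| w | action |
|---|--------|
| < L−Γ | discard (sequencing-error artifact) |
| [L−Γ, L] | assign iff support ⊆ exactly one signature |
| (L, 2L−Γ) | drop the w−L smallest counts, re-test as single |
| [2L−Γ, 2L] | assign iff support = a union of two signatures |
| (2L, 3L−3Γ) | drop to 2L, re-test as two-union |
| [3L−3Γ, 3L] | assign iff support = a union of three signatures |
| > 3L | discard (highly repetitive) |

Design choices in this tree:

* The two-union window starts at 2L−Γ (a 2-union has size 2L minus an
  intersection of ≤ Γ), the three-union window at 3L−3Γ. For the
  full-scale design these are the familiar valid sizes 7, 12–14, 15–21.
* The *subset* rule for [L−Γ, L) tolerates up to Γ missing observations
  (coverage dropouts, or an entire lost pool). The containing signature
  is provably unique because w > Γ ≥ |sig ∩ sig'|; the floor is kept at
  max(L−Γ, Γ+1) so the uniqueness argument never breaks on degenerate
  parameter choices. Without this rule a single missing pool would
  silently erase every clone assigned to it — the pool-removal
  robustness test exercises exactly that.
* Drops never remove the count of the pool the read came from (that pool
  demonstrably contains the k-mer); ties among equal smallest counts
  break toward the lower pool index, for determinism.
* A failed equality test yields `unmatched` (tallied separately from the
  error/repeat discards); case ranges are tried in increasing union
  size.

A read is assigned to the union B of the clone sets of its assigned
k-mers iff 1 ≤ |B| ≤ 3; mates are processed as independent single-end
reads. The per-pool driver classifies each distinct k-mer once (count-
order-dependent drop cases are memoized per source pool) and uses 64-bit
pool/clone bitmasks, which limits the batched path to ≤ 64 pools and
≤ 64 clones; larger designs are served k-mer-by-k-mer via
`classify_kmer`. The classifier is validated against an independent
set-based brute force over every possible support of a 9-clone design.

## Simulator

`simulate_pools` emulates pooled clone sequencing: per pool, read pairs
are apportioned to member clones by length (largest-remainder), fragment
starts are uniform within the clone, insert lengths Normal (default
mean 327, sd 10% of the mean — only the mean is standard, the sd is this
package's choice), reads are 104 bases by default with i.i.d.
substitution errors at 1% and constant base quality. Reads never run
past clone ends (clone sequencing has no genomic read-through), and
indels, quality profiles, amplification bias and chimeras are not
modeled. An optional contaminant fraction draws pairs from a supplied
foreign sequence (mimicking host-DNA carryover) and flags them in the
truth table. Provenance (clone, pool, fragment coordinates) is encoded
in read names with a reserved `|` separator, and a truth TSV accompanies
the FASTQ output, so scoring never depends on alignment.

Synthetic genomes are i.i.d. bases at a target GC with optional planted
repeat families (mutated copies of a unit placed without overlap); clone
layouts tile the genome left-to-right with Normal lengths and overlaps,
enforcing that no base is covered by more than three clones — the regime
the 3-decodable design is built for. What passing simulation tests do
*not* show: real pools have uneven molar concentrations, error rates
that rise along the read, indels, and repeat structure far heavier than
the planted families; the deconvolution *rate* on real data is therefore
expected to be lower than in simulation, while the correctness and
accounting properties checked here are model-independent.

## Reference validation conditions

The test suite validates the sequencing-scale behaviour on STD(5, 4, 1)
at full capacity — 25 clones of 30 kb in 20 pools, 30x per-pool depth
(about 0.43 M read pairs per run) — once error-free with disjoint
clones, once with 1% substitution error and 10 kb overlaps. These sizes
keep a full simulate–count–deconvolve–score cycle to a couple of minutes
on one core while preserving every regime of the classifier (single
clones, 2-unions, error discards, drop cases). The full-scale
STD(13, 7, 2, 2197) design is used for the exact combinatorial checks
and for marker-decoding recovery, where construction is cheap.

## Marker decoding

For a marker with positive-pool set S, the decoder minimizes
E(T) = |P(T) \ S| + |S \ P(T)| over clone sets |T| ≤ 3, declaring the
marker non-decodable when min E exceeds the cap (default 3, exposed as a
flag). The search is restricted to clones sharing ≥ L − cap pools with
S: any T containing a clone below that bound has |sig \ S| > cap pools
in P(T) \ S, hence E > cap, so the restriction never changes a decodable
optimum (asserted against unrestricted brute force in the tests). For
non-decodable markers the reported E is the restricted minimum, which is
sufficient to certify E > cap. Ties break toward smaller |T|, then
lexicographic clone order — the assay itself does not distinguish such
ties; the rule just makes runs reproducible. An empty S reports a
sentinel error count of −1.

## Preprocessing

Sliding-window quality trimming truncates a read at the start of the
first window (default length 4, mean-quality comparison — the window
shape is this package's choice) whose mean Phred score falls below 23;
reads shorter than 36 bases after trimming, or containing an N, are
dropped. Adapter and host-contamination removal are left to upstream
tools. Planning guidance surfaced by the simulator's documentation, not
enforced anywhere: per-clone post-deconvolution depth of ≥ 50x (hence
150–200x pre-deconvolution) is the regime the method is designed for.

## Numerical and degenerate-input choices

Primality is checked deterministically (sympy); construction is a pure
function of the parameters. Empty supports, empty pools, reads shorter
than k, clones shorter than a read (skipped with a warning) and
zero-read pools are all defined, not errors. All randomness flows
through `numpy.random.default_rng` seeds; pool i of a simulation uses
child seed [seed, i], so per-pool streams are independent and the output
is byte-identical across reruns.

## Known limitations

* No iterative error-correction between deconvolution rounds; reads
  whose k-mers are all discarded stay non-deconvolutable.
* The batched deconvolution path assumes ≤ 64 pools / ≤ 64 clones
  (bitmask width); the full 91-pool design currently runs through the
  general per-k-mer interface only.
* Assembly itself (and assembly-quality metrics such as N50 against a
  reference) is out of scope; the per-clone FASTQ files and expected
  coverages are the hand-off point to an assembler.
* The in-memory count table assumes the distinct-k-mer set of the run
  fits in RAM; there is no disk-backed or probabilistic counting.
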