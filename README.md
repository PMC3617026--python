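# bacpool

Combinatorial pooling and k-mer read deconvolution for clone-by-clone
genome sequencing.

Sequencing a genome clone by clone (e.g. the BACs of a minimum tiling
path) normally requires barcoding thousands of libraries. `bacpool`
implements the alternative: pool the clones combinatorially, sequence the
pools, and assign each read back to its source clone(s) from the set of
pools it occurs in.

## The method

**Pooling.** Clones are pooled by a *shifted transversal design*
STD(P, L, Γ): L layers of P pools (P prime), where clone *i*, written in
base P as digits (i₀ … i_Γ), joins pool `j·P + (Σ_c i_c j^c mod P)` in
layer j. The L pools of a clone form its *signature*. Two signatures
share at most Γ pools, so unions of up to ⌊(L−1)/Γ⌋ signatures are
pairwise distinct (the design is ⌊(L−1)/Γ⌋-decodable) and at least
2(L−Γ) observation errors are needed to confuse two clones. The
full-scale design used throughout the validation is STD(13, 7, 2): 2197
clones in 91 pools, 169 clones per pool, 7 pools per clone.

**Deconvolution.** Every canonical k-mer (default k = 26, the guaranteed
exact-match length of a 78-base overlap with ≤ 2 mismatches) is counted
in each pool. A k-mer's *support* — the set of pools where it occurs —
is matched against single signatures and 2- and 3-fold signature unions,
tolerating up to Γ missing observations for a single clone and dropping
spurious smallest counts above a valid range. A read is assigned to the
union B of its k-mers' clone sets iff 1 ≤ |B| ≤ 3, otherwise it is
*non-deconvolutable*.

**Marker decoding.** Binary pool-level marker calls (e.g. a GoldenGate
assay) are decoded to clone sets T minimizing
E(T) = |P(T) \ S| + |S \ P(T)|, where S is the positive-pool set and
P(T) the union of T's signatures; markers with min E > 3 are
non-decodable.

The package also ships an in-silico pool sequencer (tiled clones,
Normal insert lengths, uniform substitution errors, optional contaminant
fraction, full provenance trail) and the evaluation metrics
(deconvolution rate, overlap-aware correctness, mate concordance,
per-clone depth).

## Worked example

```python
from bacpool import (DesignParams, construct_std, GenomeSpec, ReadSimParams,
                     generate_genome, layout_clones, simulate_pools,
                     build_count_table, deconvolve_pools, evaluate_run)

design = construct_std(DesignParams(P=5, L=4, Gamma=1, n=25))   # 20 pools
genome = generate_genome(GenomeSpec(length=750_000, gc=0.44, seed=7))
layout = layout_clones(len(genome), 25, 30_000, 0, 0, 0, seed=7)
sim = simulate_pools(design, layout, genome,
                     ReadSimParams(error_rate=0.0, depth_per_pool=30, seed=11),
                     "pools/")
table = build_count_table(sim.pool_files, k=26)
res = deconvolve_pools(sim.pool_files, table, design, "deconv/", layout.clone_ids)
report = evaluate_run(res.assignments, sim.truth, layout,
                      read_length=104)
print(report.to_dict())
```

prints

```
{'deconvolution_rate': 1.0, 'correctness_rate': 1.0,
 'mate_concordance': 1.0, 'mean_coverage': 120.00213333333333}
```

Every read of the error-free run is assigned, each to exactly its source
clone (rate and correctness 1.0), mates always agree, and each clone ends
up near the expected 4 × 30x = 120x combined coverage (each clone is
sequenced in L = 4 pools). With 1% sequencing error and 10 kb clone
overlaps the rate stays above 99.9% and overlap-aware correctness at 1.0,
with reads from overlaps assigned to both flanking clones.

The same pipeline is exposed as a CLI:
`bacpool design | design-stats | simulate | index | deconvolve |
evaluate | decode-markers | trim`.

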