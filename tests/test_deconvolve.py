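"""k-mer classification and read deconvolution.

The classifier is checked against an independent brute-force oracle that
enumerates 1-, 2- and 3-clone signature unions directly over sets, with
the same smallest-count drop rule, over *every* possible pool support of
the exhaustively checkable 9-clone design.
"""

from __future__ import annotations

import itertools
import os

import numpy as np
import pytest

from bacpool.deconvolve import (
    ASSIGNED,
    DECONVOLUTED,
    ERROR_DISCARD,
    NON_DECONVOLUTABLE,
    REPEAT_DISCARD,
    UNMATCHED,
    candidate_clones,
    classify_kmer,
    deconvolve_pools,
    deconvolve_read,
    read_signature_histogram,
)
from bacpool.design import DesignParams, construct_std
from bacpool.kmers import build_count_table


def oracle_classify(counts: dict[int, int], design, source_pool):
    """Set-based re-implementation: exhaustive union search, same drop rule."""
    p = design.params
    sigs = [design.signature_set(i) for i in range(p.n)]
    L, G = p.L, p.Gamma
    lo1 = max(L - G, G + 1)
    support = set(counts)
    w = len(support)
    if w < lo1:
        return ERROR_DISCARD, frozenset()
    if w > 3 * L:
        return REPEAT_DISCARD, frozenset()

    def exact(sup):
        ww = len(sup)
        if lo1 <= ww <= L:
            containing = [i for i, s in enumerate(sigs) if sup <= s]
            if len(containing) == 1:
                return frozenset(containing)
        if 2 * L - G <= ww <= 2 * L:
            for a, b in itertools.combinations(range(p.n), 2):
                if sigs[a] | sigs[b] == sup:
                    return frozenset((a, b))
        if 3 * L - 3 * G <= ww <= 3 * L:
            for t in itertools.combinations(range(p.n), 3):
                if sigs[t[0]] | sigs[t[1]] | sigs[t[2]] == sup:
                    return frozenset(t)
        return None

    if L < w < 2 * L - G or 2 * L < w < 3 * L - 3 * G:
        target = L if w < 2 * L - G else 2 * L
        dropped = 0
        for pool in sorted(support, key=lambda q: (counts[q], q)):
            if dropped == w - target:
                break
            if pool != source_pool:
                support.discard(pool)
                dropped += 1
    hit = exact(support)
    if hit is None:
        return UNMATCHED, frozenset()
    return ASSIGNED, hit


class TestClassifier:
    def test_low_support_is_error_discard(self, std_5_4):
        cv = np.zeros(20, dtype=int)
        cv[0] = 3
        ka = classify_kmer(cv, std_5_4, source_pool=0)
        assert ka.status == ERROR_DISCARD

    def test_exact_signature_assigns_single_clone(self, std_5_4):
        cv = np.zeros(20, dtype=int)
        sig = std_5_4.signature(7)
        cv[list(sig)] = 5
        ka = classify_kmer(cv, std_5_4, source_pool=sig[0])
        assert ka.status == ASSIGNED
        assert ka.clones == frozenset({7})
        assert ka.matched_support == std_5_4.signature_set(7)

    def test_source_pool_must_be_positive(self, std_5_4):
        cv = np.zeros(20, dtype=int)
        cv[list(std_5_4.signature(0))] = 1
        missing = next(p for p in range(20) if cv[p] == 0)
        with pytest.raises(ValueError, match="source pool"):
            classify_kmer(cv, std_5_4, source_pool=missing)

    def test_huge_support_is_repeat_discard(self, tiny_design):
        cv = np.ones(9, dtype=int)  # w = 9 = 3L for L=3: still classifiable...
        # 9 pools == 3L exactly -> three-union range, not repeat
        ka = classify_kmer(cv, tiny_design, source_pool=0)
        assert ka.status in (ASSIGNED, UNMATCHED)

    def test_agrees_with_oracle_on_every_support(self, tiny_design):
        """Exhaustive equivalence over all 511 nonempty supports (unit counts)."""
        pools = range(9)
        for r in range(1, 10):
            for support in itertools.combinations(pools, r):
                counts = {p: 1 for p in support}
                cv = np.zeros(9, dtype=int)
                cv[list(support)] = 1
                src = support[0]
                got = classify_kmer(cv, tiny_design, src)
                status, clones = oracle_classify(counts, tiny_design, src)
                assert (got.status, got.clones) == (status, clones), support

    def test_agrees_with_oracle_on_random_counts(self, tiny_design):
        """Drop-rule ordering exercised with non-uniform counts."""
        rng = np.random.default_rng(99)
        for _ in range(400):
            w = int(rng.integers(1, 10))
            support = tuple(sorted(rng.choice(9, size=w, replace=False)))
            cv = np.zeros(9, dtype=int)
            cv[list(support)] = rng.integers(1, 6, size=w)
            src = int(support[rng.integers(0, w)])
            counts = {int(p): int(cv[p]) for p in support}
            got = classify_kmer(cv, tiny_design, src)
            status, clones = oracle_classify(counts, tiny_design, src)
            assert (got.status, got.clones) == (status, clones)


class TestCandidates:
    def test_signature_support_yields_its_clone(self, std_5_4):
        for i in (0, 12, 24):
            assert candidate_clones(std_5_4.signature_set(i), std_5_4) == [i]

    def test_empty_support_empty_list(self, std_5_4):
        assert candidate_clones(frozenset(), std_5_4) == []

    def test_matches_brute_force_filter(self, tiny_design):
        rng = np.random.default_rng(3)
        sigs = [tiny_design.signature_set(i) for i in range(9)]
        for _ in range(100):
            support = frozenset(
                int(p) for p in rng.choice(9, size=int(rng.integers(0, 9)), replace=False)
            )
            brute = [i for i, s in enumerate(sigs) if s <= support]
            assert candidate_clones(support, tiny_design) == brute


def build_overlap_fixture(tmp_path):
    """Four clones on the 9-clone design; A/B share a 60-base block."""
    design = construct_std(DesignParams(3, 3, 1, 9))
    rng = np.random.default_rng(17)
    bases = "ACGT"
    mk = lambda n: "".join(bases[i] for i in rng.integers(0, 4, n))
    shared = mk(60)
    clones = {i: mk(200) for i in range(9)}
    clones[0] = mk(140) + shared
    clones[1] = shared + mk(140)
    pool_paths = []
    for pool in range(9):
        path = tmp_path / f"pool{pool}.fastq"
        with open(path, "w") as fh:
            for item in design.members[pool]:
                s = clones[int(item)]
                fh.write(f"@c{item}\n{s}\n+\n{'I' * len(s)}\n")
        pool_paths.append(str(path))
    table = build_count_table(pool_paths, k=26)
    return design, clones, table, pool_paths


class TestReadLevel:
    def test_single_clone_read(self, tmp_path):
        design, clones, table, _ = build_overlap_fixture(tmp_path)
        read = clones[2][50:130]
        ra = deconvolve_read(read, table, design, source_pool=design.signature(2)[0])
        assert ra.status == DECONVOLUTED
        assert ra.clones == frozenset({2})
        assert ra.support_size == 3

    def test_read_spanning_overlap_gets_both_clones(self, tmp_path):
        design, clones, table, _ = build_overlap_fixture(tmp_path)
        # read half in clone 0's unique tail, half in the shared block
        read = clones[0][110:190]
        ra = deconvolve_read(read, table, design, source_pool=design.signature(0)[0])
        assert ra.status == DECONVOLUTED
        assert ra.clones == frozenset({0, 1})

    def test_chimera_of_four_clones_rejected(self, tmp_path):
        design, clones, table, _ = build_overlap_fixture(tmp_path)
        read = "".join(clones[i][80:110] for i in (2, 3, 4, 5))
        ra = deconvolve_read(read, table, design, source_pool=design.signature(2)[0])
        assert ra.status == NON_DECONVOLUTABLE
        assert len(ra.clones) == 4

    def test_read_with_no_table_hits_non_deconvolutable(self, tmp_path):
        design, clones, table, _ = build_overlap_fixture(tmp_path)
        ra = deconvolve_read("A" * 40, table, design, source_pool=0)
        assert ra.status == NON_DECONVOLUTABLE
        assert ra.clones == frozenset()


class TestPoolDriver:
    def test_summary_counts_match_output_files(self, clean_run):
        asn = clean_run.deconv.assignments
        summary = clean_run.deconv.summary
        assert summary["total"].sum() == len(asn)
        # summary splits equal recounts from the assignment table
        for j in (1, 2, 3):
            assert (
                summary[f"to_{j}"].sum()
                == ((asn["n_clones"] == j) & (asn["status"] == DECONVOLUTED)).sum()
            )
        # every read appears once per assigned clone or once in the ND file
        def count_reads(path):
            with open(path) as fh:
                return sum(1 for line in fh if line.startswith("@"))

        per_clone = sum(count_reads(p) for p in clean_run.deconv.clone_fastq.values())
        nd = count_reads(clean_run.deconv.non_deconvolutable_fastq)
        dec = asn[asn["status"] == DECONVOLUTED]
        assert per_clone == int(dec["n_clones"].sum())
        assert nd == int((asn["status"] == NON_DECONVOLUTABLE).sum())

    def test_pool_composition_respected(self, clean_run):
        """Deconvoluted clone sets always include a clone of the source pool."""
        design = clean_run.design
        ids = clean_run.layout.clone_ids
        members = {
            pool: {ids[int(i)] for i in items} for pool, items in design.members.items()
        }
        asn = clean_run.deconv.assignments
        dec = asn[asn["status"] == DECONVOLUTED]
        sample = dec.sample(n=2000, random_state=0)
        for rid, pool, clones in zip(sample["read_id"], sample["pool"], sample["clones"]):
            assert set(clones.split(";")) & members[pool], rid

    def test_signature_histogram_totals(self, noisy_run):
        hist = read_signature_histogram(noisy_run.deconv.assignments)
        with_kmers = (noisy_run.deconv.assignments["support_size"] > 0).sum()
        assert sum(hist.values()) == with_kmers

    def test_pool_count_mismatch_rejected(self, clean_run):
        with pytest.raises(ValueError, match="pool"):
            deconvolve_pools(
                clean_run.sim.pool_files[:-1],
                clean_run.table,
                clean_run.design,
                "/tmp/unused",
            )
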