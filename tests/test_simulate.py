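"""Synthetic genomes, clone tilings and pooled read simulation."""

from __future__ import annotations

import numpy as np
import pytest

from bacpool.design import DesignParams, construct_std
from bacpool.simulate import (
    CloneLayout,
    GenomeSpec,
    ReadSimParams,
    encode,
    generate_genome,
    layout_clones,
    parse_read_name,
    revcomp,
    simulate_pools,
)


class TestGenome:
    def test_length_and_determinism(self):
        spec = GenomeSpec(length=100_000, gc=0.44, seed=1)
        g1, g2 = generate_genome(spec), generate_genome(spec)
        assert len(g1) == 100_000
        assert g1 == g2

    def test_gc_close_to_requested(self):
        g = generate_genome(GenomeSpec(length=200_000, gc=0.44, seed=2))
        gc = (g.count("G") + g.count("C")) / len(g)
        assert gc == pytest.approx(0.44, abs=0.01)

    def test_repeat_copies_found_by_scan(self):
        """Brute-force similarity scan recovers all planted repeat copies."""
        spec = GenomeSpec(
            length=60_000, gc=0.5, repeat_families=((500, 10, 0.05),), seed=3
        )
        g = encode(generate_genome(spec))
        # recover one copy: diff against the same background without repeats
        g0 = encode(generate_genome(GenomeSpec(length=60_000, gc=0.5, seed=3)))
        changed = np.nonzero(g != g0)[0]
        assert changed.size > 0
        ref = g[int(changed[0]) : int(changed[0]) + 500]
        # slide it over the whole genome; two copies of the same unit at 5%
        # divergence are ~90% identical, background windows ~25%
        windows = np.lib.stride_tricks.sliding_window_view(g, 500)
        identity = (windows == ref).mean(axis=1)
        assert (identity >= 0.85).sum() >= 10

    def test_infeasible_repeats_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(GenomeSpec(length=1000, repeat_families=((600, 5, 0.0),)))


class TestLayout:
    def test_fixed_length_fixed_overlap(self):
        lay = layout_clones(10**6, 9, 120_000, 0, 10_000, 0, seed=1)
        assert len(lay.intervals) == 9
        for (c1, s1, e1), (c2, s2, e2) in zip(lay.intervals, lay.intervals[1:]):
            assert e1 - s2 == 10_000
            assert e1 - s1 == 120_000

    def test_zero_overlap_disjoint(self):
        lay = layout_clones(10**6, 8, 100_000, 0, 0, 0, seed=1)
        for (_, _, e1), (_, s2, _) in zip(lay.intervals, lay.intervals[1:]):
            assert s2 >= e1

    @pytest.mark.parametrize("seed", range(15))
    def test_random_layouts_satisfy_invariants(self, seed):
        lay = layout_clones(
            2_000_000, 12, 120_000, 8_000, 20_000, 5_000, seed=seed
        )
        # CloneLayout.__post_init__ enforces bounds and coverage <= 3
        assert len({cid for cid, _, _ in lay.intervals}) == 12
        for _, s, e in lay.intervals:
            assert 0 <= s < e <= 2_000_000

    def test_infeasible_tiling_rejected(self):
        with pytest.raises(ValueError):
            layout_clones(100_000, 10, 50_000, 0, 0, 0, seed=0)

    def test_overlap_graph_symmetric(self):
        lay = layout_clones(10**6, 9, 120_000, 0, 10_000, 0, seed=1)
        g = lay.overlap_graph()
        for a, nbrs in g.items():
            for b in nbrs:
                assert a in g[b]


class TestPoolSim:
    def test_error_free_reads_are_exact_substrings(self, tmp_path):
        design = construct_std(DesignParams(2, 1, 1, 1))
        genome = generate_genome(GenomeSpec(length=5_000, seed=5))
        lay = CloneLayout([("C0", 0, 5_000)], 5_000)
        params = ReadSimParams(
            read_length=50, insert_mean=150, insert_sd=10,
            error_rate=0.0, pairs_per_pool=10, seed=5,
        )
        res = simulate_pools(design, lay, genome, params, str(tmp_path))
        import pysam

        for r1_path, r2_path in res.pool_files:
            for path, orient in ((r1_path, "fwd"), (r2_path, "rev")):
                with pysam.FastxFile(path) as fh:
                    for rec in fh:
                        seq = rec.sequence if orient == "fwd" else revcomp(rec.sequence)
                        assert seq in genome
                        info = parse_read_name(rec.name)
                        frag = genome[info["start"] : info["end"]]
                        assert seq in frag

    def test_error_rate_matches_truth_alignment(self, tmp_path):
        design = construct_std(DesignParams(2, 1, 1, 1))
        genome = generate_genome(GenomeSpec(length=50_000, seed=6))
        lay = CloneLayout([("C0", 0, 50_000)], 50_000)
        params = ReadSimParams(error_rate=0.01, pairs_per_pool=2_000, seed=6)
        res = simulate_pools(design, lay, genome, params, str(tmp_path))
        import pysam

        mism = tot = 0
        r1_path, _ = res.pool_files[0]
        with pysam.FastxFile(r1_path) as fh:
            for rec in fh:
                info = parse_read_name(rec.name)
                truth = genome[info["start"] : info["start"] + len(rec.sequence)]
                mism += sum(a != b for a, b in zip(rec.sequence, truth))
                tot += len(rec.sequence)
        assert mism / tot == pytest.approx(0.01, abs=0.002)

    def test_rerun_byte_identical(self, tmp_path):
        design = construct_std(DesignParams(3, 2, 1, 4))
        genome = generate_genome(GenomeSpec(length=40_000, seed=7))
        lay = layout_clones(40_000, 4, 10_000, 0, 0, 0, seed=7)
        params = ReadSimParams(
            read_length=60, insert_mean=200, error_rate=0.01, pairs_per_pool=200, seed=8
        )
        res1 = simulate_pools(design, lay, genome, params, str(tmp_path / "a"))
        res2 = simulate_pools(design, lay, genome, params, str(tmp_path / "b"))
        for (a1, a2), (b1, b2) in zip(res1.pool_files, res2.pool_files):
            assert open(a1, "rb").read() == open(b1, "rb").read()
            assert open(a2, "rb").read() == open(b2, "rb").read()

    def test_reads_only_from_pool_members(self, clean_run):
        design = clean_run.design
        ids = clean_run.layout.clone_ids
        truth = clean_run.sim.truth
        members = {
            pool: {ids[int(i)] for i in items} for pool, items in design.members.items()
        }
        for pool, group in truth.groupby("pool"):
            assert set(group["clone_id"]) <= members[pool]

    def test_depth_budget_within_one_percent(self, clean_run):
        params = clean_run.params
        truth = clean_run.sim.truth
        lens = clean_run.layout.lengths()
        for pool, group in truth.groupby("pool"):
            content = sum(
                lens[cid]
                for cid in {
                    clean_run.layout.clone_ids[int(i)]
                    for i in clean_run.design.members[pool]
                }
            )
            bases = 2 * params.read_length * len(group)
            assert bases == pytest.approx(params.depth_per_pool * content, rel=0.01)

    def test_contaminant_fraction_flagged(self, tmp_path):
        # one clone per pool so every pool mixes clone and contaminant reads
        design = construct_std(DesignParams(2, 1, 1, 2))
        genome = generate_genome(GenomeSpec(length=20_000, seed=9))
        contam = generate_genome(GenomeSpec(length=30_000, gc=0.5, seed=10))
        lay = CloneLayout([("C0", 0, 10_000), ("C1", 10_000, 20_000)], 20_000)
        params = ReadSimParams(
            error_rate=0.0, pairs_per_pool=1_000, contaminant_fraction=0.4, seed=11
        )
        res = simulate_pools(
            design, lay, genome, params, str(tmp_path), contaminant=contam
        )
        frac = res.truth.groupby("pool")["is_contaminant"].mean()
        assert ((frac - 0.4).abs() < 0.01).all()

    def test_short_clone_skipped_with_warning(self, tmp_path, caplog):
        design = construct_std(DesignParams(2, 1, 1, 2))
        genome = generate_genome(GenomeSpec(length=10_000, seed=12))
        lay = CloneLayout([("C0", 0, 9_000), ("C1", 9_000, 9_050)], 10_000)
        params = ReadSimParams(error_rate=0.0, pairs_per_pool=50, seed=12)
        with caplog.at_level("WARNING"):
            res = simulate_pools(design, lay, genome, params, str(tmp_path))
        assert "C1" in caplog.text
        assert set(res.truth["clone_id"]) == {"C0"}
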