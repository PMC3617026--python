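"""Shared fixtures: small designs and two session-scoped simulated runs.

The simulated runs reproduce the package's reference validation
conditions: a 4-layer, 5-pools-per-layer design at full capacity (25
clones of 30 kb) sequenced to 30x per pool — once error-free with
disjoint clones, once with 1% substitution error and 10 kb overlaps.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pytest

from bacpool.deconvolve import DeconvolutionResult, deconvolve_pools
from bacpool.design import DesignParams, PoolingDesign, construct_std
from bacpool.kmers import KmerCountTable, build_count_table
from bacpool.simulate import (
    CloneLayout,
    GenomeSpec,
    ReadSimParams,
    SimResult,
    generate_genome,
    layout_clones,
    simulate_pools,
)


@pytest.fixture(scope="session")
def tiny_design() -> PoolingDesign:
    """Smallest exhaustively checkable design: 3 layers of 3 pools, 9 clones."""
    return construct_std(DesignParams(P=3, L=3, Gamma=1, n=9))


@pytest.fixture(scope="session")
def std_5_4() -> PoolingDesign:
    """The simulation-scale design: 4 layers of 5 pools, 25 clones."""
    return construct_std(DesignParams(P=5, L=4, Gamma=1, n=25))


@dataclass
class SimRun:
    design: PoolingDesign
    layout: CloneLayout
    genome: str
    params: ReadSimParams
    sim: SimResult
    table: KmerCountTable
    deconv: DeconvolutionResult


def _run(design, layout, genome, params, outdir) -> SimRun:
    sim = simulate_pools(design, layout, genome, params, os.path.join(outdir, "pools"))
    table = build_count_table(sim.pool_files, k=26)
    deconv = deconvolve_pools(
        sim.pool_files, table, design, os.path.join(outdir, "deconv"), layout.clone_ids
    )
    return SimRun(design, layout, genome, params, sim, table, deconv)


@pytest.fixture(scope="session")
def clean_run(std_5_4, tmp_path_factory) -> SimRun:
    """Error-free pools over disjoint 30 kb clones at 30x per pool."""
    genome = generate_genome(GenomeSpec(length=25 * 30_000, gc=0.44, seed=7))
    layout = layout_clones(len(genome), 25, 30_000, 0, 0, 0, seed=7)
    params = ReadSimParams(error_rate=0.0, depth_per_pool=30, seed=11)
    return _run(std_5_4, layout, genome, params, str(tmp_path_factory.mktemp("clean")))


@pytest.fixture(scope="session")
def noisy_run(std_5_4, tmp_path_factory) -> SimRun:
    """1% substitution error, consecutive clones overlapping by 10 kb."""
    glen = 25 * 30_000 - 24 * 10_000
    genome = generate_genome(GenomeSpec(length=glen, gc=0.44, seed=21))
    layout = layout_clones(glen, 25, 30_000, 0, 10_000, 0, seed=21)
    params = ReadSimParams(error_rate=0.01, depth_per_pool=30, seed=31)
    return _run(std_5_4, layout, genome, params, str(tmp_path_factory.mktemp("noisy")))
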