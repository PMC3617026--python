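"""Scoring deconvolution output against simulator truth.

A deconvoluted read is *correct* if its assigned clone set contains the
clone it was generated from, or any clone overlapping that clone in the
tiling (overlap sequence legitimately deconvolves to a neighbour).  Mate
concordance asks whether the two mates of a pair agree: one clone set
must contain the other; pairs with both mates unassigned are excluded
from the denominator, pairs with exactly one assigned mate count as
eligible but discordant.

Per-clone depth bookkeeping mirrors assembly preprocessing: a read
assigned to several clones contributes its bases to each of them (the
deconvolution deliberately amplifies coverage in overlaps), and clone
sizes may be estimated from restriction-fingerprint band counts via a
calibrated bases-per-band multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .deconvolve import DECONVOLUTED
from .simulate import CloneLayout


def _clone_sets(assignments: pd.DataFrame) -> pd.Series:
    return assignments["clones"].map(
        lambda s: frozenset(s.split(";")) if isinstance(s, str) and s else frozenset()
    )


def deconvolution_rate(assignments: pd.DataFrame) -> float:
    """Fraction of input reads assigned to 1-3 clones."""
    if len(assignments) == 0:
        raise ValueError("empty assignment table")
    return float((assignments["status"] == DECONVOLUTED).mean())


def correctness(
    assignments: pd.DataFrame, truth: pd.DataFrame, layout: CloneLayout
) -> float:
    """Overlap-aware correctness over deconvoluted reads.

    ``truth`` must map every assigned read_id (with mate suffix as emitted
    by the simulator, or bare ids matching the assignment table) to its
    source clone.
    """
    truth_map = dict(zip(truth["read_id"], truth["clone_id"]))
    overlaps = layout.overlap_graph()
    deconv = assignments[assignments["status"] == DECONVOLUTED]
    if len(deconv) == 0:
        raise ValueError("no deconvoluted reads to score")
    n_ok = 0
    for rid, clones in zip(deconv["read_id"], _clone_sets(deconv)):
        base = rid[:-2] if rid.endswith(("/1", "/2")) else rid
        src = truth_map.get(rid, truth_map.get(base))
        if src is None:
            raise KeyError(f"read {rid!r} missing from truth table")
        if src in clones or clones & overlaps.get(src, set()):
            n_ok += 1
    return n_ok / len(deconv)


def mate_concordance(assignments: pd.DataFrame) -> float:
    """Fraction of eligible read pairs whose mate clone sets are nested.

    Concordant iff both mates are assigned and ``|B_l ∩ B_r| =
    min(|B_l|, |B_r|)``.  Eligible pairs have at least one assigned mate.
    """
    sets = _clone_sets(assignments)
    mates: dict[str, list[frozenset | None]] = {}
    for rid, clones in zip(assignments["read_id"], sets):
        if not rid.endswith(("/1", "/2")):
            raise ValueError(f"read id {rid!r} lacks a /1 or /2 mate suffix")
        base, mate = rid[:-2], int(rid[-1])
        mates.setdefault(base, [None, None])[mate - 1] = clones
    eligible = 0
    concordant = 0
    for base, (left, right) in mates.items():
        if left is None or right is None:
            raise ValueError(f"pair {base!r} is missing a mate record")
        if not left and not right:
            continue
        eligible += 1
        if left and right and len(left & right) == min(len(left), len(right)):
            concordant += 1
    if eligible == 0:
        raise ValueError("no eligible pairs (all pairs fully unassigned)")
    return concordant / eligible


def calibrate_band_multiplier(
    band_counts: Iterable[float], assumed_mean_length: float
) -> float:
    """Bases-per-band multiplier so the mean estimated clone size equals
    ``assumed_mean_length`` over the fingerprinted library."""
    counts = np.asarray(list(band_counts), dtype=float)
    if counts.size == 0:
        raise ValueError("empty band-count list")
    if assumed_mean_length <= 0:
        raise ValueError("assumed_mean_length must be positive")
    return float(assumed_mean_length / counts.mean())


def estimate_clone_size(band_count: float, multiplier: float) -> float:
    """Estimated clone length in bases from its fingerprint band count."""
    if band_count <= 0:
        raise ValueError("band_count must be positive")
    return float(band_count * multiplier)


def per_clone_depth(
    assignments: pd.DataFrame,
    read_lengths: Mapping[str, int] | int,
    sizes: Mapping[str, float],
) -> pd.DataFrame:
    """Per-clone read/base totals and expected coverage.

    ``read_lengths`` is either a read_id -> length mapping or a constant.
    A read assigned to several clones contributes its bases to each.
    Coverage = assigned bases / clone size (the expected-coverage input of
    a per-clone assembler).
    """
    reads: dict[str, int] = {}
    bases: dict[str, int] = {}
    deconv = assignments[assignments["status"] == DECONVOLUTED]
    for rid, clones in zip(deconv["read_id"], _clone_sets(deconv)):
        rl = read_lengths if isinstance(read_lengths, int) else read_lengths[rid]
        for cid in clones:
            reads[cid] = reads.get(cid, 0) + 1
            bases[cid] = bases.get(cid, 0) + rl
    rows = []
    for cid in sorted(reads):
        if cid not in sizes:
            raise KeyError(f"no size available for clone {cid!r}")
        rows.append(
            {
                "clone_id": cid,
                "reads": reads[cid],
                "bases": bases[cid],
                "size": sizes[cid],
                "coverage": bases[cid] / sizes[cid],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Bundle of the quality metrics for one deconvolution run."""

    deconvolution_rate: float
    correctness_rate: float
    mate_concordance: float
    depth: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "deconvolution_rate": self.deconvolution_rate,
            "correctness_rate": self.correctness_rate,
            "mate_concordance": self.mate_concordance,
            "mean_coverage": float(self.depth["coverage"].mean()) if len(self.depth) else float("nan"),
        }


def evaluate_run(
    assignments: pd.DataFrame,
    truth: pd.DataFrame,
    layout: CloneLayout,
    read_length: int,
) -> EvalReport:
    """Compute the full report for a simulated run (true sizes from the layout)."""
    sizes = {cid: float(l) for cid, l in layout.lengths().items()}
    return EvalReport(
        deconvolution_rate=deconvolution_rate(assignments),
        correctness_rate=correctness(assignments, truth, layout),
        mate_concordance=mate_concordance(assignments),
        depth=per_clone_depth(assignments, read_length, sizes),
    )
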