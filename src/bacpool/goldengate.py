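"""Decoding pool-level marker presence calls to clone assignments.

A multiplexed genotyping assay run on the pools yields, for each marker
(unigene), a binary presence call per pool.  If the marker lies on clone
set T, its positive-pool set S should be the union P(T) of those clones'
signatures; assay noise flips individual calls.  The decoder searches all
clone subsets T of size 1..3 and minimizes

    E(T) = |P(T) \\ S|  (extra observations)  +  |S \\ P(T)|  (missing),

declaring the marker *non-decodable* when the minimum exceeds the error
cap (default 3).  The search is restricted to candidate clones sharing at
least ``L - error_cap`` pools with S: a clone below that bound would by
itself contribute more than ``error_cap`` extra observations, so it can
never appear in a solution with E <= error_cap; restricted and
unrestricted searches therefore agree on every decodable marker.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deconvolve import get_index
from .design import PoolingDesign

#: error_count reported for markers with an empty positive-pool set
UNDEFINED_ERROR = -1


@dataclass
class OPACalls:
    """Binary marker x pool presence matrix."""

    matrix: np.ndarray  # (n_markers, n_pools) of {0, 1}
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or len(self.marker_ids) != self.matrix.shape[0]:
            raise ValueError("matrix shape does not match marker ids")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("calls must be binary")

    @classmethod
    def read_tsv(cls, path) -> "OPACalls":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(matrix=df.to_numpy(), marker_ids=[str(i) for i in df.index])

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.matrix,
            index=pd.Index(self.marker_ids, name="marker"),
            columns=[f"pool_{p}" for p in range(self.matrix.shape[1])],
        )
        df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class MarkerAssignment:
    """Decoding outcome for one marker."""

    marker_id: str
    clones: tuple[int, ...]
    error_count: int
    decodable: bool


def decode_marker(
    S: frozenset[int] | set[int],
    design: PoolingDesign,
    max_set_size: int = 3,
    error_cap: int = 3,
    marker_id: str = "marker",
) -> MarkerAssignment:
    """Error-minimizing clone assignment for one positive-pool set.

    Ties break by smaller clone-set size, then lexicographically by clone
    index; an empty S is non-decodable with a sentinel error count.
    """
    idx = get_index(design)
    if any(not 0 <= p < idx.n_pools for p in S):
        raise ValueError("positive pool index outside the design")
    if not S:
        return MarkerAssignment(marker_id, (), UNDEFINED_ERROR, False)
    smask = 0
    for p in S:
        smask |= 1 << p
    cands = [
        c
        for c in range(idx.n)
        if bin(idx.sig_masks[c] & smask).count("1") >= idx.L - error_cap
    ]
    best_err = None
    best_T: tuple[int, ...] = ()
    for size in range(1, max_set_size + 1):
        for T in itertools.combinations(cands, size):
            pmask = 0
            for c in T:
                pmask |= idx.sig_masks[c]
            err = bin(pmask ^ smask).count("1")
            if best_err is None or err < best_err:
                best_err, best_T = err, T
        if best_err == 0:
            break  # no larger set can do better; smaller-set tie-break holds
    if best_err is None:  # no candidate clone at all
        best_err = len(S) + idx.L  # >= any achievable bound; certainly > cap
    decodable = best_err <= error_cap and len(best_T) > 0
    return MarkerAssignment(
        marker_id, best_T if decodable else (), int(best_err), decodable
    )


def decode_all(
    calls: OPACalls,
    design: PoolingDesign,
    max_set_size: int = 3,
    error_cap: int = 3,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Decode every marker; returns the assignment table and an E histogram."""
    idx = get_index(design)
    if calls.matrix.shape[1] != idx.n_pools:
        raise ValueError(
            f"calls have {calls.matrix.shape[1]} pool columns, design has {idx.n_pools}"
        )
    rows = []
    hist: dict[int, int] = {}
    for mid, row in zip(calls.marker_ids, calls.matrix):
        S = frozenset(int(p) for p in np.nonzero(row)[0])
        ma = decode_marker(S, design, max_set_size=max_set_size, error_cap=error_cap, marker_id=mid)
        hist[ma.error_count] = hist.get(ma.error_count, 0) + 1
        rows.append(
            {
                "marker": mid,
                "clones": ";".join(str(c) for c in ma.clones),
                "error_count": ma.error_count,
                "decodable": ma.decodable,
            }
        )
    return pd.DataFrame(rows), hist


def simulate_calls(
    design: PoolingDesign,
    n_markers: int,
    max_clones: int = 3,
    n_flips: int = 0,
    seed: int = 0,
) -> tuple[OPACalls, list[tuple[int, ...]]]:
    """Plant markers on random clone sets and flip calls at random.

    Each marker sits on 1..``max_clones`` random clones; its call row is
    the union of their signatures with exactly ``n_flips`` random bits
    flipped.  Returns the calls and the planted clone sets (sorted).
    """
    idx = get_index(design)
    rng = np.random.default_rng(seed)
    matrix = np.zeros((n_markers, idx.n_pools), dtype=np.int8)
    planted = []
    for m in range(n_markers):
        size = int(rng.integers(1, max_clones + 1))
        T = tuple(sorted(int(c) for c in rng.choice(idx.n, size=size, replace=False)))
        row = np.zeros(idx.n_pools, dtype=np.int8)
        for c in T:
            row[list(idx.sig_sets[c])] = 1
        if n_flips:
            flips = rng.choice(idx.n_pools, size=n_flips, replace=False)
            row[flips] ^= 1
        matrix[m] = row
        planted.append(T)
    ids = [f"marker_{m:04d}" for m in range(n_markers)]
    return OPACalls(matrix=matrix, marker_ids=ids), planted
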