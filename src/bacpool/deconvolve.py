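"""Read-to-clone deconvolution from pooled k-mer count vectors.

Every k-mer of a read is looked up in the per-pool count table; the set
of pools where it occurs (its *support*) is compared against clone
signatures and their 2- and 3-fold unions.  With L layers and collision
bound Gamma the valid support sizes are:

* single clone: ``L`` exactly, or ``[L - Gamma, L)`` when up to Gamma
  observations are missing (low coverage or a dropped pool) — the support
  must then be a subset of exactly one signature, which is unique because
  two signatures share at most Gamma pools;
* two overlapping clones: ``[2L - Gamma, 2L]`` and the support must equal
  a union of two signatures;
* three overlapping clones: ``[3L - 3*Gamma, 3L]``, equality with a
  3-union.

Supports slightly above a valid range (spurious extra pools from
sequencing errors) are retried after dropping the smallest counts — never
the count of the pool the read came from, which genuinely contains the
k-mer.  Supports below ``L - Gamma`` are discarded as error artifacts and
supports above ``3L`` as highly repetitive sequence.

A read is then assigned to the union B of its k-mers' clone sets iff
``1 <= |B| <= 3``; otherwise it is *non-deconvolutable*.  Mates of a pair
are treated as independent single-end reads.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .design import PoolingDesign
from .kmers import KmerCountTable, _window_codes
from .simulate import _CODE_LUT

# k-mer statuses
ERROR_DISCARD = "error_discard"
ASSIGNED = "assigned"
UNMATCHED = "unmatched"
REPEAT_DISCARD = "repeat_discard"
# read statuses
DECONVOLUTED = "deconvoluted"
NON_DECONVOLUTABLE = "non_deconvolutable"

_S_ERROR, _S_ASSIGNED, _S_UNMATCHED, _S_REPEAT, _S_DEFER = range(5)


@dataclass(frozen=True)
class KmerAssignment:
    """Outcome of classifying one k-mer's count vector."""

    status: str
    clones: frozenset[int]
    matched_support: frozenset[int]


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome of deconvolving one read."""

    read_id: str
    status: str
    clones: frozenset[int]
    source_pool: int
    support_size: int


class DesignIndex:
    """Precomputed signature sets/masks and classifier thresholds for a design."""

    def __init__(self, design: PoolingDesign):
        p = design.params
        self.design = design
        self.n = p.n
        self.n_pools = p.n_pools
        self.L = p.L
        self.Gamma = p.Gamma
        self.sig_sets = [design.signature_set(i) for i in range(p.n)]
        self.sig_masks = design.pool_masks()
        # minimum support for the subset (missing-observation) single-clone
        # case; kept above Gamma so that the containing signature is unique
        self.min_subset = max(p.L - p.Gamma, p.Gamma + 1)
        self.lo2 = 2 * p.L - p.Gamma
        self.hi2 = 2 * p.L
        self.lo3 = 3 * p.L - 3 * p.Gamma
        self.hi3 = 3 * p.L


def get_index(design: PoolingDesign) -> DesignIndex:
    idx = getattr(design, "_deconv_index", None)
    if idx is None or idx.design is not design:
        idx = DesignIndex(design)
        design._deconv_index = idx
    return idx


def candidate_clones(support: frozenset[int] | set[int], design: PoolingDesign) -> list[int]:
    """Clones whose full signature is contained in ``support``."""
    idx = get_index(design)
    mask = 0
    for p in support:
        if not 0 <= p < idx.n_pools:
            raise ValueError(f"pool index {p} outside [0, {idx.n_pools})")
        mask |= 1 << p
    return [c for c in range(idx.n) if idx.sig_masks[c] & ~mask == 0]


def _match_support(
    support_mask: int, w: int, idx: DesignIndex
) -> tuple[frozenset[int], int] | None:
    """Exact matcher for a support already inside a valid size range.

    Returns (clones, matched pool mask) or None.  Single-clone supports of
    size >= min_subset may be a strict subset of the (then unique)
    signature; 2- and 3-unions must match exactly.
    """
    cands = [c for c in range(idx.n) if idx.sig_masks[c] & ~support_mask == 0]
    if idx.min_subset <= w <= idx.L:
        containing = [
            c for c in range(idx.n) if support_mask & ~idx.sig_masks[c] == 0
        ]
        if len(containing) == 1:
            c = containing[0]
            return frozenset([c]), idx.sig_masks[c]
    if idx.lo2 <= w <= idx.hi2:
        for a, b in itertools.combinations(cands, 2):
            if idx.sig_masks[a] | idx.sig_masks[b] == support_mask:
                return frozenset([a, b]), support_mask
    if idx.lo3 <= w <= idx.hi3:
        for a, b, c in itertools.combinations(cands, 3):
            if idx.sig_masks[a] | idx.sig_masks[b] | idx.sig_masks[c] == support_mask:
                return frozenset([a, b, c]), support_mask
    return None


def _drop_smallest(
    pools: np.ndarray, counts: np.ndarray, keep: int, source_pool: int
) -> int:
    """Support mask after dropping all but ``keep`` entries, smallest counts
    first (ties to the lower pool index), never dropping ``source_pool``."""
    order = sorted(range(len(pools)), key=lambda i: (int(counts[i]), int(pools[i])))
    drop = len(pools) - keep
    mask = 0
    dropped = 0
    for i in order:
        if dropped < drop and int(pools[i]) != source_pool:
            dropped += 1
            continue
        mask |= 1 << int(pools[i])
    return mask


def _classify_entries(
    pools: np.ndarray, counts: np.ndarray, idx: DesignIndex, source_pool: int
) -> KmerAssignment:
    w = len(pools)
    L = idx.L
    if w < idx.min_subset:
        return KmerAssignment(ERROR_DISCARD, frozenset(), frozenset())
    if w > idx.hi3:
        return KmerAssignment(REPEAT_DISCARD, frozenset(), frozenset())
    mask = 0
    for p in pools:
        mask |= 1 << int(p)
    target = None
    if L < w < idx.lo2:
        target = L
    elif idx.hi2 < w < idx.lo3:
        target = 2 * L
    if target is not None:
        mask = _drop_smallest(pools, counts, target, source_pool)
        w = target
    hit = _match_support(mask, w, idx)
    if hit is None:
        return KmerAssignment(UNMATCHED, frozenset(), frozenset())
    clones, matched = hit
    return KmerAssignment(ASSIGNED, clones, _mask_to_set(matched))


def _mask_to_set(mask: int) -> frozenset[int]:
    out = set()
    i = 0
    while mask:
        if mask & 1:
            out.add(i)
        mask >>= 1
        i += 1
    return frozenset(out)


def classify_kmer(
    cv: np.ndarray, design: PoolingDesign, source_pool: int
) -> KmerAssignment:
    """Classify one dense per-pool count vector (see module docstring)."""
    idx = get_index(design)
    cv = np.asarray(cv)
    if cv.size != idx.n_pools:
        raise ValueError(f"count vector length {cv.size} != n_pools {idx.n_pools}")
    if cv[source_pool] <= 0:
        raise ValueError(f"source pool {source_pool} has zero count")
    pools = np.nonzero(cv)[0]
    return _classify_entries(pools, cv[pools], idx, source_pool)


# ---------------------------------------------------------------------------
# batch machinery


class _TableClassifier:
    """Classify every distinct k-mer of a table once, deferring the
    count-order-dependent drop cases to per-(row, source pool) lookups."""

    def __init__(self, table: KmerCountTable, design: PoolingDesign):
        idx = get_index(design)
        if table.n_pools != idx.n_pools:
            raise ValueError(
                f"table has {table.n_pools} pools but design has {idx.n_pools}"
            )
        self.table = table
        self.idx = idx
        w = table.support_sizes()
        status = np.full(table.n_kmers, _S_DEFER, dtype=np.uint8)
        status[w < idx.min_subset] = _S_ERROR
        status[w > idx.hi3] = _S_REPEAT
        exact = (
            ((w >= idx.min_subset) & (w <= idx.L))
            | ((w >= idx.lo2) & (w <= idx.hi2))
            | ((w >= idx.lo3) & (w <= idx.hi3))
        )
        clone_masks = np.zeros(table.n_kmers, dtype=np.uint64)
        clone_sets: dict[int, frozenset[int]] = {}
        rows = np.nonzero(exact)[0]
        if rows.size:
            # support masks of all rows at once (one pool entry per nnz)
            bit = np.uint64(1) << table.pools.astype(np.uint64)
            row_masks = np.bitwise_or.reduceat(bit, table.indptr[:-1])
            masks = row_masks[rows]
            uniq_masks = np.unique(masks)
            u_status = np.empty(uniq_masks.size, dtype=np.uint8)
            u_cmask = np.zeros(uniq_masks.size, dtype=np.uint64)
            for j, m in enumerate(uniq_masks):
                hit = _match_support(int(m), bin(int(m)).count("1"), idx)
                if hit is None:
                    u_status[j] = _S_UNMATCHED
                else:
                    cmask = 0
                    for c in hit[0]:
                        cmask |= 1 << c
                    u_status[j] = _S_ASSIGNED
                    u_cmask[j] = cmask
                    clone_sets[cmask] = hit[0]
            pos = np.searchsorted(uniq_masks, masks)
            status[rows] = u_status[pos]
            clone_masks[rows] = u_cmask[pos]
        self.status = status
        self.clone_masks = clone_masks
        self.clone_sets = clone_sets
        self._defer_memo: dict[tuple[int, int], tuple[int, int]] = {}

    def resolve_deferred(self, row: int, source_pool: int) -> tuple[int, int]:
        """(status, clone mask) for a drop-case row as seen from one pool."""
        key = (row, source_pool)
        hit = self._defer_memo.get(key)
        if hit is None:
            pools, counts = self.table.row(row)
            ka = _classify_entries(pools, counts, self.idx, source_pool)
            if ka.status == ASSIGNED:
                cmask = 0
                for c in ka.clones:
                    cmask |= 1 << c
                hit = (_S_ASSIGNED, cmask)
                self.clone_sets.setdefault(cmask, ka.clones)
            else:
                hit = (_S_UNMATCHED, 0)
            self._defer_memo[key] = hit
        return hit


def _read_windows(seqs: list[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical window codes of many reads plus the read index per window."""
    sep = np.array([255], dtype=np.uint8)
    chunks = []
    seg_lens = np.empty(len(seqs), dtype=np.int64)
    for i, s in enumerate(seqs):
        chunks.append(_CODE_LUT[np.frombuffer(s.encode(), dtype=np.uint8)])
        chunks.append(sep)
        seg_lens[i] = len(s) + 1
    arr = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint8)
    canon, valid = _window_codes(arr, k)
    # window at concatenated position p starts inside read i iff p falls in
    # read i's segment; invalid windows (crossing a separator) are masked out
    owner = np.repeat(np.arange(len(seqs), dtype=np.int64), seg_lens)[: valid.size]
    return canon, owner[valid]


def deconvolve_read(
    read: str,
    table: KmerCountTable,
    design: PoolingDesign,
    source_pool: int,
    read_id: str = "read",
) -> ReadAssignment:
    """Deconvolve a single read (reference path; the pool driver is batched)."""
    idx = get_index(design)
    canon, _ = _read_windows([read], table.k)
    rows = table.lookup(canon)
    clones: set[int] = set()
    for r in np.unique(rows[rows >= 0]):
        pools, counts = table.row(int(r))
        ka = _classify_entries(pools, counts, idx, source_pool)
        if ka.status == ASSIGNED:
            clones |= ka.clones
    support = frozenset().union(*(idx.sig_sets[c] for c in clones)) if clones else frozenset()
    status = DECONVOLUTED if 1 <= len(clones) <= 3 else NON_DECONVOLUTABLE
    return ReadAssignment(read_id, status, frozenset(clones), source_pool, len(support))


@dataclass
class DeconvolutionResult:
    """Outputs of :func:`deconvolve_pools`."""

    assignments: pd.DataFrame
    summary: pd.DataFrame
    clone_fastq: dict[str, str]
    non_deconvolutable_fastq: str


def deconvolve_pools(
    pool_files: Sequence[str | Sequence[str]],
    table: KmerCountTable,
    design: PoolingDesign,
    outdir: str,
    clone_ids: Sequence[str] | None = None,
) -> DeconvolutionResult:
    """Deconvolve every read of every pool.

    Each input read lands either in the FASTQ of each clone it was
    assigned to (1-3 files) or in the non-deconvolutable FASTQ.  Returns
    the per-read assignment table and a per-pool summary with columns
    pool, total, to_1, to_2, to_3, pct_deconvoluted.
    """
    idx = get_index(design)
    if len(pool_files) != table.n_pools:
        raise ValueError(
            f"{len(pool_files)} pool files for a table over {table.n_pools} pools"
        )
    if clone_ids is None:
        clone_ids = [f"clone_{i}" for i in range(idx.n)]
    if idx.n > 64 or idx.n_pools > 64:
        raise NotImplementedError(
            "batched deconvolution uses 64-bit clone/pool masks; designs beyond "
            "64 clones or 64 pools are supported k-mer-by-k-mer via classify_kmer"
        )
    clf = _TableClassifier(table, design)
    sig_mask_arr = np.array(idx.sig_masks, dtype=np.uint64)

    os.makedirs(outdir, exist_ok=True)
    clone_paths = {cid: os.path.join(outdir, f"{cid}.fastq") for cid in clone_ids}
    clone_buffers: dict[int, list[str]] = {c: [] for c in range(idx.n)}
    nd_path = os.path.join(outdir, "non_deconvolutable.fastq")
    nd_buffer: list[str] = []

    frames = []
    summary_rows = []
    for pool, entry in enumerate(pool_files):
        paths = [entry] if isinstance(entry, (str, os.PathLike)) else list(entry)
        names: list[str] = []
        seqs: list[str] = []
        quals: list[str] = []
        for path in paths:
            with pysam.FastxFile(path) as fh:
                for rec in fh:
                    names.append(rec.name)
                    seqs.append(rec.sequence)
                    quals.append(rec.quality or "I" * len(rec.sequence))
        canon, read_idx = _read_windows(seqs, table.k)
        rows = table.lookup(canon)
        present = rows >= 0
        rows_p, read_idx_p = rows[present], read_idx[present]
        status = clf.status[rows_p]
        cmask = clf.clone_masks[rows_p].copy()
        defer = status == _S_DEFER
        if defer.any():
            for r in np.unique(rows_p[defer]):
                st, cm = clf.resolve_deferred(int(r), pool)
                sel = rows_p == r
                status[sel] = st
                cmask[sel] = cm
        cmask[status != _S_ASSIGNED] = 0
        union = np.zeros(len(seqs), dtype=np.uint64)
        np.bitwise_or.at(union, read_idx_p, cmask)
        n_clones = np.bitwise_count(union)
        deconv = (n_clones >= 1) & (n_clones <= 3)

        # group reads by their clone-set mask: few distinct sets occur, so
        # labels, signature unions and output routing are computed per group
        recs = [
            f"@{names[i]}\n{seqs[i]}\n+\n{quals[i]}\n" for i in range(len(names))
        ]
        supp_size = np.zeros(len(seqs), dtype=np.int64)
        clone_lists = np.full(len(seqs), "", dtype=object)
        for um in np.unique(union):
            sel = np.nonzero(union == um)[0]
            members = sorted(_mask_to_set(int(um)))
            smask = 0
            for c in members:
                smask |= int(sig_mask_arr[c])
            supp_size[sel] = bin(smask).count("1")
            group = [recs[i] for i in sel]
            if 1 <= len(members) <= 3:
                clone_lists[sel] = ";".join(clone_ids[c] for c in members)
                for c in members:
                    clone_buffers[c].extend(group)
            else:
                nd_buffer.extend(group)
        frames.append(
            pd.DataFrame(
                {
                    "read_id": names,
                    "pool": pool,
                    "status": np.where(deconv, DECONVOLUTED, NON_DECONVOLUTABLE),
                    "clones": clone_lists,
                    "n_clones": n_clones.astype(np.int64),
                    "support_size": supp_size,
                }
            )
        )
        total = len(seqs)
        to = [int(((n_clones == j) & deconv).sum()) for j in (1, 2, 3)]
        summary_rows.append(
            {
                "pool": pool,
                "total": total,
                "to_1": to[0],
                "to_2": to[1],
                "to_3": to[2],
                "pct_deconvoluted": 100.0 * sum(to) / total if total else 0.0,
            }
        )

    for c, buf in clone_buffers.items():
        with open(clone_paths[clone_ids[c]], "w") as fh:
            fh.write("".join(buf))
    with open(nd_path, "w") as fh:
        fh.write("".join(nd_buffer))
    assignments = pd.concat(frames, ignore_index=True)
    summary = pd.DataFrame(summary_rows)
    return DeconvolutionResult(
        assignments=assignments,
        summary=summary,
        clone_fastq=clone_paths,
        non_deconvolutable_fastq=nd_path,
    )


def read_signature_histogram(assignments: pd.DataFrame) -> dict[int, int]:
    """Histogram of read-signature sizes (reads with >= 1 assigned k-mer)."""
    w = assignments.loc[assignments["support_size"] > 0, "support_size"]
    counts = np.bincount(w.to_numpy())
    return {int(x): int(c) for x, c in enumerate(counts) if c > 0}
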