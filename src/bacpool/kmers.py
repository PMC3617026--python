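"""Per-pool canonical k-mer occurrence tables.

The deconvolution signal is, for every distinct k-mer, the vector of its
occurrence counts across all L*P pools.  A k-mer and its reverse
complement are counted together under the *canonical* form (the
lexicographically smaller of the two); windows containing non-ACGT
symbols are skipped.

k-mers are packed 2 bits per base into uint64 codes (k <= 31), and the
table is stored column-sparse: a sorted array of distinct canonical codes
plus, per code, the (pool, count) pairs with count > 0.  This keeps the
memory of error-rich datasets proportional to the number of *observed*
(k-mer, pool) pairs rather than ``distinct k-mers x pools``.

The default k of 26 is chosen by a pigeonhole argument: two reads
overlapping by 78 bases with at most two mismatches must share an exact
run of at least ceil((78-2)/3) = 26 bases, so a 26-mer table can detect
any such overlap (:func:`guaranteed_exact_match_length`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam

from .simulate import _CODE_LUT

DEFAULT_K = 26
COUNT_CAP = 2**16 - 1  # counts saturate; only positivity/relative size matter


def canonical(kmer: str) -> str:
    """Canonical form: lexicographic min of a k-mer and its reverse complement."""
    codes = _CODE_LUT[np.frombuffer(kmer.upper().encode(), dtype=np.uint8)]
    if (codes > 3).any():
        raise ValueError(f"k-mer contains non-ACGT symbols: {kmer!r}")
    rc = (3 - codes)[::-1]
    for a, b in zip(codes, rc):
        if a < b:
            return kmer.upper()
        if b < a:
            return decode_code(pack_codes(rc), len(kmer))
    return kmer.upper()  # palindromic


def pack_codes(codes: np.ndarray) -> int:
    val = 0
    for c in codes:
        val = (val << 2) | int(c)
    return val


def decode_code(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append("ACGT"[(code >> shift) & 3])
    return "".join(out)


def guaranteed_exact_match_length(overlap_length: int, max_mismatches: int) -> int:
    """Largest m such that any <= ``max_mismatches`` mismatches in an
    ``overlap_length``-base overlap leave an exact run of >= m bases.

    Closed form ``ceil((overlap_length - max_mismatches) / (max_mismatches + 1))``:
    the mismatches cut the overlap into ``max_mismatches + 1`` exact
    segments and the adversary equalizes them.
    """
    if max_mismatches < 0 or overlap_length <= max_mismatches:
        raise ValueError("need overlap_length > max_mismatches >= 0")
    return -(-(overlap_length - max_mismatches) // (max_mismatches + 1))


def _window_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes of all valid k-windows of a concatenated code array.

    ``arr`` holds base codes 0..3 with 255 marking invalid symbols and
    read boundaries.  Returns (canonical uint64 codes, window validity mask
    already applied).
    """
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    invalid = (arr > 3).astype(np.int64)
    bad = np.cumsum(invalid)
    win_bad = bad[k - 1 :].copy()
    win_bad[1:] -= bad[: n - k]
    valid = win_bad == 0
    safe = np.where(arr > 3, 0, arr).astype(np.uint64)
    comp = np.uint64(3) - safe
    n_win = n - k + 1
    canon = np.empty(n_win, dtype=np.uint64)
    chunk = 1 << 18  # keep the k rolling passes in cache
    for lo in range(0, n_win, chunk):
        hi = min(lo + chunk, n_win)
        fwd = np.zeros(hi - lo, dtype=np.uint64)
        rev = np.zeros(hi - lo, dtype=np.uint64)
        for c in range(k):
            fwd = (fwd << np.uint64(2)) | safe[lo + c : hi + c]
            rev |= comp[lo + c : hi + c] << np.uint64(2 * c)
        canon[lo:hi] = np.minimum(fwd, rev)
    return canon[valid], valid


def _read_pool_codes(paths: Sequence[str], k: int) -> np.ndarray:
    """Concatenate all reads of one pool's FASTQ file(s) into a code array."""
    chunks: list[np.ndarray] = []
    sep = np.array([255], dtype=np.uint8)
    for path in paths:
        if not os.path.exists(path):
            raise FileNotFoundError(f"pool FASTQ not found: {path}")
        with pysam.FastxFile(path) as fh:
            for rec in fh:
                chunks.append(_CODE_LUT[np.frombuffer(rec.sequence.encode(), dtype=np.uint8)])
                chunks.append(sep)
    if not chunks:
        return np.empty(0, dtype=np.uint8)
    return np.concatenate(chunks)


def count_pool(paths: str | Sequence[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Distinct canonical k-mer codes and their counts for one pool."""
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    arr = _read_pool_codes(paths, k)
    canon, _ = _window_codes(arr, k)
    codes, counts = np.unique(canon, return_counts=True)
    return codes, np.minimum(counts, COUNT_CAP)


def merge_pool_counts(
    a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Merge two (codes, counts) runs of the *same* pool (saturating add)."""
    codes = np.concatenate([a[0], b[0]])
    counts = np.concatenate([a[1], b[1]])
    order = np.argsort(codes, kind="stable")
    codes, counts = codes[order], counts[order]
    uniq, start = np.unique(codes, return_index=True)
    sums = np.add.reduceat(counts.astype(np.int64), start)
    return uniq, np.minimum(sums, COUNT_CAP)


@dataclass
class KmerCountTable:
    """Column-sparse canonical k-mer -> per-pool count table.

    ``codes`` is sorted; row i of the table holds entries
    ``pools[indptr[i]:indptr[i+1]]`` / ``counts[indptr[i]:indptr[i+1]]``.
    """

    k: int
    n_pools: int
    codes: np.ndarray  # (n_kmers,) uint64, sorted
    indptr: np.ndarray  # (n_kmers + 1,) int64
    pools: np.ndarray  # (nnz,) int32
    counts: np.ndarray  # (nnz,) uint16-compatible

    FORMAT_VERSION = 1

    @property
    def n_kmers(self) -> int:
        return self.codes.size

    def support_sizes(self) -> np.ndarray:
        """w (number of pools with count > 0) for every stored k-mer."""
        return np.diff(self.indptr)

    def lookup(self, query: np.ndarray) -> np.ndarray:
        """Row indices of query codes; -1 where absent."""
        idx = np.searchsorted(self.codes, query)
        idx[idx >= self.codes.size] = 0 if self.codes.size else 0
        if self.codes.size == 0:
            return np.full(query.shape, -1, dtype=np.int64)
        hit = self.codes[idx] == query
        return np.where(hit, idx, -1)

    def row(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        s, e = self.indptr[i], self.indptr[i + 1]
        return self.pools[s:e], self.counts[s:e]

    def vector(self, kmer: str) -> np.ndarray:
        """Dense per-pool count vector of one k-mer (canonicalized); zeros if absent."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        code = np.array([pack_codes(_CODE_LUT[np.frombuffer(canonical(kmer).encode(), dtype=np.uint8)])], dtype=np.uint64)
        out = np.zeros(self.n_pools, dtype=np.int64)
        i = int(self.lookup(code)[0])
        if i >= 0:
            pools, counts = self.row(i)
            out[pools] = counts
        return out

    def save(self, path: str) -> None:
        np.savez_compressed(
            path,
            version=np.int64(self.FORMAT_VERSION),
            k=np.int64(self.k),
            n_pools=np.int64(self.n_pools),
            codes=self.codes,
            indptr=self.indptr,
            pools=self.pools,
            counts=self.counts,
        )

    @classmethod
    def load(cls, path: str) -> "KmerCountTable":
        with np.load(path) as z:
            if int(z["version"]) != cls.FORMAT_VERSION:
                raise ValueError(f"unsupported table version {int(z['version'])}")
            return cls(
                k=int(z["k"]),
                n_pools=int(z["n_pools"]),
                codes=z["codes"],
                indptr=z["indptr"],
                pools=z["pools"],
                counts=z["counts"],
            )

    def to_tsv(self, path: str, limit: int | None = None) -> None:
        """Plain-text export: kmer, then one count column per pool."""
        with open(path, "w") as fh:
            fh.write("kmer\t" + "\t".join(f"pool_{p}" for p in range(self.n_pools)) + "\n")
            n = self.n_kmers if limit is None else min(limit, self.n_kmers)
            for i in range(n):
                dense = np.zeros(self.n_pools, dtype=np.int64)
                pools, counts = self.row(i)
                dense[pools] = counts
                fh.write(decode_code(int(self.codes[i]), self.k) + "\t" + "\t".join(map(str, dense)) + "\n")


def assemble_table(
    per_pool: Iterable[tuple[np.ndarray, np.ndarray]], k: int, n_pools: int
) -> KmerCountTable:
    """Combine per-pool (codes, counts) runs into one sparse table."""
    code_parts, pool_parts, count_parts = [], [], []
    for pool, (codes, counts) in enumerate(per_pool):
        code_parts.append(codes)
        pool_parts.append(np.full(codes.size, pool, dtype=np.int32))
        count_parts.append(counts)
    if pool_parts and len(pool_parts) != n_pools:
        raise ValueError(f"got {len(pool_parts)} pools of counts, expected {n_pools}")
    all_codes = np.concatenate(code_parts) if code_parts else np.empty(0, dtype=np.uint64)
    all_pools = np.concatenate(pool_parts) if pool_parts else np.empty(0, dtype=np.int32)
    all_counts = np.concatenate(count_parts) if count_parts else np.empty(0, dtype=np.int64)
    order = np.argsort(all_codes, kind="stable")  # stable keeps pools ascending per code
    all_codes, all_pools, all_counts = all_codes[order], all_pools[order], all_counts[order]
    uniq, start = np.unique(all_codes, return_index=True)
    indptr = np.concatenate([start, [all_codes.size]]).astype(np.int64)
    return KmerCountTable(
        k=k,
        n_pools=n_pools,
        codes=uniq,
        indptr=indptr,
        pools=all_pools,
        counts=np.minimum(all_counts, COUNT_CAP).astype(np.uint16),
    )


def build_count_table(
    pool_files: Sequence[str | Sequence[str]], k: int = DEFAULT_K
) -> KmerCountTable:
    """Count canonical k-mers of every pool's FASTQ file(s).

    ``pool_files`` is ordered by global pool index; each entry may be one
    path or a sequence of paths (e.g. the two mate files of a pool).
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31] (codes are packed in 64 bits)")
    per_pool = []
    for pool, entry in enumerate(pool_files):
        try:
            per_pool.append(count_pool(entry, k))
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"pool {pool}: {exc}") from exc
    return assemble_table(per_pool, k=k, n_pools=len(pool_files))


def kmer_signature_histogram(table: KmerCountTable) -> dict[int, int]:
    """Histogram of k-mer support sizes w -> number of distinct k-mers.

    For clone-unique sequence at adequate depth the mass concentrates at
    w = L; overlap sequence peaks in the two- and three-union ranges.
    """
    w = table.support_sizes()
    if w.size == 0:
        return {}
    counts = np.bincount(w)
    return {int(x): int(c) for x, c in enumerate(counts) if c > 0}
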