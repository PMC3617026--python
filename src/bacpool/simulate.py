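"""In-silico pooled clone sequencing.

Generates a synthetic genome, tiles it with (optionally overlapping)
clones, pools the clones according to a shifted transversal design, and
"sequences" each pool with paired-end reads carrying i.i.d. substitution
errors.  Every read name encodes its provenance (source clone, pool and
fragment coordinates), and a truth table is written alongside the FASTQ
files, so downstream deconvolution can be scored exactly.

The error model is substitution-only with a constant base quality; insert
lengths are Normal; reads never extend past the ends of their source clone
(clone sequencing has no genomic read-through).
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
    _CODE_LUT[ord(chr(_b).lower())] = _i

#: field separator reserved for provenance-bearing read names
NAME_SEP = "|"
NAME_PREFIX = "bp"

#: clone id used for contaminant-derived reads in names and truth tables
CONTAMINANT_ID = "*"


def encode(seq: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3 (255 for anything else)."""
    return _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASE_LUT[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return decode(3 - encode(seq)[::-1])


@dataclass(frozen=True)
class GenomeSpec:
    """Synthetic genome recipe: length, GC content and repeat families.

    ``repeat_families`` is a list of ``(unit_length, copies, divergence)``
    tuples; each family's unit is copied ``copies`` times at random
    non-overlapping positions, each copy mutated at the per-base
    ``divergence`` rate.
    """

    length: int
    gc: float = 0.44
    repeat_families: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")


def generate_genome(spec: GenomeSpec) -> str:
    """Random genome with the requested GC fraction and planted repeats.

    Deterministic for a fixed ``spec.seed``.  Raises if the repeat copies
    cannot be placed without overlap.
    """
    rng = np.random.default_rng(spec.seed)
    at = (1.0 - spec.gc) / 2.0
    gc = spec.gc / 2.0
    codes = rng.choice(4, size=spec.length, p=[at, gc, gc, at]).astype(np.uint8)
    occupied: list[tuple[int, int]] = []
    for unit_len, copies, divergence in spec.repeat_families:
        if unit_len * copies > spec.length:
            raise ValueError(
                f"repeat family ({unit_len} x {copies}) cannot fit in genome"
            )
        unit = rng.choice(4, size=unit_len, p=[at, gc, gc, at]).astype(np.uint8)
        placed = 0
        attempts = 0
        while placed < copies:
            attempts += 1
            if attempts > 1000 * copies:
                raise ValueError("infeasible repeat placement (genome too crowded)")
            start = int(rng.integers(0, spec.length - unit_len + 1))
            span = (start, start + unit_len)
            if any(s < span[1] and span[0] < e for s, e in occupied):
                continue
            copy = unit.copy()
            if divergence > 0:
                mut = rng.random(unit_len) < divergence
                copy[mut] = (copy[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
            codes[span[0] : span[1]] = copy
            occupied.append(span)
            placed += 1
    return decode(codes)


@dataclass
class CloneLayout:
    """Tiling of a genome by clones: list of (clone_id, start, end), 0-based half-open."""

    intervals: list[tuple[str, int, int]]
    genome_length: int

    def __post_init__(self) -> None:
        events: list[tuple[int, int]] = []
        for cid, start, end in self.intervals:
            if not 0 <= start < end <= self.genome_length:
                raise ValueError(f"clone {cid}: interval [{start}, {end}) out of range")
            events.append((start, 1))
            events.append((end, -1))
        cover = 0
        for _, delta in sorted(events):
            cover += delta
            if cover > 3:
                raise ValueError("a base is covered by more than 3 clones")

    @property
    def clone_ids(self) -> list[str]:
        return [cid for cid, _, _ in self.intervals]

    def lengths(self) -> dict[str, int]:
        return {cid: end - start for cid, start, end in self.intervals}

    def overlap_graph(self) -> dict[str, set[str]]:
        """clone id -> set of clone ids whose intervals intersect it."""
        out: dict[str, set[str]] = {cid: set() for cid in self.clone_ids}
        ivs = self.intervals
        for i, (ci, si, ei) in enumerate(ivs):
            for cj, sj, ej in ivs[i + 1 :]:
                if si < ej and sj < ei:
                    out[ci].add(cj)
                    out[cj].add(ci)
        return out


def layout_clones(
    genome_length: int,
    n_clones: int,
    mean_len: float,
    sd_len: float,
    mean_overlap: float,
    sd_overlap: float,
    seed: int = 0,
    id_prefix: str = "C",
) -> CloneLayout:
    """Tile a genome left to right with clones of Normal length and overlap.

    Consecutive clones overlap by ``max(0, Normal(mean_overlap, sd_overlap))``
    bases; lengths are truncated positive.  Raises if the tiling does not fit.
    """
    if n_clones * (mean_len - mean_overlap) > genome_length + mean_overlap:
        raise ValueError("infeasible tiling: clones do not fit at the requested overlap")
    rng = np.random.default_rng(seed)
    intervals: list[tuple[str, int, int]] = []
    pos = 0
    width = len(str(max(n_clones - 1, 1)))
    for i in range(n_clones):
        length = 0
        while length <= 0:
            length = int(round(rng.normal(mean_len, sd_len))) if sd_len > 0 else int(mean_len)
        start, end = pos, pos + length
        if end > genome_length:
            raise ValueError(f"infeasible tiling: clone {i} extends past the genome end")
        intervals.append((f"{id_prefix}{i:0{width}d}", start, end))
        overlap = max(0, int(round(rng.normal(mean_overlap, sd_overlap)))) if sd_overlap > 0 else int(mean_overlap)
        overlap = min(overlap, length - 1)
        pos = end - overlap
    return CloneLayout(intervals=intervals, genome_length=genome_length)


@dataclass(frozen=True)
class ReadSimParams:
    """Paired-end sequencing parameters for the pool simulator.

    Defaults follow the in-silico validation conditions this package
    emulates: 104-base reads, 327-base inserts (sd = 10% of the mean) and a
    1% uniform per-base substitution error rate.  Exactly one of
    ``pairs_per_pool`` or ``depth_per_pool`` sets the sampling budget;
    ``depth_per_pool`` is the target per-base coverage of each pool's
    clone content.
    """

    read_length: int = 104
    insert_mean: float = 327.0
    insert_sd: float = 32.7
    error_rate: float = 0.01
    pairs_per_pool: int | None = None
    depth_per_pool: float | None = None
    contaminant_fraction: float = 0.0
    base_quality: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValueError("contaminant_fraction must be in [0, 1)")
        if (self.pairs_per_pool is None) == (self.depth_per_pool is None):
            raise ValueError("set exactly one of pairs_per_pool / depth_per_pool")


@dataclass
class SimResult:
    """Paths and truth produced by :func:`simulate_pools`."""

    pool_files: list[tuple[str, str]]
    truth_path: str
    truth: pd.DataFrame = field(repr=False)


def make_read_name(clone_id: str, pool: int, start: int, end: int, idx: int) -> str:
    return NAME_SEP.join((NAME_PREFIX, clone_id, str(pool), str(start), str(end), str(idx)))


def parse_read_name(name: str) -> dict:
    """Invert :func:`make_read_name`; accepts a trailing ``/1`` or ``/2`` mate tag."""
    mate = 0
    if name.endswith("/1") or name.endswith("/2"):
        mate = int(name[-1])
        name = name[:-2]
    fields = name.split(NAME_SEP)
    if len(fields) != 6 or fields[0] != NAME_PREFIX:
        raise ValueError(f"not a provenance-bearing read name: {name!r}")
    return {
        "clone_id": fields[1],
        "pool": int(fields[2]),
        "start": int(fields[3]),
        "end": int(fields[4]),
        "index": int(fields[5]),
        "mate": mate,
        "is_contaminant": fields[1] == CONTAMINANT_ID,
    }


def _mutate(rng: np.random.Generator, codes: np.ndarray, error_rate: float) -> np.ndarray:
    if error_rate <= 0:
        return codes
    mask = rng.random(codes.shape) < error_rate
    shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    codes = codes.copy()
    codes[mask] = (codes[mask] + shift) % 4
    return codes


def _fragment_batch(
    rng: np.random.Generator,
    clone_codes: np.ndarray,
    n_pairs: int,
    params: ReadSimParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sample fragments and return (starts, ends, R1 codes, R2 codes)."""
    rl = params.read_length
    clen = clone_codes.size
    inserts = np.rint(rng.normal(params.insert_mean, params.insert_sd, size=n_pairs))
    inserts = np.clip(inserts, rl, clen).astype(np.int64)
    starts = np.floor(rng.random(n_pairs) * (clen - inserts + 1)).astype(np.int64)
    ends = starts + inserts
    offs = np.arange(rl)
    r1 = clone_codes[starts[:, None] + offs]
    r2 = 3 - clone_codes[ends[:, None] - 1 - offs]  # reverse complement of the tail
    r1 = _mutate(rng, r1, params.error_rate)
    r2 = _mutate(rng, r2, params.error_rate)
    return starts, ends, r1, r2


def _split_budget(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` by ``weights``."""
    if weights.sum() == 0:
        return np.zeros_like(weights, dtype=np.int64)
    exact = weights / weights.sum() * total
    base = np.floor(exact).astype(np.int64)
    rem = total - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:rem]] += 1
    return base


def simulate_pools(
    design,
    layout: CloneLayout,
    genome: str,
    params: ReadSimParams,
    outdir: str,
    contaminant: str | None = None,
    gzip_output: bool = False,
) -> SimResult:
    """Sequence every pool of ``design`` in silico.

    Each pool's reads are drawn only from its member clones (plus an
    optional contaminant fraction), pairs apportioned by clone length.
    Writes ``pool_XXX_R1.fastq[.gz]`` / ``_R2`` per pool and a
    ``truth.tsv`` with one row per read.  Deterministic for a fixed
    ``params.seed``.
    """
    if len(layout.intervals) != design.params.n:
        raise ValueError(
            f"layout has {len(layout.intervals)} clones but design pools n={design.params.n}"
        )
    if params.contaminant_fraction > 0 and contaminant is None:
        raise ValueError("contaminant_fraction > 0 requires a contaminant sequence")
    for cid in layout.clone_ids:
        if NAME_SEP in cid:
            raise ValueError(f"clone id {cid!r} contains the reserved separator {NAME_SEP!r}")
    os.makedirs(outdir, exist_ok=True)
    genome_codes = encode(genome)
    if (genome_codes > 3).any():
        raise ValueError("genome contains non-ACGT symbols")
    clone_codes = {cid: genome_codes[s:e] for cid, s, e in layout.intervals}
    clone_len = layout.lengths()
    contam_codes = encode(contaminant) if contaminant is not None else None
    qual = chr(33 + params.base_quality) * params.read_length
    rl = params.read_length

    pool_files: list[tuple[str, str]] = []
    truth_rows: list[pd.DataFrame] = []
    n_pools = design.params.n_pools
    for pool in range(n_pools):
        rng = np.random.default_rng([params.seed, pool])
        member_ids = [layout.clone_ids[i] for i in design.members[pool]]
        usable = [cid for cid in member_ids if clone_len[cid] >= rl]
        for cid in member_ids:
            if clone_len[cid] < rl:
                logger.warning("pool %d: clone %s shorter than a read; skipped", pool, cid)
        lengths = np.array([clone_len[cid] for cid in usable], dtype=np.float64)
        if params.pairs_per_pool is not None:
            pool_pairs = params.pairs_per_pool
        else:
            pool_pairs = int(round(params.depth_per_pool * lengths.sum() / (2 * rl)))
        n_contam = int(round(pool_pairs * params.contaminant_fraction))
        budgets = _split_budget(lengths, pool_pairs - n_contam)

        suffix = ".fastq.gz" if gzip_output else ".fastq"
        p1 = os.path.join(outdir, f"pool_{pool:03d}_R1{suffix}")
        p2 = os.path.join(outdir, f"pool_{pool:03d}_R2{suffix}")
        opener = gzip.open if gzip_output else open
        lines1: list[str] = []
        lines2: list[str] = []
        names: list[str] = []
        clones_col: list[str] = []
        starts_col: list[int] = []
        ends_col: list[int] = []
        idx = 0
        sources: list[tuple[str, np.ndarray, int]] = [
            (cid, clone_codes[cid], int(b)) for cid, b in zip(usable, budgets)
        ]
        if n_contam > 0:
            sources.append((CONTAMINANT_ID, contam_codes, n_contam))
        for cid, codes, n_pairs in sources:
            if n_pairs == 0:
                continue
            starts, ends, r1, r2 = _fragment_batch(rng, codes, n_pairs, params)
            s1 = [decode(row) for row in r1]
            s2 = [decode(row) for row in r2]
            for j in range(n_pairs):
                name = make_read_name(cid, pool, int(starts[j]), int(ends[j]), idx)
                lines1.append(f"@{name}/1\n{s1[j]}\n+\n{qual}\n")
                lines2.append(f"@{name}/2\n{s2[j]}\n+\n{qual}\n")
                names.append(name)
                idx += 1
            clones_col.extend([cid] * n_pairs)
            starts_col.extend(starts.tolist())
            ends_col.extend(ends.tolist())
        with opener(p1, "wt") as fh:
            fh.write("".join(lines1))
        with opener(p2, "wt") as fh:
            fh.write("".join(lines2))
        pool_files.append((p1, p2))
        truth_rows.append(
            pd.DataFrame(
                {
                    "read_id": names,
                    "clone_id": clones_col,
                    "pool": pool,
                    "start": starts_col,
                    "end": ends_col,
                    "is_contaminant": [c == CONTAMINANT_ID for c in clones_col],
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    truth_path = os.path.join(outdir, "truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimResult(pool_files=pool_files, truth_path=truth_path, truth=truth)
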