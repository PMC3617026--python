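"""Read preprocessing and standard-format I/O.

Quality trimming follows the usual sliding-window rule: scan each read
left to right, and at the first window whose mean Phred quality falls
below the threshold (default 23) truncate the read at the window start.
Trimmed reads shorter than the minimum length (default 36) or containing
an 'N' are dropped.  All coordinates in interval outputs are 0-based
half-open.

FASTQ/FASTA parsing is delegated to pysam's FastxFile (which handles
gzip transparently); writing emits plain 4-line records, gzipped when the
path ends in ``.gz``.
"""

from __future__ import annotations

import gzip
import json
import logging
import sys
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

import pysam
import yaml

logger = logging.getLogger("bacpool")


class FastqRecord(NamedTuple):
    name: str
    sequence: str
    quality: str | None


class FastqFormatError(ValueError):
    """Malformed FASTQ/FASTA input."""


def read_fastx(path: str) -> Iterator[FastqRecord]:
    """Iterate FASTQ/FASTA records (gzip transparent). Raises on malformed input."""
    fastq = None  # inferred from the first record
    try:
        with pysam.FastxFile(str(path)) as fh:
            for i, rec in enumerate(fh):
                if rec.sequence is None:
                    raise FastqFormatError(f"{path}: record {i} has no sequence")
                if fastq is None:
                    fastq = rec.quality is not None
                if fastq and (
                    rec.quality is None or len(rec.quality) != len(rec.sequence)
                ):
                    raise FastqFormatError(
                        f"{path}: truncated or malformed FASTQ record {i} ({rec.name})"
                    )
                name = rec.name if rec.comment is None else f"{rec.name} {rec.comment}"
                yield FastqRecord(name, rec.sequence, rec.quality)
    except OSError as exc:
        raise FastqFormatError(f"{path}: {exc}") from exc


def _opener(path: str, mode: str):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


def write_fastq(path: str, records: Iterable[FastqRecord]) -> int:
    """Write 4-line FASTQ records; returns the number written."""
    n = 0
    with _opener(path, "wt") as fh:
        for rec in records:
            if rec.quality is None or len(rec.quality) != len(rec.sequence):
                raise FastqFormatError(
                    f"record {rec.name!r}: quality length does not match sequence"
                )
            fh.write(f"@{rec.name}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n


def write_fasta(path: str, records: Iterable[tuple[str, str]], width: int = 80) -> int:
    n = 0
    with _opener(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            n += 1
    return n


@dataclass(frozen=True)
class TrimPolicy:
    """Quality/length/N filtering policy for raw reads."""

    window_min_quality: int = 23
    min_length: int = 36
    drop_reads_with_N: bool = True
    window_length: int = 4
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if self.window_min_quality < 0 or self.min_length < 0 or self.window_length < 1:
            raise ValueError("trim policy thresholds must be nonnegative")


@dataclass
class TrimCounts:
    kept: int = 0
    trimmed: int = 0  # kept reads that lost bases
    dropped: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.dropped


def trim_record(rec: FastqRecord, policy: TrimPolicy) -> FastqRecord | None:
    """Trim one read; returns None if it is dropped."""
    if rec.quality is None:
        raise FastqFormatError(f"record {rec.name!r} has no qualities to trim on")
    quals = [ord(c) - policy.phred_offset for c in rec.quality]
    w = policy.window_length
    cut = len(quals)
    for i in range(0, max(len(quals) - w + 1, 1)):
        window = quals[i : i + w]
        if window and sum(window) / len(window) < policy.window_min_quality:
            cut = i
            break
    seq = rec.sequence[:cut]
    if len(seq) < policy.min_length:
        return None
    if policy.drop_reads_with_N and ("N" in seq or "n" in seq):
        return None
    return FastqRecord(rec.name, seq, rec.quality[:cut])


def quality_trim(
    records: Iterable[FastqRecord], policy: TrimPolicy
) -> tuple[list[FastqRecord], TrimCounts]:
    """Apply :func:`trim_record` to a stream; returns survivors and counts."""
    counts = TrimCounts()
    out = []
    for rec in records:
        trimmed = trim_record(rec, policy)
        if trimmed is None:
            counts.dropped += 1
        else:
            counts.kept += 1
            if len(trimmed.sequence) < len(rec.sequence):
                counts.trimmed += 1
            out.append(trimmed)
    return out, counts


def read_pool_list(path: str) -> list[list[str]]:
    """Pool file list: one line per pool (in pool order), whitespace-separated
    paths for pools split across several FASTQ files."""
    pools = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pools.append(line.split())
    if not pools:
        raise ValueError(f"pool list {path} is empty")
    return pools


def load_config(path: str) -> dict:
    """YAML or JSON run configuration."""
    with open(path) as fh:
        text = fh.read()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )
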