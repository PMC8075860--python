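"""FASTQ input, quality filtering, mate orientation and unique-read collapsing.

Amplicon libraries sequence the same few hundred bases millions of times,
so distinct read sequences are few.  Collapsing identical sequences before
alignment (keeping their multiplicity) reduces the alignment workload by
orders of magnitude without changing any downstream count.
"""

from __future__ import annotations

import gzip
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class SequencingRead:
    read_id: str
    bases: str
    qualities: np.ndarray  # per-base Phred scores
    mate: int = 1


@dataclass
class UniqueRead:
    """A distinct read sequence and its multiplicity after collapsing."""

    bases: str
    count: int
    source_mates: Counter = field(default_factory=Counter)


@dataclass
class FilterStats:
    reads_in: int = 0
    reads_passed: int = 0
    failed_quality: int = 0
    failed_n: int = 0


def reverse_complement(bases: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N maps to N)."""
    return bases.translate(_COMPLEMENT)[::-1]


def _open_maybe_gzip(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_one(path, mate: int) -> Iterator[SequencingRead]:
    with _open_maybe_gzip(path) as fh:
        n = 0
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                n += 1
                if len(seq) != len(qual):
                    raise ValueError(
                        f"{path}: record {title!r}: sequence length "
                        f"{len(seq)} != quality length {len(qual)}"
                    )
                if not seq:
                    raise ValueError(f"{path}: record {title!r} is empty")
                phred = np.frombuffer(qual.encode(), np.uint8).astype(np.int16) - 33
                yield SequencingRead(title.split()[0], seq.upper(), phred, mate)
        except ValueError as exc:
            # FastqGeneralIterator raises bare ValueErrors on truncation
            if "length" in str(exc) and path is not None and str(path) not in str(exc):
                raise ValueError(f"{path}: after record {n}: {exc}") from exc
            raise


def read_fastq(*paths: str | os.PathLike) -> Iterator[SequencingRead]:
    """Stream reads from one (single-end) or two (paired) FASTQ files.

    Files may be plain or gzip-compressed, Phred+33 encoded.  With two
    paths the first is mate 1 and the second mate 2.  Malformed records
    raise a ValueError naming the file and record.
    """
    if not 1 <= len(paths) <= 2:
        raise ValueError("read_fastq takes one or two FASTQ paths")
    for mate, path in enumerate(paths, start=1):
        if not os.path.exists(path):
            raise FileNotFoundError(f"FASTQ file not found: {path}")
        yield from _iter_one(path, mate)


def quality_filter(
    reads: Iterable[SequencingRead], min_mean_quality: float
) -> tuple[list[SequencingRead], FilterStats]:
    """Keep reads with mean Phred >= threshold and no N base.

    The comparison is inclusive (a mean exactly at the threshold passes).
    N-containing reads are dropped regardless of quality because an N
    inside a putative insert cannot be verified against the reference.
    """
    stats = FilterStats()
    kept: list[SequencingRead] = []
    for read in reads:
        stats.reads_in += 1
        if "N" in read.bases:
            stats.failed_n += 1
            continue
        if read.qualities.mean() < min_mean_quality:
            stats.failed_quality += 1
            continue
        stats.reads_passed += 1
        kept.append(read)
    return kept, stats


def orient_reads(reads: Iterable[SequencingRead]) -> Iterator[SequencingRead]:
    """Reverse-complement mate-2 reads into reference orientation.

    Mate 2 sequences the opposite strand of the amplicon; after this step
    every read can be aligned to the forward reference directly.
    """
    for read in reads:
        if read.mate == 2:
            yield SequencingRead(
                read.read_id,
                reverse_complement(read.bases),
                read.qualities[::-1],
                read.mate,
            )
        else:
            yield read


def collapse_unique(reads: Iterable[SequencingRead]) -> list[UniqueRead]:
    """Collapse identical sequences into UniqueReads with multiplicities.

    Output is ordered by descending count, ties broken lexicographically
    by sequence, so the result is independent of input order.  Counts sum
    to the number of input reads.
    """
    counts: Counter[str] = Counter()
    mates: dict[str, Counter] = {}
    for read in reads:
        counts[read.bases] += 1
        if read.bases not in mates:
            mates[read.bases] = Counter()
        mates[read.bases][read.mate] += 1
    out = [
        UniqueRead(bases=seq, count=cnt, source_mates=mates[seq])
        for seq, cnt in counts.items()
    ]
    out.sort(key=lambda u: (-u.count, u.bases))
    return out
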