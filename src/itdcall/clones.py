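"""Clone merging, quantification (VAF/AR), filtering and serial tracking.

A *clone* is the set of reads supporting the same ITD: identical insert
sequence over the portion each read actually sequenced, the same length
(exactly for non-trailing calls, within a small tolerance for trailing
length estimates) and the same insertion site within a few bp.  The
variant allele frequency (VAF) of a clone is its supporting reads divided
by the reads covering the insertion site; the allelic ratio (AR) is the
mutant-to-wild-type ratio AR = VAF / (1 - VAF), the unit conventionally
reported by fragment analysis.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .detect import ITDCall
from .reference import ReferenceAmplicon, RunConfig


@dataclass
class CloneRecord:
    """Merged ITD evidence across reads of one sample."""

    consensus_insert: str
    length_estimate: int
    ref_pos: int
    trailing: bool
    side: str = ""
    exact_length: bool = True
    supporting_reads: int = 0
    supporting_unique: int = 0
    coverage: int = 0
    vaf: float = 0.0
    ar: float = 0.0
    annotation: str = ""
    mate_support: Counter = field(default_factory=Counter)
    calls: list = field(default_factory=list)  # (ITDCall, count)


@dataclass
class CloneTrajectory:
    """One clone followed across an ordered series of samples."""

    consensus_insert: str
    length_estimate: int
    ref_pos: int
    trailing: bool
    vafs: list  # per-timepoint VAF, None where undetected
    category: str  # persisting | lost | gained | transient


def compute_vaf(supporting_reads: int, coverage: int) -> float:
    """Fraction of site-covering reads that support the ITD."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= supporting_reads <= coverage:
        raise ValueError("supporting_reads must be in [0, coverage]")
    return supporting_reads / coverage


def vaf_to_ar(vaf: float) -> float:
    """Mutant:wild-type allelic ratio; AR = VAF / (1 - VAF)."""
    if not 0.0 <= vaf <= 1.0:
        raise ValueError("vaf must be in [0, 1]")
    if vaf == 1.0:
        return math.inf
    return vaf / (1.0 - vaf)


def ar_to_vaf(ar: float) -> float:
    """Inverse of vaf_to_ar; VAF = AR / (1 + AR)."""
    if ar < 0:
        raise ValueError("ar must be >= 0")
    if math.isinf(ar):
        return 1.0
    return ar / (1.0 + ar)


def _seqs_compatible(seq_a: str, seq_b: str, trailing: bool, side: str) -> bool:
    """Sequenced portions identical over their overlap.

    Equal-length (non-trailing) inserts must match exactly.  Trailing
    inserts from reads with different anchors sequence different amounts
    of the duplication: 3' overhangs are compared over their common
    prefix, 5' overhangs over their common suffix.
    """
    if not trailing or len(seq_a) == len(seq_b):
        return seq_a == seq_b
    k = min(len(seq_a), len(seq_b))
    if side == "left":
        return seq_a[-k:] == seq_b[-k:]
    return seq_a[:k] == seq_b[:k]


def calls_mergeable(a: ITDCall, b: ITDCall, cfg: RunConfig) -> bool:
    """Pairwise merge rule; transitive closure of this defines clones."""
    if a.insert.trailing != b.insert.trailing and not cfg.merge_trailing_with_exact:
        return False
    if a.insert.trailing and b.insert.trailing:
        if a.insert.side != b.insert.side:
            return False
        if abs(a.length_estimate - b.length_estimate) > cfg.trailing_length_tolerance:
            return False
    elif a.length_estimate != b.length_estimate:
        return False
    if abs(a.insert.ref_pos - b.insert.ref_pos) > cfg.merge_site_tolerance:
        return False
    return _seqs_compatible(
        a.insert.sequence, b.insert.sequence, a.insert.trailing, a.insert.side
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_calls(
    calls: Sequence[tuple[ITDCall, int]], cfg: RunConfig
) -> list[CloneRecord]:
    """Merge per-read ITD calls into (unquantified) clones.

    ``calls`` pairs each call with its read multiplicity.  Merging is the
    transitive closure of :func:`calls_mergeable`; the consensus insert is
    the most-supported insert sequence of the clone (ties broken toward
    the longer, then lexicographically smaller sequence).  Output is
    sorted by descending support.

    Equal inserts are grouped by hash first so that deep samples with many
    singleton error variants do not incur a quadratic pairwise sweep; the
    pairwise rule is only evaluated between group representatives that can
    possibly merge (nearby sites, compatible lengths).
    """
    if not calls:
        return []
    uf = _UnionFind(len(calls))
    # exact groups: identical (trailing, side, sequence) merge iff sites close
    groups: dict[tuple, list[int]] = defaultdict(list)
    for i, (call, _) in enumerate(calls):
        key = (call.insert.trailing, call.insert.side, call.insert.sequence)
        groups[key].append(i)
    trailing_reps: list[int] = []
    for key, members in groups.items():
        members.sort(key=lambda i: calls[i][0].insert.ref_pos)
        for a, b in zip(members, members[1:]):
            if calls_mergeable(calls[a][0], calls[b][0], cfg):
                uf.union(a, b)
        if key[0]:  # trailing group
            trailing_reps.extend(members)
    # cross-group sweep for trailing calls only: overhangs of different
    # depths sequence different portions of the same duplication, so they
    # live in different exact-sequence groups.  Non-trailing calls can
    # only merge on full sequence equality and are fully handled above.
    by_site: dict[int, list[int]] = defaultdict(list)
    width = cfg.merge_site_tolerance + 1
    for i in trailing_reps:
        by_site[calls[i][0].insert.ref_pos // width].append(i)
    for bucket, members in by_site.items():
        pool = members + by_site.get(bucket + 1, []) + by_site.get(bucket - 1, [])
        for a in members:
            for b in pool:
                if b <= a or uf.find(a) == uf.find(b):
                    continue
                if calls_mergeable(calls[a][0], calls[b][0], cfg):
                    uf.union(a, b)

    clusters: dict[int, list[int]] = defaultdict(list)
    for i in range(len(calls)):
        clusters[uf.find(i)].append(i)

    clones: list[CloneRecord] = []
    for members in clusters.values():
        weight: Counter[str] = Counter()
        for i in members:
            call, count = calls[i]
            weight[call.insert.sequence] += count
        consensus = max(
            weight, key=lambda s: (weight[s], len(s), [-ord(c) for c in s])
        )
        lead = max(
            (calls[i] for i in members if calls[i][0].insert.sequence == consensus),
            key=lambda pair: pair[1],
        )[0]
        clone = CloneRecord(
            consensus_insert=consensus,
            length_estimate=lead.length_estimate,
            ref_pos=lead.insert.ref_pos,
            trailing=lead.insert.trailing,
            side=lead.insert.side,
            exact_length=lead.exact_length,
            calls=[calls[i] for i in members],
        )
        clone.supporting_reads = sum(calls[i][1] for i in members)
        clone.supporting_unique = len(members)
        clones.append(clone)
    clones.sort(key=lambda c: (-c.supporting_reads, c.ref_pos, c.length_estimate))
    return clones


def compute_coverage(
    alignments: Sequence[tuple[int, int, int]], ref_pos: int, ref_length: int
) -> int:
    """Reads whose alignment spans the insertion point.

    ``alignments`` is a sequence of (ref_start, ref_end, count).  A read
    spans position p when it covers both flanking bases ref[p-1] and
    ref[p]; at the amplicon boundaries the single existing flanking base
    suffices.  Reads whose own insert defines the position are added
    separately during quantification (they span by construction even when
    soft-clipping truncates their aligned interval).
    """
    if not 0 <= ref_pos <= ref_length:
        raise ValueError("ref_pos outside reference")
    lo = max(ref_pos - 1, 0)
    hi = min(ref_pos + 1, ref_length)
    return sum(
        count for start, end, count in alignments if start <= lo and end >= hi
    )


def quantify_clones(
    clones: list[CloneRecord],
    alignments: Sequence[tuple[int, int, int]],
    ref: ReferenceAmplicon,
    cfg: RunConfig,
    supporting_spans: Optional[dict] = None,
) -> list[CloneRecord]:
    """Fill coverage, VAF and AR for each clone.

    Coverage at a clone's site counts alignment-spanning reads plus any
    ITD-supporting reads (of any clone within site tolerance) whose
    soft-clipped alignment does not span the point on its own.
    """
    n = len(ref)
    starts = np.array([a[0] for a in alignments], dtype=np.int64)
    ends = np.array([a[1] for a in alignments], dtype=np.int64)
    counts = np.array([a[2] for a in alignments], dtype=np.int64)
    # all supporting reads with their spans, for the "span by construction"
    # coverage correction
    sup_pos: list[int] = []
    sup_start: list[int] = []
    sup_end: list[int] = []
    sup_count: list[int] = []
    for clone in clones:
        for call, count in clone.calls:
            src = call.insert.source
            span = supporting_spans.get(id(src)) if (supporting_spans and src) else None
            if span is None:
                continue
            sup_pos.append(clone.ref_pos)
            sup_start.append(span[0])
            sup_end.append(span[1])
            sup_count.append(count)
    sup_pos_a = np.array(sup_pos, dtype=np.int64)
    sup_start_a = np.array(sup_start, dtype=np.int64)
    sup_end_a = np.array(sup_end, dtype=np.int64)
    sup_count_a = np.array(sup_count, dtype=np.int64)

    cov_cache: dict[int, int] = {}

    def coverage_at(p: int) -> int:
        if p not in cov_cache:
            lo = max(p - 1, 0)
            hi = min(p + 1, n)
            base = int(counts[(starts <= lo) & (ends >= hi)].sum())
            if len(sup_pos_a):
                mask = (
                    (np.abs(sup_pos_a - p) <= cfg.merge_site_tolerance)
                    & ~((sup_start_a <= lo) & (sup_end_a >= hi))
                )
                base += int(sup_count_a[mask].sum())
            cov_cache[p] = base
        return cov_cache[p]

    for clone in clones:
        clone.coverage = coverage_at(clone.ref_pos)
        clone.vaf = compute_vaf(clone.supporting_reads, clone.coverage)
        clone.ar = vaf_to_ar(clone.vaf)
        clone.annotation = ref.annotate(clone.ref_pos)
        clone.mate_support = sum(
            (call.insert.source.source_mates for call, _ in clone.calls
             if call.insert.source is not None),
            Counter(),
        )
    return clones


def apply_filters(
    clones: list[CloneRecord],
    cfg: RunConfig,
    mate_site_coverage: Optional[dict[int, set[int]]] = None,
) -> tuple[list[CloneRecord], list[tuple[CloneRecord, str]]]:
    """Final call-set filter.

    Drops clones with fewer than ``min_supporting_reads`` supporting
    reads.  With paired-end data, when the insertion site is covered by
    reads from both mates, support must also come from both mates
    (``require_both_mates``); single-mate support at such a site is a
    hallmark of read-end artifacts.
    """
    kept: list[CloneRecord] = []
    audit: list[tuple[CloneRecord, str]] = []
    for clone in clones:
        if clone.supporting_reads < cfg.min_supporting_reads:
            audit.append((clone, "support"))
            continue
        if cfg.require_both_mates and mate_site_coverage:
            covering = mate_site_coverage.get(clone.ref_pos, set())
            if covering >= {1, 2}:
                supported = {m for m, c in clone.mate_support.items() if c > 0}
                if not supported >= {1, 2}:
                    audit.append((clone, "single_mate"))
                    continue
        kept.append(clone)
    return kept, audit


def clones_mergeable(a: CloneRecord, b: CloneRecord, cfg: RunConfig) -> bool:
    """Cross-sample clone identity: exactly the within-sample merge rule."""
    if a.trailing != b.trailing and not cfg.merge_trailing_with_exact:
        return False
    if a.trailing and b.trailing:
        if a.side != b.side:
            return False
        if abs(a.length_estimate - b.length_estimate) > cfg.trailing_length_tolerance:
            return False
    elif a.length_estimate != b.length_estimate:
        return False
    if abs(a.ref_pos - b.ref_pos) > cfg.merge_site_tolerance:
        return False
    return _seqs_compatible(a.consensus_insert, b.consensus_insert, a.trailing, a.side)


def track_clones(
    samples: Sequence[list[CloneRecord]],
    labels: Optional[Sequence[str]] = None,
    cfg: Optional[RunConfig] = None,
) -> list[CloneTrajectory]:
    """Match clones across an ordered sample series and categorise them.

    The first sample is treated as diagnosis and the last as relapse (or
    generic endpoints): clones present at both are *persisting*, at the
    first only *lost*, at the last only *gained*; clones seen only at
    intermediate timepoints are *transient*.
    """
    if len(samples) < 2:
        raise ValueError("tracking requires at least two samples")
    cfg = cfg or RunConfig()
    if labels is not None and len(labels) != len(samples):
        raise ValueError("one label per sample required")
    flat: list[tuple[int, CloneRecord]] = [
        (t, clone) for t, clones in enumerate(samples) for clone in clones
    ]
    uf = _UnionFind(len(flat))
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            if clones_mergeable(flat[i][1], flat[j][1], cfg):
                uf.union(i, j)
    clusters: dict[int, list[int]] = defaultdict(list)
    for i in range(len(flat)):
        clusters[uf.find(i)].append(i)
    out: list[CloneTrajectory] = []
    last = len(samples) - 1
    for members in clusters.values():
        vafs: list = [None] * len(samples)
        for i in members:
            t, clone = flat[i]
            vafs[t] = (vafs[t] or 0.0) + clone.vaf
        lead = max(members, key=lambda i: flat[i][1].supporting_reads)
        rep = flat[lead][1]
        if vafs[0] is not None and vafs[last] is not None:
            category = "persisting"
        elif vafs[0] is not None:
            category = "lost"
        elif vafs[last] is not None:
            category = "gained"
        else:
            category = "transient"
        out.append(
            CloneTrajectory(
                consensus_insert=rep.consensus_insert,
                length_estimate=rep.length_estimate,
                ref_pos=rep.ref_pos,
                trailing=rep.trailing,
                vafs=vafs,
                category=category,
            )
        )
    out.sort(key=lambda t: (t.ref_pos, t.length_estimate, t.consensus_insert))
    return out
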