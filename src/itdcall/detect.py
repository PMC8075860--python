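"""Insert extraction, tandem verification and trailing-length estimation.

An ITD shows up in a read alignment in one of two ways:

* a *non-trailing* insert: a contiguous run of gap columns in the
  reference row, fully enclosed by aligned read sequence, whose bases
  duplicate the reference segment immediately adjacent to the insertion
  point.  Its length is exact.
* a *trailing* insert: the duplication is too long (or sits too close to
  a read end) for one read to anchor both of its junctions, so the second
  copy appears as an unaligned (soft-clipped) read overhang.  The overhang
  matches a reference window some distance away from the clip point; that
  offset between the two copies estimates the full duplication length,
  which is flagged non-exact.

Either way the insert is only *called* an ITD if a reference window with
identity >= 1 - tandem_max_mismatch_fraction sits tandem-adjacent to the
insertion point; anything else is reported as a non-ITD insertion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .align import GAP, PairwiseAlignment, align_semi_global, encode
from .preprocess import UniqueRead
from .reference import ReferenceAmplicon, RunConfig


@dataclass
class InsertCandidate:
    """One putative insert on one read, before tandem verification.

    ``ref_pos`` is the 0-based reference position immediately after the
    inserted bases; ``side`` records which read end a trailing insert
    abuts ('right' = 3' overhang, 'left' = 5' overhang, '' = internal).
    """

    sequence: str
    ref_pos: int
    read_offset: int
    trailing: bool
    side: str = ""
    source: Optional[UniqueRead] = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ITDCall:
    """A verified tandem duplication on one read."""

    insert: InsertCandidate
    tandem_start: int
    tandem_end: int
    length_estimate: int
    exact_length: bool
    mismatches_in_tandem: int


def classify_trailing(candidate: InsertCandidate, read_length: int) -> bool:
    """An insert is trailing iff it abuts either end of the read.

    A read-end insert has no anchoring sequence beyond one junction, so
    the duplication cannot be confirmed as fully spanned and its length
    can only be estimated.  With a 250 bp read this is the fate of every
    duplication longer than about half the read length (2L > read length
    leaves no geometry that encloses the insert between two anchors).
    """
    return (
        candidate.read_offset == 0
        or candidate.read_offset + candidate.length == read_length
    )


def extract_inserts(
    aln: PairwiseAlignment, min_insert_length: int
) -> list[InsertCandidate]:
    """Insert candidates from one alignment.

    Internal reference-row gap runs of length >= min_insert_length become
    non-trailing candidates; unaligned read overhangs at either end (the
    free end gaps of the alignment) of that length become trailing
    candidates.  Read-row gap runs (deletions) never seed candidates.
    """
    read = aln.read_row.replace(GAP, "")
    m = len(read)
    out: list[InsertCandidate] = []

    head = aln.read_start
    if head >= min_insert_length:
        out.append(
            InsertCandidate(
                sequence=read[:head],
                ref_pos=aln.ref_start,
                read_offset=0,
                trailing=True,
                side="left",
            )
        )

    # walk the aligned core for internal reference-gap runs
    read_pos = aln.read_start
    ref_pos = aln.ref_start
    run_start = None
    core = slice(aln.read_start, len(aln.read_row) - (m - aln.read_end))
    for a, b in zip(aln.read_row[core], aln.ref_row[core]):
        if b == GAP:
            if run_start is None:
                run_start = read_pos
            read_pos += 1
        else:
            if run_start is not None:
                seq = read[run_start:read_pos]
                if len(seq) >= min_insert_length:
                    cand = InsertCandidate(
                        sequence=seq,
                        ref_pos=ref_pos,
                        read_offset=run_start,
                        trailing=False,
                    )
                    cand.trailing = classify_trailing(cand, m)
                    out.append(cand)
                run_start = None
            if a != GAP:
                read_pos += 1
            ref_pos += 1
    if run_start is not None:  # gap run flush with the aligned end
        seq = read[run_start:read_pos]
        if len(seq) >= min_insert_length:
            cand = InsertCandidate(
                sequence=seq, ref_pos=ref_pos, read_offset=run_start, trailing=True,
                side="right",
            )
            out.append(cand)

    tail = m - aln.read_end
    if tail >= min_insert_length:
        out.append(
            InsertCandidate(
                sequence=read[aln.read_end :],
                ref_pos=aln.ref_end,
                read_offset=aln.read_end,
                trailing=True,
                side="right",
            )
        )
    return out


def count_deletions(aln: PairwiseAlignment, min_length: int = 1) -> int:
    """Number of read-row gap runs (deletions) of at least min_length."""
    n = 0
    run = 0
    for a in aln.read_row:
        if a == GAP:
            run += 1
        else:
            if run >= min_length:
                n += 1
            run = 0
    return n + (1 if run >= min_length else 0)


def _window_mismatches(seq: str, ref_seq: str) -> np.ndarray:
    """Hamming distance of ``seq`` to every same-length reference window."""
    windows = np.lib.stride_tricks.sliding_window_view(encode(ref_seq), len(seq))
    return (windows != encode(seq)).sum(axis=1)


def find_tandem(
    candidate: InsertCandidate, ref: ReferenceAmplicon, cfg: RunConfig
) -> Optional[ITDCall]:
    """Verify that an insert candidate duplicates adjacent reference sequence.

    Non-trailing candidates: the adjacent upstream window is tested first,
    then the adjacent downstream window, then (on failure) a full sliding
    scan plus a gapped fallback; the matched window must start or end
    within merge_site_tolerance bp of the insertion point.  Trailing
    candidates: the sequenced portion of the insert is matched against all
    windows strictly on its far side of the clip point; the offset between
    window and insertion point estimates the full duplication length.

    Returns None when no tandem-compatible window reaches identity
    >= 1 - tandem_max_mismatch_fraction (a non-ITD insertion).
    """
    seq = candidate.sequence
    k = len(seq)
    n = len(ref)
    p = candidate.ref_pos
    max_mm = int(np.floor(cfg.tandem_max_mismatch_fraction * k))

    if k > n:
        return None

    if candidate.trailing:
        return _find_tandem_trailing(candidate, ref, cfg, max_mm)

    mm = _window_mismatches(seq, ref.sequence)
    # adjacent-first, upstream before downstream
    for w in (p - k, p):
        if 0 <= w <= n - k and mm[w] <= max_mm:
            return ITDCall(candidate, w, w + k, k, True, int(mm[w]))
    tol = cfg.merge_site_tolerance
    best: tuple | None = None
    lo = max(0, p - k - tol)
    hi = min(n - k, p + tol)
    for w in range(lo, hi + 1):
        if mm[w] > max_mm:
            continue
        # tandem-adjacent: window end near p (upstream copy) or start near p
        d_up = abs((w + k) - p)
        d_down = abs(w - p)
        d = min(d_up, d_down)
        if d > tol:
            continue
        key = (int(mm[w]), d, 0 if d_up <= d_down else 1, w)
        if best is None or key < best[0]:
            best = (key, w)
    if best is not None:
        w = best[1]
        return ITDCall(candidate, w, w + k, k, True, int(mm[w]))
    # gapped fallback: the insert may carry a small indel relative to its
    # wild-type copy; locate the window by aligning the insert itself
    aln = align_semi_global(seq, ref, cfg)
    w_s, w_e = aln.ref_start, aln.ref_end
    matches = sum(
        1 for a, b in zip(aln.read_row, aln.ref_row) if a == b and a != GAP
    )
    if k - matches <= max_mm and (abs(w_e - p) <= tol or abs(w_s - p) <= tol):
        return ITDCall(candidate, w_s, w_e, k, True, k - matches)
    return None


def _find_tandem_trailing(
    candidate: InsertCandidate, ref: ReferenceAmplicon, cfg: RunConfig, max_mm: int
) -> Optional[ITDCall]:
    seq = candidate.sequence
    k = len(seq)
    n = len(ref)
    p = candidate.ref_pos
    mm = _window_mismatches(seq, ref.sequence)
    best: tuple | None = None
    if candidate.side == "right":
        # 3' overhang: the clipped read tail starts with the second copy
        # (and may run on into wild-type sequence past the duplication);
        # its template starts upstream of the clip point, and the offset
        # between template start and clip point is the duplication length
        for w in range(0, min(p - cfg.min_insert_length, n - k) + 1):
            if mm[w] > max_mm:
                continue
            estimate = p - w
            key = (int(mm[w]), estimate)
            if best is None or key < best[0]:
                best = (key, w, estimate)
    else:
        # 5' overhang: the clipped read head ends with the tail of the
        # first copy (possibly preceded by wild-type sequence); its
        # template ends downstream of the alignment start
        for w in range(max(p + cfg.min_insert_length - k, 0), n - k + 1):
            if mm[w] > max_mm:
                continue
            estimate = (w + k) - p
            key = (int(mm[w]), estimate)
            if best is None or key < best[0]:
                best = (key, w, estimate)
    if best is None:
        return None
    _, w, estimate = best
    return ITDCall(candidate, w, w + k, int(estimate), False, int(best[0][0]))


def estimate_trailing_length(
    candidate: InsertCandidate, ref: ReferenceAmplicon, cfg: RunConfig
) -> tuple[int, bool]:
    """Duplication-length estimate for a trailing insert.

    Returns ``(length_estimate, exact=False)``; the estimate is the offset
    between the matched wild-type window and the insertion point, which
    infers the unsequenced remainder of the duplication.  Raises if no
    tandem-compatible window exists.
    """
    if not candidate.trailing:
        raise ValueError("candidate is not trailing; its length is exact")
    max_mm = int(np.floor(cfg.tandem_max_mismatch_fraction * candidate.length))
    call = _find_tandem_trailing(candidate, ref, cfg, max_mm)
    if call is None:
        raise ValueError("no tandem-compatible reference window for trailing insert")
    return call.length_estimate, False
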