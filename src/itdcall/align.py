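"""Pairwise alignment of reads against the amplicon reference.

Reads are aligned semi-globally with affine gap penalties: end gaps are
free on both sequences, so a read may map anywhere inside the amplicon and
read sequence overhanging the aligned region (e.g. the unsequenced-tandem
side of a long ITD) is soft-clipped rather than penalised.  Under a
positive match reward this is computed as a maximal-scoring local
alignment (Smith-Waterman with Gotoh affine gaps).

The dynamic program runs as a numba-compiled kernel.  Reads that match the
reference ungapped with at most two interior mismatches skip the kernel:
for such reads the full-length ungapped alignment is provably optimal
under the default-style scoring (any gap costs more than two mismatches,
and clipping can only pay off for mismatches within a few bases of a read
end), which covers the overwhelming majority of wild-type reads in a deep
amplicon sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .reference import ReferenceAmplicon, RunConfig

GAP = "-"

_CODE = np.full(256, 255, np.uint8)
for _i, _c in enumerate("ACGTN"):
    _CODE[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), np.uint8)]


@dataclass
class PairwiseAlignment:
    """Gapped alignment of one read against the reference.

    ``read_row`` contains the full read; read bases outside the aligned
    core appear opposite end-gap runs of ``-`` in ``ref_row``.  Removing
    gaps from ``ref_row`` yields ``reference[ref_start:ref_end)``.
    """

    read_row: str
    ref_row: str
    score: float
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int

    @property
    def read_bases_aligned(self) -> int:
        return self.read_end - self.read_start

    @property
    def read_length(self) -> int:
        return len(self.read_row) - self.read_row.count(GAP)


@njit(cache=True)
def _sw_affine(read, ref, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m = read.shape[0]
    n = ref.shape[0]
    NEG = -1e30
    M = np.full((m + 1, n + 1), NEG, np.float64)
    X = np.full((m + 1, n + 1), NEG, np.float64)  # gap in ref row (read insertion)
    Y = np.full((m + 1, n + 1), NEG, np.float64)  # gap in read row (deletion)
    pM = np.zeros((m + 1, n + 1), np.uint8)  # 0=start 1=M 2=X 3=Y
    pX = np.zeros((m + 1, n + 1), np.uint8)  # 1=open 2=extend
    pY = np.zeros((m + 1, n + 1), np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        ri = read[i - 1]
        for j in range(1, n + 1):
            s = match if ri == ref[j - 1] else mismatch
            # diagonal; ties prefer continuing a match run, then an
            # insertion, then a deletion (strict > keeps earlier option)
            prev = 0.0
            p = 0
            if M[i - 1, j - 1] > prev:
                prev = M[i - 1, j - 1]
                p = 1
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
                p = 2
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
                p = 3
            M[i, j] = prev + s
            pM[i, j] = p
            vo = M[i - 1, j] + gap_open
            ve = X[i - 1, j] + gap_extend
            if vo >= ve:
                X[i, j] = vo
                pX[i, j] = 1
            else:
                X[i, j] = ve
                pX[i, j] = 2
            vo = M[i, j - 1] + gap_open
            ve = Y[i, j - 1] + gap_extend
            if vo >= ve:
                Y[i, j] = vo
                pY[i, j] = 1
            else:
                Y[i, j] = ve
                pY[i, j] = 2
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    return M, X, Y, pM, pX, pY, best, bi, bj


def _traceback(read: str, ref: str, mats) -> PairwiseAlignment:
    M, X, Y, pM, pX, pY, best, bi, bj = mats
    m = len(read)
    read_cols: list[str] = []
    ref_cols: list[str] = []
    i, j = bi, bj
    state = 1
    while i > 0 or j > 0:
        if state == 1:
            p = pM[i, j]
            read_cols.append(read[i - 1])
            ref_cols.append(ref[j - 1])
            i -= 1
            j -= 1
            if p == 0:
                break
            state = p
        elif state == 2:
            p = pX[i, j]
            read_cols.append(read[i - 1])
            ref_cols.append(GAP)
            i -= 1
            state = 1 if p == 1 else 2
        else:
            p = pY[i, j]
            read_cols.append(GAP)
            ref_cols.append(ref[j - 1])
            j -= 1
            state = 1 if p == 1 else 3
    if bi == 0 and bj == 0:  # nothing aligned at all (score 0)
        i = j = 0
        read_cols = []
        ref_cols = []
    read_start, ref_start = i, j
    core_read = "".join(reversed(read_cols))
    core_ref = "".join(reversed(ref_cols))
    head = read[:read_start]
    tail = read[bi:]
    return PairwiseAlignment(
        read_row=head + core_read + tail,
        ref_row=GAP * len(head) + core_ref + GAP * len(tail),
        score=float(best),
        ref_start=ref_start,
        ref_end=bj,
        read_start=read_start,
        read_end=bi,
    )


def _ungapped_shortcut(
    read: str, ref: str, cfg: RunConfig
) -> PairwiseAlignment | None:
    """Full-length ungapped alignment when it is provably optimal.

    Requires few enough mismatches that any gap-containing alignment
    scores strictly worse (x * (match - mismatch) < -gap_open), none of
    them within 8 bp of a read end so no clipped alignment can shed them
    cheaply either.
    """
    m, n = len(read), len(ref)
    if m < 30 or m > n:
        return None
    # any gap opening must cost more than the mismatches it could save
    x_max = int(np.ceil(-cfg.gap_open / (cfg.match - cfg.mismatch))) - 1
    if x_max < 0:
        return None
    rc = encode(read)
    refc = encode(ref)
    windows = np.lib.stride_tricks.sliding_window_view(refc, m)
    mism = (windows != rc).sum(axis=1)
    off = int(np.argmin(mism))
    x = int(mism[off])
    if x > x_max:
        return None
    if x:
        pos = np.nonzero(windows[off] != rc)[0]
        if pos.min() < 8 or pos.max() >= m - 8:
            return None
    score = (m - x) * cfg.match + x * cfg.mismatch
    return PairwiseAlignment(
        read_row=read,
        ref_row=ref[off : off + m],
        score=float(score),
        ref_start=off,
        ref_end=off + m,
        read_start=0,
        read_end=m,
    )


def align_semi_global(
    read: str, ref: ReferenceAmplicon | str, cfg: RunConfig
) -> PairwiseAlignment:
    """Optimal free-end-gap affine alignment of ``read`` against ``ref``."""
    if not read:
        raise ValueError("cannot align an empty read")
    ref_seq = ref.sequence if isinstance(ref, ReferenceAmplicon) else ref
    fast = _ungapped_shortcut(read, ref_seq, cfg)
    if fast is not None:
        return fast
    mats = _sw_affine(
        encode(read),
        encode(ref_seq),
        float(cfg.match),
        float(cfg.mismatch),
        float(cfg.gap_open),
        float(cfg.gap_extend),
    )
    return _traceback(read, ref_seq, mats)


def passes_score_filter(
    aln: PairwiseAlignment, read_length: int, cfg: RunConfig
) -> bool:
    """True iff score >= min_fraction of the perfect-read score (inclusive)."""
    return aln.score >= cfg.min_alignment_score_fraction * read_length * cfg.match


def render_alignment(aln: PairwiseAlignment, itd=None, width: int = 60) -> str:
    """Human-readable alignment block in the style of the clone reports.

    Three lines per wrap: read row, a connector row ('|' match, '.'
    mismatch, blank at gap columns), reference row.  When an ITD call is
    supplied a fourth marker line flags insert columns with 'i' and the
    wild-type tandem columns with 't'.
    """
    connector = []
    for a, b in zip(aln.read_row, aln.ref_row):
        if a == GAP or b == GAP:
            connector.append(" ")
        elif a == b:
            connector.append("|")
        else:
            connector.append(".")
    connector = "".join(connector)

    marker = None
    if itd is not None:
        cand = getattr(itd, "insert", itd)
        marks = [" "] * len(aln.read_row)
        ref_i = aln.ref_start
        read_pos = 0
        for col, (a, b) in enumerate(zip(aln.read_row, aln.ref_row)):
            if a != GAP:
                if cand.read_offset <= read_pos < cand.read_offset + cand.length:
                    marks[col] = "i"
                read_pos += 1
            if b != GAP:
                tstart = getattr(itd, "tandem_start", None)
                if tstart is not None and tstart <= ref_i < itd.tandem_end:
                    marks[col] = "t"
                ref_i += 1
        marker = "".join(marks)

    blocks = []
    for start in range(0, len(aln.read_row), width):
        end = start + width
        lines = [
            f"read {aln.read_row[start:end]}",
            f"     {connector[start:end]}",
            f"ref  {aln.ref_row[start:end]}",
        ]
        if marker is not None:
            lines.append(f"itd  {marker[start:end]}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks)
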