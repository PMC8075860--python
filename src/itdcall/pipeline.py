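"""End-to-end sample processing: reads in, clone table out.

The stages mirror the assay's analysis: FASTQ -> quality filter ->
orient mate 2 -> collapse identical sequences -> align each unique
sequence once -> extract and verify insert candidates -> merge calls
into clones -> quantify (coverage, VAF, AR) -> filter -> report.
Every per-read result is weighted by the unique sequence's multiplicity,
so collapsing changes no downstream count.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import clones as clones_mod
from .align import align_semi_global, passes_score_filter
from .clones import CloneRecord, CloneTrajectory
from .detect import ITDCall, count_deletions, extract_inserts, find_tandem
from .preprocess import (
    FilterStats,
    SequencingRead,
    UniqueRead,
    collapse_unique,
    orient_reads,
    quality_filter,
    read_fastq,
)
from .reference import ReferenceAmplicon, RunConfig

CLONE_COLUMNS = [
    "sample",
    "insert",
    "length",
    "exact_length",
    "ref_pos",
    "annotation",
    "trailing",
    "supporting_reads",
    "supporting_unique",
    "coverage",
    "vaf",
    "ar",
]


@dataclass
class SampleSummary:
    sample: str = "sample"
    reads_in: int = 0
    qc_passed: int = 0
    unique_sequences: int = 0
    aligned: int = 0              # reads (weighted) passing the score filter
    itd_supporting: int = 0       # reads (weighted) with a verified ITD call
    deletion_reads: int = 0
    clone_count: int = 0
    parameters: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("reads_in", self.reads_in),
            ("qc_passed", self.qc_passed),
            ("unique_sequences", self.unique_sequences),
            ("aligned", self.aligned),
            ("itd_supporting", self.itd_supporting),
            ("deletion_reads", self.deletion_reads),
            ("clone_count", self.clone_count),
        ] + sorted(self.parameters.items())
        return pd.DataFrame(rows, columns=["key", "value"])


@dataclass
class SampleResult:
    sample: str
    clones: list[CloneRecord]
    filtered: list[tuple[CloneRecord, str]]
    non_itd_insertions: pd.DataFrame
    filter_stats: FilterStats
    summary: SampleSummary

    def clone_table(self) -> pd.DataFrame:
        return clones_to_frame(self.clones, self.sample)


def clones_to_frame(clones: Sequence[CloneRecord], sample: str) -> pd.DataFrame:
    rows = [
        {
            "sample": sample,
            "insert": c.consensus_insert,
            "length": c.length_estimate,
            "exact_length": c.exact_length,
            "ref_pos": c.ref_pos,
            "annotation": c.annotation,
            "trailing": c.trailing,
            "supporting_reads": c.supporting_reads,
            "supporting_unique": c.supporting_unique,
            "coverage": c.coverage,
            "vaf": c.vaf,
            "ar": c.ar,
        }
        for c in clones
    ]
    return pd.DataFrame(rows, columns=CLONE_COLUMNS)


def run_reads(
    reads: Sequence[SequencingRead],
    ref: ReferenceAmplicon,
    cfg: Optional[RunConfig] = None,
    sample: str = "sample",
) -> SampleResult:
    """Run the pipeline on in-memory reads (see :func:`run_sample`)."""
    cfg = cfg or RunConfig()
    passed, stats = quality_filter(reads, cfg.min_mean_quality)
    uniques = collapse_unique(orient_reads(passed))

    aligned_weight = 0
    deletion_weight = 0
    spans: list[tuple[int, int, int]] = []       # (ref_start, ref_end, count)
    span_by_unique: dict[int, tuple[int, int]] = {}
    mate_site_coverage: dict[int, set[int]] = {}
    calls: list[tuple[ITDCall, int]] = []
    non_itd: dict[tuple, int] = {}

    for unique in uniques:
        aln = align_semi_global(unique.bases, ref, cfg)
        if not passes_score_filter(aln, len(unique.bases), cfg):
            continue
        aligned_weight += unique.count
        spans.append((aln.ref_start, aln.ref_end, unique.count))
        span_by_unique[id(unique)] = (aln.ref_start, aln.ref_end)
        if count_deletions(aln, 1):
            deletion_weight += unique.count
        for cand in extract_inserts(aln, cfg.min_insert_length):
            cand.source = unique
            call = find_tandem(cand, ref, cfg)
            if call is None:
                key = (cand.sequence, cand.ref_pos, cand.trailing)
                non_itd[key] = non_itd.get(key, 0) + unique.count
            else:
                calls.append((call, unique.count))

    merged = clones_mod.merge_calls(calls, cfg)

    # which mates produced spanning reads at each called site (for the
    # paired-end artifact filter); cached per distinct site
    has_pairs = any(u.source_mates.get(2) for u in uniques)
    if cfg.require_both_mates and has_pairs:
        for clone in merged:
            p = clone.ref_pos
            if p in mate_site_coverage:
                continue
            covering: set[int] = set()
            lo = max(p - 1, 0)
            hi = min(p + 1, len(ref))
            for unique in uniques:
                span = span_by_unique.get(id(unique))
                if span and span[0] <= lo and span[1] >= hi:
                    covering |= {m for m, c in unique.source_mates.items() if c}
            mate_site_coverage[p] = covering

    clones_mod.quantify_clones(merged, spans, ref, cfg, span_by_unique)
    kept, audit = clones_mod.apply_filters(merged, cfg, mate_site_coverage)

    non_itd_frame = pd.DataFrame(
        [
            {"insert": seq, "ref_pos": pos, "trailing": trailing, "reads": count}
            for (seq, pos, trailing), count in sorted(non_itd.items())
        ],
        columns=["insert", "ref_pos", "trailing", "reads"],
    )

    summary = SampleSummary(
        sample=sample,
        reads_in=stats.reads_in,
        qc_passed=stats.reads_passed,
        unique_sequences=len(uniques),
        aligned=aligned_weight,
        itd_supporting=sum(count for _, count in calls),
        deletion_reads=deletion_weight,
        clone_count=len(kept),
        parameters={
            "min_insert_length": cfg.min_insert_length,
            "min_mean_quality": cfg.min_mean_quality,
            "min_alignment_score_fraction": cfg.min_alignment_score_fraction,
            "tandem_max_mismatch_fraction": cfg.tandem_max_mismatch_fraction,
            "min_supporting_reads": cfg.min_supporting_reads,
            "merge_site_tolerance": cfg.merge_site_tolerance,
        },
    )
    return SampleResult(
        sample=sample,
        clones=kept,
        filtered=audit,
        non_itd_insertions=non_itd_frame,
        filter_stats=stats,
        summary=summary,
    )


def run_sample(
    r1: str | os.PathLike,
    r2: str | os.PathLike | None = None,
    ref: ReferenceAmplicon | None = None,
    cfg: Optional[RunConfig] = None,
    sample: Optional[str] = None,
    out_dir: str | os.PathLike | None = None,
) -> SampleResult:
    """Call ITD clones for one sample from FASTQ file(s).

    When ``out_dir`` is given, writes four fixed-format TSVs there:
    ``<sample>.clones.tsv`` (the final call set), ``.insertions.tsv``
    (non-ITD insertions), ``.filtered.tsv`` (audit of removed clones) and
    ``.summary.tsv`` (stage counts and parameters).  Floating point
    values are printed with 6 significant digits.
    """
    if ref is None:
        raise ValueError("a reference amplicon is required")
    if sample is None:
        sample = os.path.basename(str(r1)).split(".")[0]
    paths = (r1,) if r2 is None else (r1, r2)
    reads = list(read_fastq(*paths))
    result = run_reads(reads, ref, cfg, sample=sample)
    if out_dir is not None:
        write_tables(result, out_dir)
    return result


def write_tables(result: SampleResult, out_dir: str | os.PathLike) -> dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    base = os.path.join(str(out_dir), result.sample)
    paths = {
        "clones": f"{base}.clones.tsv",
        "insertions": f"{base}.insertions.tsv",
        "filtered": f"{base}.filtered.tsv",
        "summary": f"{base}.summary.tsv",
    }
    result.clone_table().to_csv(
        paths["clones"], sep="\t", index=False, float_format="%.6g"
    )
    result.non_itd_insertions.to_csv(
        paths["insertions"], sep="\t", index=False, float_format="%.6g"
    )
    audit = clones_to_frame([c for c, _ in result.filtered], result.sample)
    audit["reason"] = [reason for _, reason in result.filtered]
    audit.to_csv(paths["filtered"], sep="\t", index=False, float_format="%.6g")
    result.summary.to_frame().to_csv(
        paths["summary"], sep="\t", index=False, float_format="%.6g"
    )
    return paths


def trajectories_to_frame(
    trajectories: Sequence[CloneTrajectory], labels: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for t in trajectories:
        row = {
            "insert": t.consensus_insert,
            "length": t.length_estimate,
            "ref_pos": t.ref_pos,
            "trailing": t.trailing,
            "category": t.category,
        }
        for label, vaf in zip(labels, t.vafs):
            row[f"vaf_{label}"] = "" if vaf is None else vaf
        rows.append(row)
    return pd.DataFrame(rows)


def read_clone_table(path: str | os.PathLike) -> list[CloneRecord]:
    """Load a clone TSV written by :func:`write_tables` back into records."""
    df = pd.read_csv(path, sep="\t", dtype={"insert": str, "annotation": str})
    out = []
    for _, row in df.iterrows():
        out.append(
            CloneRecord(
                consensus_insert=row["insert"],
                length_estimate=int(row["length"]),
                ref_pos=int(row["ref_pos"]),
                trailing=bool(row["trailing"]),
                exact_length=bool(row["exact_length"]),
                supporting_reads=int(row["supporting_reads"]),
                supporting_unique=int(row["supporting_unique"]),
                coverage=int(row["coverage"]),
                vaf=float(row["vaf"]),
                ar=float(row["ar"]),
                annotation="" if pd.isna(row["annotation"]) else str(row["annotation"]),
            )
        )
    return out
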