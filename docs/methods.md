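# Methods

## Model of the mutation

An internal tandem duplication (ITD) is modelled as a reference segment
`ref[d : d+L)` duplicated in place: the mutant allele is
`ref[: d+L) + ref[d : d+L) + ref[d+L :)`.  All coordinates are 0-based;
an insertion "at position p" sits between `ref[p−1]` and `ref[p]`, and
intervals are half-open.  Because the two copies are identical, the
junction is only defined up to slippage within the repeat: duplicating
`[d, d+L)` and `[d+k, d+L+k)` produces the same allele string whenever
the flanking bases coincide.  The caller therefore reports one canonical
placement (the leftmost produced by its deterministic traceback) and all
equivalence-sensitive comparisons — clone merging, simulation evaluation
— accept either junction of the repeat within the site tolerance.

The reference is the sequenced amplicon itself (a few hundred bp), not a
genome.  Protein or transcript annotation is an optional user-supplied
per-position lookup table; the package makes no assumption about the
numbering scheme.

## Alignment

Each distinct read sequence is aligned once against the amplicon with
affine gap scoring (gap of length k costs `open + (k−1)·extend`) and free
end gaps on both sequences, computed as a maximal-scoring local alignment
(Smith–Waterman–Gotoh).  Under a positive match reward the two
formulations coincide, and the local form naturally soft-clips read
sequence that has no adjacent reference counterpart — which is exactly
the signature of a trailing ITD.

Default scores: match +5, mismatch −15, gap open −36, gap extend −0.5.
Two properties drove this choice and are worth preserving when tuning:

* the mismatch penalty must exceed the match reward by enough that
  spurious extension of an alignment across the duplication junction
  into merely-similar sequence has a steeply negative score drift
  (with −4 instead of −15 the aligner demonstrably chases chance
  similarity past the clip point and corrupts trailing length
  estimates);
* the gap-open penalty must be large enough that scattered short gaps
  never beat one contiguous insert run, but small enough that a true
  insert plus its anchors always outscores clipping.  With these values
  an internal (non-trailing) insert of length L is preferred over
  clipping when the upstream anchor exceeds ≈ 1.1·L + 7 bp and the
  downstream anchor exceeds ≈ 7 + 0.1·L bp; longer duplications surface
  as soft-clipped overhangs instead, which is the trailing pathway.
  This reproduces the geometric rule that duplications with
  2·L > read length cannot be fully anchored.

Traceback tie-breaking prefers diagonal over insertion over deletion, and
the earliest maximal cell, making results bit-stable across runs.  Reads
that match the reference ungapped with at most one interior mismatch
(none within 8 bp of a read end) skip the dynamic program after an exact
sliding-window check; for such reads the ungapped alignment is provably
optimal under the default-style scoring, and in deep amplicon data this
covers the overwhelming majority of wild-type reads.  The kernel is
numba-compiled; a pure-Python brute-force scorer and Biopython's
`PairwiseAligner` serve as independent oracles in the test suite.

Alignments scoring below half the perfect-read score
(`min_alignment_score_fraction = 0.5`) are discarded as off-target or
garbage.  Note this filter also bounds how short a trailing anchor can
be in practice: a read must still align over at least half its length.

## Insert extraction and tandem verification

Reference-row gap runs ≥ `min_insert_length` (default 6 bp) that are
fully enclosed by aligned sequence become non-trailing candidates with
exact length.  Soft-clipped overhangs ≥ 6 bp at either read end become
trailing candidates.  Read-row gap runs (deletions) are counted in the
summary but never called — the method targets duplications.

A candidate is verified by matching its sequence against reference
windows (vectorised Hamming scan; a gapped fallback alignment handles
inserts that carry small indels).  A call requires window identity
≥ 1 − `tandem_max_mismatch_fraction` (default 0.1, allowing ITDs with
point mutations or non-templated junction bases) *and* tandem adjacency:

* non-trailing: the window must start or end within
  `merge_site_tolerance` (3 bp) of the insertion point; the adjacent
  upstream window is tested first, then downstream, then the scan.
* trailing, 3′ overhang: the window must start ≥ 6 bp upstream of the
  clip point; the duplication length estimate is
  `clip_point − window_start`.  The overhang may run past the second
  copy into wild-type sequence; the offset rule is unaffected.
* trailing, 5′ overhang: mirror image; estimate is
  `window_end − alignment_start`.

On error-free simulated reads the offset estimate is exact even when
junction slippage shifts the clip point, because clip point and window
shift together; in real data junction artifacts perturb it by a few
bases, so trailing estimates are flagged non-exact and treated as
±3 bp throughout.  Candidates without a tandem-compatible window are
reported in a separate non-ITD insertion table.

## Clones and quantification

Calls merge into one clone when trailing status and (for trailing) clip
side agree, lengths agree (exactly for non-trailing, within 3 bp for
trailing estimates), sites are within `merge_site_tolerance`, and the
sequenced portions are identical over their overlap (common prefix for
3′ overhangs, common suffix for 5′ overhangs).  Merging is the
transitive closure of this pairwise rule; equal sequences are grouped by
hash first so deep samples with many singleton error variants stay
near-linear.  Trailing and non-trailing clones are never merged by
default — they are different evidence classes.  The consensus insert is
the most-supported sequence.  A consequence of requiring overlap
identity is that reads whose sequencing error falls inside the insert
form small sibling clones next to the main one; the simulation
evaluator therefore sums clones matching the simulated duplication.

Coverage at a site counts reads whose alignment spans both flanking
bases (the single existing flank at the amplicon boundaries), plus
ITD-supporting reads whose soft-clipped alignment stops at the junction
— they derive from molecules spanning the site by construction.
VAF = supporting/covering reads; AR = VAF/(1−VAF).  The denominator
counts reads, mate-aware (each mate once), not fragments.

Filters: clones need `min_supporting_reads` (default 2; there is
deliberately no VAF floor, since the support requirement is what limits
detection at high depth).  With paired-end data, a clone at a site
covered by both mates' windows must be supported by both mates.  Clone
identity across serial samples reuses exactly the within-sample merge
rule, avoiding silent identity drift in MRD series; trajectories are
categorised persisting / lost / gained relative to the first and last
timepoints (transient for middle-only detections).

## Simulator

The simulator emulates the fixed-primer amplicon assay: single-end reads
start at a configurable amplicon offset (default the 5′ end); paired
mode takes mate 1 from the 5′ end and mate 2 reverse-complemented from
the 3′ end.  Mixtures are either count-exact (deterministic allele
counts, used for all headline VAF recoveries) or sampled (multinomial
allele of origin, emulating dilution noise).  Errors are uniform
per-base substitutions at a configurable rate with constant Q37
qualities — Illumina amplicon errors are substitution-dominated, and a
substitution-only model keeps the specificity experiment crisp.  An
optional per-copy mismatch count stress-tests the tandem identity
tolerance.  Not modelled: PCR bias and chimeras, indel sequencing
errors, quality-score profiles, primer artifacts.  Passing tests on
simulated data therefore demonstrate the correctness of the detection
arithmetic and its noise robustness to substitution errors, not
robustness to every artifact of real libraries.

The packaged default reference is a fixed synthetic 600 bp amplicon
generated once from a seeded random sequence and committed verbatim; it
contains no internal exact repeat ≥ 10 bp, so simulated tandems are
unambiguous.  Real analyses must supply the actual amplicon FASTA.

## Validation problem sizes

The acceptance script and test suite use: 1,000 reads per length for the
minimum-insert scan; 10 samples × 50,000 reads (0.1 % substitution
errors) for specificity; 100,000 reads per count-exact VAF recovery;
1,000,000 reads for the 0.0067 % limit-of-detection mixture; and a
five-step 1:10 dilution from 67 % VAF with 300,000 sampled reads per
step (100,000 in the test suite) with 0.1 % errors.  These sizes give
count-exact targets that are deterministic and stochastic targets whose
sampling noise is far below the tolerances asserted.

## Known limitations

* ITDs longer than `read_length − min_insert_length` (244 bp at
  defaults) are invisible; in practice the score filter and anchor
  economics bound reliable trailing calls somewhat lower.
* Non-trailing calls require the scoring-dependent anchor geometry
  above; duplications between roughly 45 % and 50 % of the read length
  may be reported trailing (with a ±3 bp estimate) rather than exact.
* Trailing estimates from very short overhangs are only as unique as
  the overhang sequence; a 6 bp overhang can match multiple windows.
* Mixed 5′/3′ trailing evidence for the same duplication (e.g. from
  opposite-end read geometries) is reported as two clones, one per clip
  side, because their insertion-point coordinates differ by the
  duplication length.
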