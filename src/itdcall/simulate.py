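"""Synthetic amplicon read simulator and evaluation helpers.

Emulates the targeted two-step PCR assay: every read derives from a fixed
position of the amplicon (mate 1 from the 5' end, mate 2 from the 3' end
on the opposite strand), so the simulator produces 250 bp reads from the
wild-type amplicon and from ITD-bearing alleles (a reference segment
duplicated in place), mixed either count-exactly or by sampling, with
optional uniform per-base substitution errors and constant Q37 quality
strings.  Count-exact mixtures make VAF recoveries deterministic, which
is what the validation experiments need; sampled mixtures emulate the
binomial noise of a real dilution.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import reverse_complement
from .reference import ReferenceAmplicon, RunConfig

#: Fixed synthetic 600 bp amplicon used as the default simulation target.
#: Generated once from a seeded random sequence and committed verbatim so
#: the package is self-contained; the real FLT3 exon 14-15 amplicon is a
#: user input, not shipped.  It has no internal exact repeat of >= 10 bp,
#: so any tandem the detector reports on simulated data is one the
#: simulator put there.
SYNTHETIC_AMPLICON = (
    "GCGAGCACTCCGGCGCGAAAAGAAAAGCGAAACGCCGCAGCGTGTAACCCGCGAAACAATCCGCAGCATA"
    "GCCTTTACCTGACATCCTCGGTGGCGTCCTTGCAGTATCTTAATACATGTCGATGATCCGCCGTGCCCTT"
    "CCATACTCCTCGGAAGCAGTGGGACCATACATCCGGTACGACCATGTCTTATCCCCCGGTATAACATCGC"
    "CCTTTCCAGGAGAGCCTCACATAATGAGCTGCTTGTCCTCCTATTGTTCAGTACGGCTACGACACATCCA"
    "GCAGATTAGAAACTGCTACGAGAGCGCGGACTCACTGGAGCACCAAACCGAGACGAGTGTACGGATCCGA"
    "TCTCCTTCAGACACAAGTCAGCAGATTGTGCAAATGGAGACCTAAACGCGCGAGAGCCATCTTAGTGAGA"
    "CACGCTCAATTGGTTAACAGAATCAGACGCTCTTACATCTTGGAGGAGCCGCGTCTCGGATTCAGAGACC"
    "GCAGAATACCCGGGCTGGAACTCTTAATTGATCCCAGATAATGCTTAACAAGGCGGCTCCTATGGCTTGT"
    "GAGCGATGTCCTTTGTCGCGAGGGTGGAGAAAGTCCTGGT"
)

_BASES = np.frombuffer(b"ACGT", np.uint8)


def default_reference() -> ReferenceAmplicon:
    return ReferenceAmplicon("synthetic_amplicon", SYNTHETIC_AMPLICON)


@dataclass(frozen=True)
class ITDSpec:
    """A tandem duplication: ref[dup_start : dup_start+dup_length) repeated.

    The duplicated copy is inserted immediately after the original, so the
    insertion site (first reference base after the insert) is
    ``dup_start + dup_length``.  ``extra_mismatches`` point changes are
    injected into the second copy only, emulating ITDs that carry
    non-templated or mutated bases.
    """

    dup_start: int
    dup_length: int
    extra_mismatches: int = 0

    @property
    def insertion_site(self) -> int:
        return self.dup_start + self.dup_length

    def validate(self, ref_length: int) -> None:
        if self.dup_length < 1:
            raise ValueError("dup_length must be >= 1")
        if self.dup_start < 0 or self.insertion_site > ref_length:
            raise ValueError("duplicated segment must lie within the reference")
        if self.extra_mismatches > self.dup_length:
            raise ValueError("more mismatches than duplicated bases")


@dataclass
class MixtureSpec:
    """A mixture of alleles to sequence.

    ``alleles`` pairs each allele (an ITDSpec, or None for wild type) with
    either an exact read count (``count_exact=True``) or a fraction of
    ``total_reads`` to be drawn multinomially.  ``offset`` is the 0-based
    allele position single-end reads start from.
    """

    alleles: Sequence[tuple[Optional[ITDSpec], float]]
    total_reads: int = 0
    count_exact: bool = True
    read_length: int = 250
    substitution_error_rate: float = 0.0
    seed: int = 0
    paired: bool = False
    offset: int = 0

    def __post_init__(self) -> None:
        if self.count_exact:
            counts = [c for _, c in self.alleles]
            if any(int(c) != c or c < 0 for c in counts):
                raise ValueError("count_exact mixtures need non-negative integer counts")
            total = int(sum(counts))
            if self.total_reads and total != self.total_reads:
                raise ValueError(
                    f"allele counts sum to {total}, expected total_reads={self.total_reads}"
                )
            self.total_reads = total
        else:
            if self.total_reads <= 0:
                raise ValueError("sampled mixtures need total_reads > 0")


@dataclass
class SimulatedRead:
    bases: str
    mate: int
    allele: int  # index into MixtureSpec.alleles


def make_itd_allele(
    ref: ReferenceAmplicon, spec: ITDSpec, rng: Optional[np.random.Generator] = None
) -> str:
    """Allele sequence carrying the tandem duplication of ``spec``."""
    spec.validate(len(ref))
    seq = ref.sequence
    copy = seq[spec.dup_start : spec.insertion_site]
    if spec.extra_mismatches:
        if rng is None:
            rng = np.random.default_rng(0)
        arr = np.frombuffer(copy.encode(), np.uint8).copy()
        pos = rng.choice(len(arr), size=spec.extra_mismatches, replace=False)
        for p in pos:
            choices = _BASES[_BASES != arr[p]]
            arr[p] = rng.choice(choices)
        copy = arr.tobytes().decode()
    out = seq[: spec.insertion_site] + copy + seq[spec.insertion_site :]
    assert len(out) == len(seq) + spec.dup_length
    return out


def _apply_errors(
    seqs: list[str], rate: float, rng: np.random.Generator
) -> list[str]:
    if rate <= 0:
        return seqs
    out = []
    lengths = np.array([len(s) for s in seqs])
    n_err = rng.binomial(lengths, rate)
    for seq, k in zip(seqs, n_err):
        if k == 0:
            out.append(seq)
            continue
        arr = np.frombuffer(seq.encode(), np.uint8).copy()
        pos = rng.choice(len(arr), size=k, replace=False)
        for p in pos:
            choices = _BASES[_BASES != arr[p]]
            arr[p] = choices[rng.integers(len(choices))]
        out.append(arr.tobytes().decode())
    return out


def simulate_reads(
    ref: ReferenceAmplicon, mix: MixtureSpec
) -> list[SimulatedRead]:
    """Generate reads for a mixture, deterministically under its seed."""
    rng = np.random.default_rng(mix.seed)
    alleles = []
    for spec, _ in mix.alleles:
        alleles.append(
            ref.sequence if spec is None else make_itd_allele(ref, spec, rng)
        )
    for seq in alleles:
        if mix.read_length > len(seq):
            raise ValueError("read_length exceeds allele length")

    if mix.count_exact:
        counts = [int(c) for _, c in mix.alleles]
    else:
        fracs = np.array([f for _, f in mix.alleles], float)
        if not np.isclose(fracs.sum(), 1.0):
            raise ValueError("allele fractions must sum to 1")
        counts = rng.multinomial(mix.total_reads, fracs).tolist()

    reads: list[SimulatedRead] = []
    for idx, (seq, count) in enumerate(zip(alleles, counts)):
        if count == 0:
            continue
        if mix.paired:
            r1 = seq[: mix.read_length]
            r2 = reverse_complement(seq[-mix.read_length :])
            bases = [r1, r2] * count
            mates = [1, 2] * count
        else:
            start = min(mix.offset, len(seq) - mix.read_length)
            r1 = seq[start : start + mix.read_length]
            bases = [r1] * count
            mates = [1] * count
        bases = _apply_errors(bases, mix.substitution_error_rate, rng)
        reads.extend(
            SimulatedRead(b, m, idx) for b, m in zip(bases, mates)
        )
    return reads


def write_fastq(
    reads: Sequence[SimulatedRead],
    r1_path: str | os.PathLike,
    r2_path: str | os.PathLike | None = None,
    quality_char: str = "F",  # Phred 37
) -> None:
    """Write simulated reads as Phred+33 FASTQ (gzip if path ends in .gz)."""

    def opener(path):
        if str(path).endswith(".gz"):
            return gzip.open(path, "wt")
        return open(path, "w")

    handles = {1: opener(r1_path)}
    if r2_path is not None:
        handles[2] = opener(r2_path)
    try:
        counters = {1: 0, 2: 0}
        chunks: dict[int, list[str]] = {1: [], 2: []}
        for read in reads:
            mate = read.mate if read.mate in handles else 1
            counters[mate] += 1
            chunks[mate].append(
                f"@sim_{counters[mate]}_a{read.allele}/{mate}\n"
                f"{read.bases}\n+\n{quality_char * len(read.bases)}\n"
            )
            if len(chunks[mate]) >= 10000:
                handles[mate].write("".join(chunks[mate]))
                chunks[mate].clear()
        for mate, chunk in chunks.items():
            if chunk and mate in handles:
                handles[mate].write("".join(chunk))
    finally:
        for fh in handles.values():
            fh.close()


def simulate_dilution_series(
    ref: ReferenceAmplicon,
    itd: ITDSpec,
    start_vaf: float,
    dilution_factor: float = 10.0,
    n_steps: int = 5,
    reads_per_step: int = 300_000,
    seed: int = 0,
    count_exact: bool = False,
    substitution_error_rate: float = 0.0,
    read_length: int = 250,
    offset: int = 0,
) -> tuple[list[MixtureSpec], pd.DataFrame]:
    """Serial dilution of an ITD allele into wild type.

    Step i has expected VAF ``start_vaf / dilution_factor**i``.  In
    count-exact mode read counts are rounded to the nearest integer and
    the truth table records the realised (count-exact) fraction; in
    sampled mode each read's allele of origin is drawn binomially.
    Warns when the most dilute step expects fewer than one ITD read.
    """
    if not 0 < start_vaf < 1:
        raise ValueError("start_vaf must be in (0, 1)")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    expected = [start_vaf / dilution_factor**i for i in range(n_steps)]
    if expected[-1] * reads_per_step < 1:
        import warnings

        warnings.warn(
            "most dilute step expects < 1 supporting read; "
            "it will likely be reported ITD-negative",
            stacklevel=2,
        )
    mixtures: list[MixtureSpec] = []
    rows = []
    for i, vaf in enumerate(expected):
        if count_exact:
            n_itd = round(vaf * reads_per_step)
            mix = MixtureSpec(
                alleles=[(itd, n_itd), (None, reads_per_step - n_itd)],
                count_exact=True,
                read_length=read_length,
                substitution_error_rate=substitution_error_rate,
                seed=seed + i,
                offset=offset,
            )
            truth_vaf = n_itd / reads_per_step
        else:
            mix = MixtureSpec(
                alleles=[(itd, vaf), (None, 1.0 - vaf)],
                total_reads=reads_per_step,
                count_exact=False,
                read_length=read_length,
                substitution_error_rate=substitution_error_rate,
                seed=seed + i,
                offset=offset,
            )
            truth_vaf = vaf
        mixtures.append(mix)
        rows.append(
            {
                "sample": f"dilution_{i}",
                "expected_vaf": truth_vaf,
                "dup_start": itd.dup_start,
                "dup_length": itd.dup_length,
            }
        )
    return mixtures, pd.DataFrame(rows)


def measured_vaf(clones, spec: ITDSpec, site_tolerance: int = 3) -> float:
    """Total VAF of called clones attributable to a simulated duplication.

    A clone matches when its insertion point lies within ``site_tolerance``
    of either junction of the simulated repeat (tandem slippage makes the
    two equivalent) and its length agrees -- exactly for non-trailing
    clones, within the trailing estimate tolerance of 3 bp otherwise.
    Summing over matching clones mirrors how sequencing-error variants of
    one duplication are reported as sibling clones.
    """
    junctions = (spec.dup_start, spec.insertion_site)
    total = 0.0
    for clone in clones:
        if min(abs(clone.ref_pos - j) for j in junctions) > site_tolerance:
            continue
        delta = abs(clone.length_estimate - spec.dup_length)
        if delta <= (3 if clone.trailing else 0):
            total += clone.vaf
    return total


@dataclass
class EvalResult:
    """Expected-vs-measured VAF pairs and their linear-fit R^2."""

    expected: list[float]
    measured: list[float]
    r_squared: float


def linearity_r2(expected: Sequence[float], measured: Sequence[float]) -> EvalResult:
    """Ordinary least squares of measured on expected VAF; returns R^2.

    R^2 = 1 means the measured VAFs fall on one straight line through the
    expected values (linearity, not identity: a constant scale factor
    still gives R^2 = 1).
    """
    expected = [float(x) for x in expected]
    measured = [float(y) for y in measured]
    if len(expected) != len(measured) or len(expected) < 2:
        raise ValueError("need >= 2 expected/measured pairs")
    fit = stats.linregress(expected, measured)
    return EvalResult(expected, measured, float(fit.rvalue**2))
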