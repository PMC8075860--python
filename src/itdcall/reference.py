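"""Reference amplicon and run configuration.

The pipeline calls internal tandem duplications (ITDs) against a single
wild-type amplicon sequence -- typically the PCR product spanning FLT3
exons 14-15 -- rather than a whole-genome reference.  All coordinates are
0-based; an insertion "at position p" sits between ``ref[p-1]`` and
``ref[p]``, and intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field

from Bio import SeqIO

_VALID_REF = set("ACGT")


@dataclass(frozen=True)
class ReferenceAmplicon:
    """Wild-type target sequence with optional per-position annotation.

    Parameters
    ----------
    name
        Free-text label (FASTA header or user-supplied).
    sequence
        Uppercase DNA over {A, C, G, T}.  ``N`` is not permitted in the
        reference: an ambiguous reference base would make tandem
        verification unverifiable.
    annotation
        Optional mapping from 0-based reference position to an external
        label (e.g. transcript coordinate or protein codon).  When given it
        must cover every position exactly once.
    """

    name: str
    sequence: str
    annotation: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence is empty")
        bad = set(self.sequence) - _VALID_REF
        if bad:
            raise ValueError(
                f"reference contains invalid characters {sorted(bad)}; "
                "only A/C/G/T are allowed"
            )
        if self.annotation is not None:
            expected = set(range(len(self.sequence)))
            if set(self.annotation) != expected:
                raise ValueError(
                    "annotation must cover every reference position exactly once"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def annotate(self, pos: int) -> str:
        """External label for a 0-based position ('' when no annotation)."""
        if self.annotation is None:
            return ""
        return self.annotation.get(pos, "")


@dataclass
class RunConfig:
    """All tunable parameters of one pipeline run.

    Scores are encoded so that a higher alignment score is better: the
    match reward is positive, the mismatch/gap penalties negative.  A gap
    of length k costs ``gap_open + (k - 1) * gap_extend``.
    """

    min_insert_length: int = 6          # bp; shortest insert ever called
    read_length_hint: int = 250         # bp; expected read length of the assay
    min_mean_quality: float = 25.0      # Phred; mean base quality cutoff
    match: float = 5.0
    mismatch: float = -15.0
    gap_open: float = -36.0
    gap_extend: float = -0.5
    min_alignment_score_fraction: float = 0.5   # of read_length * match
    tandem_max_mismatch_fraction: float = 0.1
    min_supporting_reads: int = 2
    merge_site_tolerance: int = 3       # bp; site tolerance for tandem adjacency / merging
    trailing_length_tolerance: int = 3  # bp; merge window for trailing length estimates
    require_both_mates: bool = True     # paired data: demand support from both mates
    merge_trailing_with_exact: bool = False
    count_fragments: bool = False       # VAF denominator counts fragments, not reads
    random_seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_insert_length < 1:
            raise ValueError("min_insert_length must be >= 1")
        for name in ("min_alignment_score_fraction", "tandem_max_mismatch_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend > 0:
            raise ValueError("mismatch and gap scores must be penalties (<= 0)")
        if self.min_supporting_reads < 0:
            raise ValueError("min_supporting_reads must be >= 0")

    @classmethod
    def from_file(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        """Load a flat ``key=value`` config file; keyword overrides win.

        Lines starting with '#' and blank lines are ignored.  Unknown keys
        are an error so typos do not silently fall back to defaults.
        """
        values: dict[str, object] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
                values[key] = _coerce(val, fields[key].type)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _coerce(value: str, annot: object) -> object:
    text = str(annot)
    if "bool" in text:
        if value.lower() in ("1", "true", "yes", "on"):
            return True
        if value.lower() in ("0", "false", "no", "off"):
            return False
        raise ValueError(f"cannot parse boolean from {value!r}")
    if "int" in text:
        return int(value)
    if "float" in text:
        return float(value)
    return value


def load_reference(
    path_or_text: str | os.PathLike,
    name: str = "amplicon",
    annotation: dict[int, str] | None = None,
) -> ReferenceAmplicon:
    """Load the wild-type amplicon from a FASTA file or a bare string.

    Accepts either the path of a single-record FASTA file or the raw
    sequence itself.  Case and whitespace are normalised; characters
    outside A/C/G/T (including N) are rejected.
    """
    text = str(path_or_text)
    if os.path.exists(text) or text.lstrip().startswith(">"):
        if os.path.exists(text):
            with open(text) as fh:
                records = list(SeqIO.parse(fh, "fasta"))
        else:
            records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if len(records) == 0:
            raise ValueError(f"no FASTA record found in {text[:50]!r}")
        if len(records) > 1:
            raise ValueError(
                f"expected a single-record FASTA, found {len(records)} records"
            )
        name = records[0].id or name
        seq = str(records[0].seq)
    else:
        seq = text
    seq = "".join(seq.split()).upper()
    return ReferenceAmplicon(name=name, sequence=seq, annotation=annotation)


def load_annotation(path: str | os.PathLike) -> dict[int, str]:
    """Read a 2-column TSV of ``position<TAB>label`` (0-based positions)."""
    table: dict[int, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            pos, _, label = line.partition("\t")
            table[int(pos)] = label
    return table


def write_fasta(ref: ReferenceAmplicon, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, len(ref.sequence), 70):
            fh.write(ref.sequence[i : i + 70] + "\n")


def max_detectable_itd_length(read_length: int, min_insert_length: int) -> int:
    """Longest ITD insert a single read of ``read_length`` bp can reveal.

    An insert is only callable if, besides the inserted bases, the read
    retains at least ``min_insert_length`` anchoring bases; the bound is
    therefore ``read_length - min_insert_length`` (244 bp for the 250 bp /
    6 bp defaults of the assay).  Longer duplications are invisible to the
    method and this limit should be reported with any negative result.
    """
    if min_insert_length < 1:
        raise ValueError("min_insert_length must be >= 1")
    if read_length < min_insert_length:
        raise ValueError(
            f"read_length ({read_length}) must be >= min_insert_length "
            f"({min_insert_length})"
        )
    return read_length - min_insert_length
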