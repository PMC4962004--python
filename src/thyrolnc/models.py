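"""Core domain types shared across the pipeline stages.

Coordinates are 0-based half-open everywhere inside the package; the GTF
boundary convention (1-based inclusive) is converted at the I/O edge only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class TranscriptModel:
    """One assembled transcript model.

    ``exons`` is an ordered tuple of ``(start, end)`` intervals, sorted,
    non-overlapping and non-adjacent (introns are at least one base).
    ``source_assembler`` and ``sample_id`` record provenance; ``coverage``
    is the assembler-reported read coverage of the model.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source_assembler: str = ""
    sample_id: str = ""
    coverage: float = 0.0
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs at least one exon")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"{self.transcript_id}: empty or inverted exon [{start}, {end})")
            if prev_end is not None and start <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons must be sorted with introns >= 1 base"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        """Total exonic (spliced) length in bases."""
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


def structure_key(model: TranscriptModel) -> str:
    """Deduplication key for pooled transcript models.

    Multi-exon transcripts are identified by their intron chain on a given
    chromosome and strand (Cuffcompare-style), so models differing only in
    the ends of terminal exons collapse to one structure.  Single-exon
    transcripts fall back to the exact exon interval.
    """
    if model.n_exons >= 2:
        chain = ",".join(f"{s}-{e}" for s, e in model.introns)
        return f"{model.chrom}:{model.strand}:I:{chain}"
    (s, e), = model.exons
    return f"{model.chrom}:{model.strand}:SE:{s}-{e}"


@dataclass
class SupportRecord:
    """A deduplicated transcript structure with its observed support."""

    key: str
    samples: set[str]
    assemblers: set[str]
    representative: TranscriptModel
    coverage: float  # max coverage over all occurrences

    def is_reliable(self) -> bool:
        """Found in at least two samples, or by both assemblers."""
        return len(self.samples) >= 2 or len(self.assemblers) >= 2


DISCARD_REASONS = (
    "unreliable",
    "low_coverage",
    "single_exon",
    "too_short",
    "annotated_noncoding_biotype",
    "none",
)


@dataclass
class CodingVerdict:
    """Per-scorer output of the coding-potential consensus.

    ``consensus`` is the OR of the four flags: a transcript is treated as
    coding if *any* scorer calls it coding.
    """

    hexamer_score: float
    hexamer_coding: bool
    orf_fraction_score: float
    orf_fraction_coding: bool
    domain_evalue: float
    domain_coding: bool
    longest_orf_codons: int
    orf_coding: bool

    @property
    def consensus(self) -> bool:
        return (
            self.hexamer_coding
            or self.orf_fraction_coding
            or self.domain_coding
            or self.orf_coding
        )


@dataclass
class ClassifiedTranscript:
    """A transcript with its pipeline fate."""

    key: str
    label: str  # known_mRNA | novel_mRNA | candidate_lncRNA | discarded
    discard_reason: str = "none"
    matched_annotation_id: Optional[str] = None
    representative: Optional[TranscriptModel] = None
    verdict: Optional[CodingVerdict] = None

    def __post_init__(self) -> None:
        if (self.label == "discarded") != (self.discard_reason != "none"):
            raise ValueError("discard_reason must be set iff label == 'discarded'")


@dataclass(frozen=True)
class CisPair:
    """A differentially expressed lncRNA gene joined to a DE mRNA gene."""

    lnc_gene_id: str
    mrna_gene_id: str
    distance: int  # signed gap between gene bodies; 0 when overlapping
    relative_position: str  # upstream | downstream | overlapping
    direction_class: str  # e.g. "up-up", "down-up"

    @property
    def same_direction(self) -> bool:
        a, b = self.direction_class.split("-")
        return a == b


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics for one group of animals: mean, SEM and n."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("GroupSummary requires n >= 2")
        if self.sem <= 0:
            raise ValueError("GroupSummary requires sem > 0")


@dataclass(frozen=True)
class AlignmentHit:
    """Best local-alignment hit of a query against a subject sequence."""

    query_id: str
    subject_id: str
    score: int
    evalue: float
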