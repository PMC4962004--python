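"""Open reading frame scanning.

An ORF is defined here as an ATG followed by an in-frame stop codon
(TAA/TAG/TGA); its length in codons counts the codons from the ATG up to
but excluding the stop.  All six frames (three on each strand) are
scanned.  This complete-ORF definition is used consistently by the
coding-potential scorers and by the synthetic-data generator that plants
(or destroys) ORFs.
"""
from __future__ import annotations

from dataclasses import dataclass

STOP_CODONS = {"TAA", "TAG", "TGA"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Orf:
    """One open reading frame found in a transcript sequence.

    ``start`` is the 0-based offset of the ATG in the scanned strand's
    sequence; ``strand`` is "+" for the given sequence, "-" for its
    reverse complement.  ``codons`` excludes the stop codon.
    """

    strand: str
    frame: int
    start: int
    codons: int

    @property
    def nt_length(self) -> int:
        return self.codons * 3


def _scan_strand(seq: str, strand: str) -> list[Orf]:
    orfs: list[Orf] = []
    n = len(seq)
    for frame in range(3):
        start_pos: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if start_pos is not None:
                    orfs.append(Orf(strand, frame, start_pos, (i - start_pos) // 3))
                    start_pos = None
            elif start_pos is None and codon == "ATG":
                start_pos = i
        # an ATG with no downstream in-frame stop is not a complete ORF
    return orfs


def find_orfs(seq: str) -> list[Orf]:
    """All complete ORFs in the six frames of ``seq``."""
    seq = seq.upper()
    return _scan_strand(seq, "+") + _scan_strand(reverse_complement(seq), "-")


def longest_orf(seq: str) -> Orf | None:
    """The longest six-frame ORF, or None if no complete ORF exists.

    Ties break toward the forward strand, then lower frame, then lower
    start, so the result is deterministic.
    """
    orfs = find_orfs(seq)
    if not orfs:
        return None
    return max(orfs, key=lambda o: (o.codons, o.strand == "+", -o.frame, -o.start))


def longest_orf_codons(seq: str) -> int:
    orf = longest_orf(seq)
    return 0 if orf is None else orf.codons


def orf_sequence(seq: str, orf: Orf) -> str:
    """Nucleotide sequence of an ORF (ATG..last sense codon, no stop)."""
    s = seq.upper() if orf.strand == "+" else reverse_complement(seq.upper())
    return s[orf.start : orf.start + orf.nt_length]
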