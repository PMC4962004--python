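"""GTF and FASTA readers/writers.

GTF files are 1-based with inclusive ends; internally the package uses
0-based half-open coordinates.  Only ``exon`` feature rows are consumed:
exon rows sharing a ``transcript_id`` are grouped into one transcript,
sorted by start, regardless of row order in the file.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

from .models import TranscriptModel

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    pass


def _parse_attributes(field: str, path: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(field))
    for required in ("gene_id", "transcript_id"):
        if required not in attrs:
            raise GtfParseError(f"{path}:{lineno}: missing required attribute {required!r}")
    return attrs


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read a GTF file into :class:`TranscriptModel` records.

    Raises :class:`GtfParseError` with the offending line number on
    malformed rows (missing attributes, end < start, unknown strand).
    """
    path = Path(path)
    # transcript_id -> (chrom, strand, gene_id, attrs, [(start, end), ...])
    pending: dict[str, tuple[str, str, str, dict[str, str], list[tuple[int, int]]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_field = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise GtfParseError(f"{path}:{lineno}: end < start")
            if strand not in {"+", "-"}:
                raise GtfParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = _parse_attributes(attr_field, str(path), lineno)
            tid = attrs["transcript_id"]
            interval = (start1 - 1, end1)  # to 0-based half-open
            if tid not in pending:
                pending[tid] = (chrom, strand, attrs["gene_id"], attrs, [interval])
                order.append(tid)
            else:
                chrom0, strand0, _g, _a, ivs = pending[tid]
                if (chrom0, strand0) != (chrom, strand):
                    raise GtfParseError(
                        f"{path}:{lineno}: transcript {tid} spans chromosomes or strands"
                    )
                ivs.append(interval)
    models = []
    for tid in order:
        chrom, strand, gene_id, attrs, ivs = pending[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(ivs)),
                source_assembler=attrs.get("assembler", ""),
                sample_id=attrs.get("sample", ""),
                coverage=float(attrs.get("cov", 0.0)),
                biotype=attrs.get("biotype", ""),
            )
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | Path, source: str = "thyrolnc") -> None:
    """Write transcript models as GTF exon rows (1-based inclusive)."""
    with open(path, "w") as fh:
        for m in models:
            extra = ""
            if m.sample_id:
                extra += f' sample "{m.sample_id}";'
            if m.source_assembler:
                extra += f' assembler "{m.source_assembler}";'
            if m.coverage:
                extra += f' cov "{m.coverage:g}";'
            if m.biotype:
                extra += f' biotype "{m.biotype}";'
            for start, end in m.exons:
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t{m.strand}\t.\t"
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";{extra}\n'
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` dict (upper-cased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def spliced_sequence(genome: Mapping[str, str], model: TranscriptModel) -> str:
    """Extract the spliced, sense-strand sequence of a transcript model."""
    from Bio.Seq import Seq

    chrom_seq = genome[model.chrom]
    seq = "".join(chrom_seq[s:e] for s, e in model.exons)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq
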