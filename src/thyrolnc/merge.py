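"""Pooling of per-(sample, assembler) transcript models and the
reliability rule.

Models emitted independently by two assemblers on several samples are
deduplicated by structure key (intron chain; exact exon interval for
single-exon models).  A pooled structure is considered *reliable* if it
was found in at least two samples or by both assemblers; everything else
is dropped as assembler noise.
"""
from __future__ import annotations

from typing import Iterable

import pandas as pd

from .models import SupportRecord, TranscriptModel, structure_key


def pool_models(models: Iterable[TranscriptModel]) -> list[SupportRecord]:
    """Deduplicate transcript models into one SupportRecord per structure.

    The representative model of a structure is the occurrence with the
    highest coverage (ties broken by lexicographically smallest
    transcript_id); the record's coverage is the maximum over all
    occurrences, and sample/assembler support sets are unions.
    """
    records: dict[str, SupportRecord] = {}
    for m in models:
        key = structure_key(m)
        rec = records.get(key)
        if rec is None:
            records[key] = SupportRecord(
                key=key,
                samples={m.sample_id} if m.sample_id else set(),
                assemblers={m.source_assembler} if m.source_assembler else set(),
                representative=m,
                coverage=m.coverage,
            )
        else:
            if m.sample_id:
                rec.samples.add(m.sample_id)
            if m.source_assembler:
                rec.assemblers.add(m.source_assembler)
            rec.coverage = max(rec.coverage, m.coverage)
            better = m.coverage > rec.representative.coverage or (
                m.coverage == rec.representative.coverage
                and m.transcript_id < rec.representative.transcript_id
            )
            if better:
                rec.representative = m
    return [records[k] for k in sorted(records)]


def apply_reliability_rule(
    records: Iterable[SupportRecord],
) -> tuple[list[SupportRecord], list[SupportRecord], dict[str, int]]:
    """Split pooled records into (retained, dropped, drop-reason counts).

    Retained iff found in >= 2 samples OR by both assemblers.
    """
    retained: list[SupportRecord] = []
    dropped: list[SupportRecord] = []
    for rec in records:
        if rec.is_reliable():
            retained.append(rec)
        else:
            dropped.append(rec)
    return retained, dropped, {"unreliable": len(dropped)}


def support_table(records: Iterable[SupportRecord]) -> pd.DataFrame:
    """Tabular view of pooled support, one row per structure."""
    rows = [
        {
            "key": r.key,
            "representative": r.representative.transcript_id,
            "samples": ",".join(sorted(r.samples)),
            "n_samples": len(r.samples),
            "assemblers": ",".join(sorted(r.assemblers)),
            "n_assemblers": len(r.assemblers),
            "coverage": r.coverage,
            "n_exons": r.representative.n_exons,
            "length": r.representative.length,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "key", "representative", "samples", "n_samples",
            "assemblers", "n_assemblers", "coverage", "n_exons", "length",
        ],
    )
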