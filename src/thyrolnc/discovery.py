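"""The lncRNA / novel-mRNA discovery cascade.

Reliable pooled transcripts are filtered in four stages:

1. coverage:  read coverage < 3 is eliminated (strict ``<``);
2. structure: single-exon transcripts and transcripts shorter than
   200 bp of exonic sequence are excluded (strict ``<``);
3. annotation: transcripts matching an annotated mRNA intron chain are
   set aside as known mRNAs; transcripts with same-strand exonic overlap
   against annotated pseudogene / pre-miRNA / tRNA / rRNA / snoRNA loci
   are removed;
4. coding consensus: survivors flagged coding by any of the four
   scorers become novel mRNAs, the rest are candidate lncRNAs.

Antisense overlap with an annotated mRNA does not remove a transcript:
antisense lncRNAs are a major class and stay in the candidate set.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Optional

import pandas as pd
from intervaltree import IntervalTree

from . import coding
from .gtf import spliced_sequence
from .models import (
    ClassifiedTranscript,
    CodingVerdict,
    SupportRecord,
    TranscriptModel,
    structure_key,
)

MIN_COVERAGE = 3.0
MIN_EXONS = 2
MIN_LENGTH = 200

REMOVED_BIOTYPES = frozenset({"pseudogene", "pre_miRNA", "tRNA", "rRNA", "snoRNA"})


def filter_coverage(
    records: Iterable[SupportRecord], min_coverage: float = MIN_COVERAGE
) -> tuple[list[SupportRecord], list[SupportRecord]]:
    """Partition records into (pass, drop) by read coverage.

    A record drops iff coverage < min_coverage; the boundary value passes.
    """
    passed, dropped = [], []
    for rec in records:
        if rec.coverage is None:
            raise ValueError(f"record {rec.key} has no coverage value")
        (dropped if rec.coverage < min_coverage else passed).append(rec)
    return passed, dropped


def filter_structure(
    records: Iterable[SupportRecord],
    min_exons: int = MIN_EXONS,
    min_length: int = MIN_LENGTH,
) -> tuple[list[SupportRecord], list[SupportRecord]]:
    """Drop single-exon and short transcripts (exonic length < min_length)."""
    passed, dropped = [], []
    for rec in records:
        m = rec.representative
        if m.n_exons < min_exons or m.length < min_length:
            dropped.append(rec)
        else:
            passed.append(rec)
    return passed, dropped


class AnnotationIndex:
    """Intron-chain and exon-overlap lookup over a reference annotation."""

    def __init__(self, annotation: Iterable[TranscriptModel]):
        self.mrna_chains: dict[str, str] = {}
        self.noncoding_trees: dict[tuple[str, str], IntervalTree] = {}
        seen_biotypes = set()
        for t in annotation:
            if not t.biotype:
                raise ValueError(
                    f"annotation record {t.transcript_id} lacks a biotype attribute"
                )
            seen_biotypes.add(t.biotype)
            if t.biotype == "mRNA":
                self.mrna_chains.setdefault(structure_key(t), t.transcript_id)
            elif t.biotype in REMOVED_BIOTYPES:
                tree = self.noncoding_trees.setdefault((t.chrom, t.strand), IntervalTree())
                for s, e in t.exons:
                    tree[s:e] = t.transcript_id
        self.biotypes = seen_biotypes

    def match_known_mrna(self, model: TranscriptModel) -> Optional[str]:
        return self.mrna_chains.get(structure_key(model))

    def overlaps_noncoding(self, model: TranscriptModel) -> Optional[str]:
        """Same-strand exonic overlap (>= 1 bp) with a removed biotype locus."""
        tree = self.noncoding_trees.get((model.chrom, model.strand))
        if tree is None:
            return None
        for s, e in model.exons:
            hits = tree[s:e]
            if hits:
                return sorted(iv.data for iv in hits)[0]
        return None


def remove_annotated(
    records: Iterable[SupportRecord], annotation: AnnotationIndex | Iterable[TranscriptModel]
) -> tuple[list[ClassifiedTranscript], list[ClassifiedTranscript], list[SupportRecord]]:
    """Split records into (known mRNAs, annotated-noncoding drops, survivors)."""
    if not isinstance(annotation, AnnotationIndex):
        annotation = AnnotationIndex(annotation)
    known: list[ClassifiedTranscript] = []
    removed: list[ClassifiedTranscript] = []
    survivors: list[SupportRecord] = []
    for rec in records:
        m = rec.representative
        mrna_id = annotation.match_known_mrna(m)
        if mrna_id is not None:
            known.append(
                ClassifiedTranscript(
                    key=rec.key, label="known_mRNA",
                    matched_annotation_id=mrna_id, representative=m,
                )
            )
            continue
        nc_id = annotation.overlaps_noncoding(m)
        if nc_id is not None:
            removed.append(
                ClassifiedTranscript(
                    key=rec.key, label="discarded",
                    discard_reason="annotated_noncoding_biotype",
                    matched_annotation_id=nc_id, representative=m,
                )
            )
            continue
        survivors.append(rec)
    return known, removed, survivors


def classify_survivors(
    survivors: Iterable[SupportRecord],
    verdicts: Mapping[str, CodingVerdict],
) -> tuple[list[ClassifiedTranscript], list[ClassifiedTranscript]]:
    """Consensus-coding survivors become novel mRNAs, the rest lncRNAs."""
    novel, lnc = [], []
    for rec in survivors:
        verdict = verdicts.get(rec.key)
        if verdict is None:
            raise ValueError(f"no coding verdict for survivor {rec.key}")
        ct = ClassifiedTranscript(
            key=rec.key,
            label="novel_mRNA" if verdict.consensus else "candidate_lncRNA",
            representative=rec.representative,
            verdict=verdict,
        )
        (novel if verdict.consensus else lnc).append(ct)
    return novel, lnc


def _verdict_from_external(row: Mapping[str, float]) -> CodingVerdict:
    """Build a verdict from externally supplied tool scores.

    Expected keys: ``cnci`` and ``cpc`` scores (coding iff >= 0),
    ``pfam`` E-value (coding iff < 1e-3), ``orf_codons`` (coding iff
    >= 100).  Missing tools default to non-coding evidence.
    """
    cnci = float(row.get("cnci", -1.0))
    cpc = float(row.get("cpc", -1.0))
    pfam = float(row.get("pfam", float("inf")))
    orf_codons = int(row.get("orf_codons", 0))
    return CodingVerdict(
        hexamer_score=cnci,
        hexamer_coding=cnci >= 0.0,
        orf_fraction_score=cpc,
        orf_fraction_coding=cpc >= 0.0,
        domain_evalue=pfam,
        domain_coding=pfam < coding.DOMAIN_EVALUE_THRESHOLD,
        longest_orf_codons=orf_codons,
        orf_coding=orf_codons >= coding.CODING_ORF_CODONS,
    )


def run_discovery(
    records: Iterable[SupportRecord],
    annotation: Iterable[TranscriptModel] | AnnotationIndex,
    genome: Mapping[str, str],
    min_coverage: float = MIN_COVERAGE,
    min_exons: int = MIN_EXONS,
    min_length: int = MIN_LENGTH,
    external_scores: Optional[pd.DataFrame] = None,
) -> tuple[list[ClassifiedTranscript], pd.DataFrame]:
    """Run the full cascade; returns classifications and stage counts.

    ``external_scores`` (columns: key, tool, value) bypasses the
    stand-in scorers for the structures it covers; tools are named
    cnci / cpc / pfam / orf_codons.
    """
    records = list(records)
    classified: list[ClassifiedTranscript] = []
    stage_counts = [("input", len(records))]

    cov_pass, cov_drop = filter_coverage(records, min_coverage)
    classified += [
        ClassifiedTranscript(key=r.key, label="discarded", discard_reason="low_coverage",
                             representative=r.representative)
        for r in cov_drop
    ]
    stage_counts.append(("coverage", len(cov_pass)))

    struct_pass, struct_drop = filter_structure(cov_pass, min_exons, min_length)
    for r in struct_drop:
        reason = "single_exon" if r.representative.n_exons < min_exons else "too_short"
        classified.append(
            ClassifiedTranscript(key=r.key, label="discarded", discard_reason=reason,
                                 representative=r.representative)
        )
    stage_counts.append(("structure", len(struct_pass)))

    known, removed, survivors = remove_annotated(struct_pass, annotation)
    classified += known + removed
    stage_counts.append(("annotation", len(survivors)))

    external: dict[str, dict[str, float]] = {}
    if external_scores is not None:
        for _, row in external_scores.iterrows():
            external.setdefault(str(row["key"]), {})[str(row["tool"])] = float(row["value"])

    verdicts: dict[str, CodingVerdict] = {}
    for rec in survivors:
        if rec.key in external:
            verdicts[rec.key] = _verdict_from_external(external[rec.key])
        else:
            seq = spliced_sequence(genome, rec.representative)
            verdicts[rec.key] = coding.score_coding(seq)
    novel, lnc = classify_survivors(survivors, verdicts)
    classified += novel + lnc
    stage_counts.append(("candidate_lncRNA", len(lnc)))

    counts = pd.DataFrame(stage_counts, columns=["stage", "survivors"])
    return classified, counts


def classification_table(classified: Iterable[ClassifiedTranscript]) -> pd.DataFrame:
    rows = [
        {
            "key": c.key,
            "label": c.label,
            "discard_reason": c.discard_reason,
            "matched_annotation_id": c.matched_annotation_id or "",
            "representative": c.representative.transcript_id if c.representative else "",
            "gene_id": c.representative.gene_id if c.representative else "",
        }
        for c in classified
    ]
    return pd.DataFrame(
        rows,
        columns=["key", "label", "discard_reason", "matched_annotation_id",
                 "representative", "gene_id"],
    )
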