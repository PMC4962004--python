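"""Homology classification of candidate lncRNAs against reference sets.

Queries are aligned with exact local (Smith-Waterman) alignment under a
fixed DNA scheme -- match +1, mismatch -2, gap open -5 (first gapped
position), gap extension -2 -- and hits are assessed with a
Karlin-Altschul E-value

    E = K * m * n * exp(-lambda * S)

using fixed calibration constants shipped as named configuration values.
A candidate is similar to a reference set iff its best hit has
E < 1e-6.  An optional k-mer prefilter (k = 11, blastn's default word
size) skips pairs sharing too few exact words; at the default threshold
it cannot change flags, because alignments reaching the E-value cutoff
under this scheme require long exact or near-exact stretches.
"""
from __future__ import annotations

import math
from typing import Iterable, Mapping

import pandas as pd

from .models import AlignmentHit

MATCH = 1
MISMATCH = -2
GAP_OPEN = -5
GAP_EXTEND = -2

#: Karlin-Altschul calibration constants for the scoring scheme above.
KA_K = 0.711
KA_LAMBDA = 1.37

E_THRESHOLD = 1e-6
WORD_SIZE = 11


def _aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = None


def local_align(query: str, subject: str) -> int:
    """Optimal local-alignment score of two DNA sequences.

    Empty sequences score 0; the score is symmetric in its arguments.
    """
    if not query or not subject:
        return 0
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = _aligner()
    return int(_ALIGNER.score(query.upper(), subject.upper()))


def evalue(score: float, m: int, n: int, k: float = KA_K, lam: float = KA_LAMBDA) -> float:
    """Karlin-Altschul expected number of chance hits of this score."""
    if m <= 0 or n <= 0:
        return math.inf
    return k * m * n * math.exp(-lam * score)


def _kmers(seq: str, k: int = WORD_SIZE) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shared_kmer_counts(
    queries: Mapping[str, str], subjects: Mapping[str, str], k: int = WORD_SIZE
) -> dict[tuple[str, str], int]:
    """Number of distinct shared k-words for every query/subject pair
    that shares at least one, via an inverted word index."""
    index: dict[str, list[str]] = {}
    for sid, seq in subjects.items():
        for w in _kmers(seq.upper(), k):
            index.setdefault(w, []).append(sid)
    counts: dict[tuple[str, str], int] = {}
    for qid, seq in queries.items():
        for w in _kmers(seq.upper(), k):
            for sid in index.get(w, ()):
                key = (qid, sid)
                counts[key] = counts.get(key, 0) + 1
    return counts


def best_hits(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    min_shared_kmers: int | None = None,
) -> dict[str, AlignmentHit]:
    """Best-scoring subject hit per query (smallest E-value).

    With ``min_shared_kmers`` set, only pairs sharing at least that many
    exact 11-words are aligned; other pairs are treated as scoreless.
    """
    pairs: Iterable[tuple[str, str]]
    if min_shared_kmers is not None:
        counts = shared_kmer_counts(queries, subjects)
        pairs = [pair for pair, c in counts.items() if c >= min_shared_kmers]
    else:
        pairs = [(q, s) for q in queries for s in subjects]
    best: dict[str, AlignmentHit] = {}
    for qid, sid in pairs:
        score = local_align(queries[qid], subjects[sid])
        e = evalue(score, len(queries[qid]), len(subjects[sid]))
        prev = best.get(qid)
        if prev is None or e < prev.evalue or (e == prev.evalue and sid < prev.subject_id):
            best[qid] = AlignmentHit(query_id=qid, subject_id=sid, score=score, evalue=e)
    return best


def classify_homology(
    candidates: Mapping[str, str],
    databases: Mapping[str, Mapping[str, str]],
    e_threshold: float = E_THRESHOLD,
    min_shared_kmers: int | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Flag candidates similar to each reference set at E < threshold.

    Returns a per-candidate flag table (one boolean column per database
    plus ``both`` when exactly two databases are given) and a percentage
    summary (flagged / total candidates * 100, one decimal).
    """
    if not databases or any(not db for db in databases.values()):
        raise ValueError("all reference databases must be non-empty")
    flags = pd.DataFrame(index=sorted(candidates), dtype=bool)
    hits_by_db: dict[str, dict[str, AlignmentHit]] = {}
    for name, db in databases.items():
        hits = best_hits(candidates, db, min_shared_kmers=min_shared_kmers)
        hits_by_db[name] = hits
        flags[name] = [
            (qid in hits and hits[qid].evalue < e_threshold) for qid in flags.index
        ]
    db_names = list(databases)
    if len(db_names) == 2:
        flags["both"] = flags[db_names[0]] & flags[db_names[1]]
    total = len(flags)
    summary = {
        col: percentage(int(flags[col].sum()), total) for col in flags.columns
    }
    return flags, summary


def percentage(numerator: int, denominator: int) -> float:
    """Share of a candidate set as a percentage, one decimal place."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, 1)


def hits_table(hits: Mapping[str, AlignmentHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"query": h.query_id, "subject": h.subject_id, "score": h.score,
             "evalue": h.evalue}
            for h in hits.values()
        ],
        columns=["query", "subject", "score", "evalue"],
    )
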