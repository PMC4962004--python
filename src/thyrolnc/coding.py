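"""Coding-potential scorers and their consensus.

Four scorers mirror the thresholds of the tools commonly combined in
lncRNA discovery pipelines, each exposed with the decision boundary of
its archetype:

* ``hexamer`` (CNCI-like): mean in-frame hexamer log-likelihood ratio of
  the longest ORF against a coding vs noncoding background; coding iff
  score >= 0.
* ``orf_fraction`` (CPC-like): fraction of the transcript covered by the
  longest ORF, centered so 0 is the decision point; coding iff >= 0.
* ``domain`` (Pfam-scan-like): best E-value of translated-ORF matches
  against a bundled toy domain library; coding iff E < 1e-3.
* ``orf`` (PhyloCSF-like stand-in): coding iff a sufficiently long ORF
  (>= 100 codons by default) exists.

The consensus is the OR of the four flags: any positive scorer marks the
transcript as coding.  External tool outputs can be supplied through the
discovery stage to bypass these stand-ins.
"""
from __future__ import annotations

import itertools
import math

import numpy as np

from .models import CodingVerdict
from .orf import find_orfs, longest_orf, orf_sequence

VALID_SYMBOLS = frozenset("ACGTN")

#: Minimum ORF length (codons) for the PhyloCSF-like scorer to call coding.
CODING_ORF_CODONS = 100

#: E-value threshold for the domain scanner.
DOMAIN_EVALUE_THRESHOLD = 1e-3

#: ORFs shorter than this contribute no hexamer/domain evidence.
MIN_SCORABLE_ORF_CODONS = 10

#: Toy protein domain library used by the domain scanner.  Real Pfam
#: domain hits can be supplied as an external score table instead.
DOMAIN_LIBRARY: dict[str, str] = {
    "TOYDOM1": "WKDHPLNRVGYC",
    "TOYDOM2": "FQESTAILKWPR",
    "TOYDOM3": "HHCYDRNKWLSG",
}

_BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(_BASES, repeat=3) if "".join(c) not in STOPS
)

# Fixed pseudo-random codon usage weights acting as the coding background
# calibration table.  The constant seed makes the table a reproducible
# package constant, not a tunable.
_TABLE_SEED = 20160709


def _codon_weights() -> dict[str, float]:
    rng = np.random.default_rng(_TABLE_SEED)
    raw = rng.gamma(1.0, size=len(SENSE_CODONS))
    raw /= raw.sum()
    return dict(zip(SENSE_CODONS, raw))

CODON_WEIGHTS: dict[str, float] = _codon_weights()

_LOG_UNIFORM_HEXAMER = -6.0 * math.log(4.0)


def validate_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_SYMBOLS
    if bad:
        raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
    return seq


def hexamer_score(seq: str) -> float:
    """Mean in-frame hexamer log-ratio (coding vs uniform) of the longest ORF.

    Hexamers are taken at codon boundaries inside the longest six-frame
    ORF (stop excluded).  Sequences without a scorable ORF get -1.0.
    """
    orf = longest_orf(seq)
    if orf is None or orf.codons < MIN_SCORABLE_ORF_CODONS:
        return -1.0
    cds = orf_sequence(seq, orf)
    ratios = []
    for i in range(0, len(cds) - 5, 3):
        c1, c2 = cds[i : i + 3], cds[i + 3 : i + 6]
        w1, w2 = CODON_WEIGHTS.get(c1), CODON_WEIGHTS.get(c2)
        if w1 is None or w2 is None:  # ambiguous bases
            continue
        ratios.append(math.log(w1) + math.log(w2) - _LOG_UNIFORM_HEXAMER)
    if not ratios:
        return -1.0
    return float(np.mean(ratios))


def orf_fraction_score(seq: str) -> float:
    """Longest-ORF fraction of transcript length, centered at 0.5."""
    if not seq:
        return -0.5
    orf = longest_orf(seq)
    frac = 0.0 if orf is None else orf.nt_length / len(seq)
    return frac - 0.5


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds).translate())


def domain_scan_evalue(seq: str) -> float:
    """Best E-value of toy-domain matches in all translated ORFs.

    For an exact peptide match of length L the E-value is the classical
    word-search expectation  E = (translated residues) x (library
    residues) x 20^-L ; no match yields +inf.
    """
    orfs = [o for o in find_orfs(seq) if o.codons >= MIN_SCORABLE_ORF_CODONS]
    if not orfs:
        return math.inf
    proteins = [_translate(orf_sequence(seq, o)) for o in orfs]
    n_res = sum(len(p) for p in proteins)
    d_res = sum(len(d) for d in DOMAIN_LIBRARY.values())
    best = math.inf
    for pep in DOMAIN_LIBRARY.values():
        if any(pep in prot for prot in proteins):
            e = n_res * d_res * 20.0 ** (-len(pep))
            best = min(best, e)
    return best


def score_coding(
    seq: str,
    min_orf_codons: int = CODING_ORF_CODONS,
    domain_threshold: float = DOMAIN_EVALUE_THRESHOLD,
) -> CodingVerdict:
    """Run all four stand-in scorers on a spliced sense-strand sequence."""
    seq = validate_sequence(seq)
    hx = hexamer_score(seq)
    of = orf_fraction_score(seq)
    ev = domain_scan_evalue(seq)
    orf = longest_orf(seq)
    codons = 0 if orf is None else orf.codons
    return CodingVerdict(
        hexamer_score=hx,
        hexamer_coding=hx >= 0.0,
        orf_fraction_score=of,
        orf_fraction_coding=of >= 0.0,
        domain_evalue=ev,
        domain_coding=ev < domain_threshold,
        longest_orf_codons=codons,
        orf_coding=codons >= min_orf_codons,
    )
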