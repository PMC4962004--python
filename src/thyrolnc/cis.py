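"""Cis target prediction for differentially expressed lncRNAs.

A DE mRNA gene is a candidate cis target of a DE lncRNA gene if the two
gene bodies lie on the same chromosome within a fixed window (default
100 kb, boundary inclusive) of each other.  Distance is the gap between
the gene-body intervals (0 when they overlap), strand-agnostic; pairing
is done at gene level on the union of transcript intervals per gene.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .models import CisPair

WINDOW = 100_000


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chrom: str
    start: int
    end: int


def gene_loci(models) -> list[GeneLocus]:
    """Union gene-body interval per gene id from transcript models."""
    agg: dict[str, list] = {}
    for m in models:
        rec = agg.get(m.gene_id)
        if rec is None:
            agg[m.gene_id] = [m.chrom, m.start, m.end]
        else:
            if rec[0] != m.chrom:
                raise ValueError(f"gene {m.gene_id} spans chromosomes")
            rec[1] = min(rec[1], m.start)
            rec[2] = max(rec[2], m.end)
    return [GeneLocus(g, c, s, e) for g, (c, s, e) in sorted(agg.items())]


def signed_distance(lnc: GeneLocus, mrna: GeneLocus) -> int | None:
    """Signed gene-body gap: 0 if overlapping, positive when the mRNA
    lies downstream (rightward, plus-strand convention) of the lncRNA."""
    if lnc.chrom != mrna.chrom:
        return None
    if mrna.start >= lnc.end:
        return mrna.start - lnc.end
    if lnc.start >= mrna.end:
        return -(lnc.start - mrna.end)
    return 0


def find_neighbors(
    lnc: GeneLocus, mrna_loci: Iterable[GeneLocus], window: int = WINDOW
) -> list[tuple[GeneLocus, int]]:
    """mRNA loci within ``window`` bases of the lncRNA gene body
    (inclusive boundary), with signed distances."""
    out = []
    for m in mrna_loci:
        d = signed_distance(lnc, m)
        if d is not None and abs(d) <= window:
            out.append((m, d))
    return out


def classify_direction(lnc_direction: str, mrna_direction: str) -> str:
    """Join two DE directions into a pair class such as 'up-down'."""
    for d in (lnc_direction, mrna_direction):
        if d not in {"up", "down"}:
            raise ValueError(f"direction must be 'up' or 'down', got {d!r}")
    return f"{lnc_direction}-{mrna_direction}"


def predict_pairs(
    de_lnc_loci: Iterable[GeneLocus],
    de_mrna_loci: Iterable[GeneLocus],
    lnc_directions: Mapping[str, str],
    mrna_directions: Mapping[str, str],
    window: int = WINDOW,
) -> tuple[list[CisPair], dict[str, int]]:
    """All DE lncRNA x DE mRNA pairs within the window, plus a summary.

    The summary reports the pair total, the same/opposite-direction
    split and per-lncRNA target multiplicity; total = same + opposite.
    """
    de_mrna_loci = list(de_mrna_loci)
    pairs: list[CisPair] = []
    multiplicity: dict[str, int] = {}
    for lnc in de_lnc_loci:
        for mrna, dist in find_neighbors(lnc, de_mrna_loci, window):
            cls = classify_direction(
                lnc_directions[lnc.gene_id], mrna_directions[mrna.gene_id]
            )
            position = (
                "overlapping" if dist == 0 else ("downstream" if dist > 0 else "upstream")
            )
            pairs.append(
                CisPair(
                    lnc_gene_id=lnc.gene_id,
                    mrna_gene_id=mrna.gene_id,
                    distance=dist,
                    relative_position=position,
                    direction_class=cls,
                )
            )
            multiplicity[lnc.gene_id] = multiplicity.get(lnc.gene_id, 0) + 1
    same = sum(1 for p in pairs if p.same_direction)
    by_class: dict[str, int] = {}
    for p in pairs:
        by_class[p.direction_class] = by_class.get(p.direction_class, 0) + 1
    summary = {
        "n_pairs": len(pairs),
        "same_direction": same,
        "opposite_direction": len(pairs) - same,
        "n_lnc_genes_with_targets": len(multiplicity),
        **{f"class:{k}": v for k, v in sorted(by_class.items())},
    }
    return pairs, summary


def pairs_table(pairs: Iterable[CisPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_gene_id": p.lnc_gene_id,
                "mrna_gene_id": p.mrna_gene_id,
                "distance": p.distance,
                "relative_position": p.relative_position,
                "direction_class": p.direction_class,
            }
            for p in pairs
        ],
        columns=["lnc_gene_id", "mrna_gene_id", "distance",
                 "relative_position", "direction_class"],
    )
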