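"""FPKM quantification and expression-set derivation.

FPKM (fragments per kilobase of exon per million mapped fragments):

    FPKM[t, s] = count[t, s] * 1e9 / (L[t] * N[s])

with L the exonic length of transcript t in bases and N the number of
mapped fragments of sample s (supplied per sample; genome-wide mapped
fragments, not the column sum of the table).
"""
from __future__ import annotations

from typing import Mapping

import pandas as pd

HIGH_EXPRESSION_FPKM = 1000.0


def compute_fpkm(
    counts: pd.DataFrame, lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """FPKM matrix from fragment counts, exonic lengths and library sizes."""
    lengths = lengths.reindex(counts.index)
    library_sizes = library_sizes.reindex(counts.columns)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:3]
        raise ValueError(f"missing exonic length for transcripts {missing}")
    if library_sizes.isna().any():
        raise ValueError("missing library size for some samples")
    if (lengths <= 0).any():
        raise ValueError("exonic lengths must be positive")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)


def _breed_samples(breed_map: Mapping[str, str], samples) -> dict[str, list[str]]:
    by_breed: dict[str, list[str]] = {}
    for s in samples:
        if s not in breed_map:
            raise ValueError(f"sample {s!r} not assigned to a breed")
        by_breed.setdefault(breed_map[s], []).append(s)
    return by_breed


def expression_sets(
    fpkm: pd.DataFrame,
    breed_map: Mapping[str, str],
    expressed_threshold: float = 0.0,
    high_threshold: float = HIGH_EXPRESSION_FPKM,
) -> dict[str, set[str]]:
    """Derive expressed / shared / breed-specific / high-expression sets.

    A transcript is expressed in a breed iff FPKM > expressed_threshold
    in at least one sample of that breed; breed-specific means expressed
    in exactly one breed.  High expression means mean FPKM above
    ``high_threshold`` in at least one breed.  The returned dict maps
    ``expressed`` / ``shared`` / ``specific:<breed>`` / ``high`` to id sets,
    and satisfies |expressed| = |shared| + sum of |specific:*|.
    """
    by_breed = _breed_samples(breed_map, fpkm.columns)
    if len(by_breed) != 2:
        raise ValueError(f"expected exactly two breeds, got {sorted(by_breed)}")
    expressed_in = {
        breed: set(fpkm.index[(fpkm[cols] > expressed_threshold).any(axis=1)])
        for breed, cols in by_breed.items()
    }
    breeds = sorted(by_breed)
    shared = expressed_in[breeds[0]] & expressed_in[breeds[1]]
    sets: dict[str, set[str]] = {
        "expressed": expressed_in[breeds[0]] | expressed_in[breeds[1]],
        "shared": shared,
    }
    for b in breeds:
        other = breeds[1] if b == breeds[0] else breeds[0]
        sets[f"specific:{b}"] = expressed_in[b] - expressed_in[other]
    high: set[str] = set()
    for b, cols in by_breed.items():
        mean = fpkm[cols].mean(axis=1)
        high |= set(mean.index[mean > high_threshold])
    sets["high"] = high
    return sets


def expression_share(fpkm: pd.DataFrame, breed_map: Mapping[str, str]) -> pd.DataFrame:
    """Per-breed share of total expression for every transcript.

    share[t, breed] = mean FPKM of t over the breed's samples divided by
    the sum of mean FPKM over all transcripts; columns sum to 1.
    """
    by_breed = _breed_samples(breed_map, fpkm.columns)
    out = {}
    for breed, cols in sorted(by_breed.items()):
        mean = fpkm[cols].mean(axis=1)
        total = mean.sum()
        if total <= 0:
            raise ValueError(f"breed {breed!r} has zero total expression")
        out[breed] = mean / total
    return pd.DataFrame(out)
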