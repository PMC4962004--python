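"""Term enrichment of DE gene sets with BH correction.

The default test is the upper-tail hypergeometric: for a term with K
universe genes of which k are differentially expressed, out of n DE
genes in an N-gene universe, p = P(X >= k) with X ~ Hypergeom(N, K, n).
A term is enriched iff its BH-adjusted p is below 0.05 (strict).

An optional length-bias mode reweights the null in the spirit of
GOseq: a monotone selection-probability curve is fit to DE status as a
function of gene length by isotonic regression, and each term is tested
against a Wallenius noncentral hypergeometric null whose odds equal the
mean weight inside the term over the mean weight outside.  Uniform
weights recover the plain hypergeometric exactly.
"""
from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, nchypergeom_wallenius

from .de import bh_adjust

ADJ_P_THRESHOLD = 0.05


def length_bias_weights(gene_lengths: pd.Series, de_flags: pd.Series) -> pd.Series:
    """Monotone per-gene selection weights from a length-bias fit.

    Isotonic regression of DE status on gene length yields a
    non-decreasing DE-probability curve; weights are that curve
    normalised to mean 1 (so no bias gives uniform weights).  Weights
    are invariant to rescaling all lengths by a constant.
    """
    from sklearn.isotonic import IsotonicRegression

    lengths = gene_lengths.astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    flags = de_flags.reindex(lengths.index).astype(float)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(lengths.to_numpy(), flags.to_numpy())
    fitted = np.maximum(fitted, 1e-9)
    weights = fitted / fitted.mean()
    return pd.Series(weights, index=lengths.index, name="weight")


def enrich_terms(
    de_genes: Iterable[str],
    universe: Iterable[str],
    term_map: pd.DataFrame,
    adj_p_threshold: float = ADJ_P_THRESHOLD,
    weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Enrichment table over all terms with at least one universe gene.

    ``term_map`` has columns ``gene`` and ``term``.  With ``weights``
    given (from :func:`length_bias_weights`), the Wallenius noncentral
    null is used instead of the central hypergeometric.
    """
    universe = set(universe)
    de = set(de_genes)
    stray = de - universe
    if stray:
        raise ValueError(f"DE genes outside the universe: {sorted(stray)[:3]}")
    tm = term_map[term_map["gene"].isin(universe)]
    n_univ = len(universe)
    n_de = len(de)
    rows = []
    for term, genes in tm.groupby("term")["gene"]:
        members = set(genes)
        big_k = len(members)
        k = len(members & de)
        if weights is None:
            p = float(hypergeom.sf(k - 1, n_univ, big_k, n_de))
        else:
            w_in = float(weights.reindex(list(members)).mean())
            outside = universe - members
            w_out = float(weights.reindex(list(outside)).mean()) if outside else w_in
            odds = w_in / w_out if w_out > 0 else 1.0
            if abs(odds - 1.0) < 1e-12:
                p = float(hypergeom.sf(k - 1, n_univ, big_k, n_de))
            else:
                p = float(
                    nchypergeom_wallenius.sf(k - 1, n_univ, big_k, n_de, odds)
                )
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append({"term": term, "k": k, "K": big_k, "n": n_de, "N": n_univ, "p": p})
    result = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if result.empty:
        result["p_adj"] = []
        result["enriched"] = []
        return result
    result["p_adj"] = bh_adjust(result["p"].to_numpy())
    result["enriched"] = result["p_adj"] < adj_p_threshold
    return result.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
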