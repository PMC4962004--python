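"""Two-group negative-binomial differential expression.

The test is an exact conditional NB test in the classic edgeR style:
size-factor-normalised per-group totals are compared under the
equal-mean null by conditioning on their sum, which turns the NB pair
into a (negative-)hypergeometric-type distribution that does not depend
on the unknown mean.  With dispersion 0 the conditional law reduces to
the exact binomial split test.  Dispersions are method-of-moments
estimates shrunk 50/50 toward a mean-trended common value, which is
essential at two samples per group.  Multiple testing is controlled by
Benjamini-Hochberg; calls use a strict q < threshold rule.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

DEFAULT_Q = 0.05


# ---------------------------------------------------------------------------
# Benjamini-Hochberg (single source of truth; the enrichment module uses it)

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.  Input p-values
    must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Normalisation and dispersion

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (rows with any zero are excluded)."""
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        return pd.Series(1.0, index=counts.columns)
    log_geo = np.log(positive).mean(axis=1)
    sf = np.exp(np.log(positive).sub(log_geo, axis=0).median(axis=0))
    return sf


def _group_columns(groups: Mapping[str, str], samples) -> tuple[str, str, list[str], list[str]]:
    by_group: dict[str, list[str]] = {}
    for s in samples:
        if s not in groups:
            raise ValueError(f"sample {s!r} has no group assignment")
        by_group.setdefault(groups[s], []).append(s)
    if len(by_group) != 2:
        raise ValueError(f"expected exactly two groups, got {sorted(by_group)}")
    g1, g2 = sorted(by_group)
    return g1, g2, by_group[g1], by_group[g2]


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    shrink: bool = True,
    trend_bins: int = 10,
) -> pd.Series:
    """Per-transcript NB dispersion (alpha in Var = mu + alpha * mu^2).

    Within-group method-of-moments estimates on size-factor-normalised
    counts are pooled across the two groups, floored at 0 and (by
    default) shrunk 50/50 toward a mean-trended common value obtained
    from binned medians.
    """
    g1, g2, cols1, cols2 = _group_columns(groups, counts.columns)
    for name, cols in ((g1, cols1), (g2, cols2)):
        if len(cols) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    sf = size_factors(counts)
    z = counts.div(sf, axis=1)

    raw = np.zeros(len(counts))
    for cols in (cols1, cols2):
        m = z[cols].mean(axis=1).to_numpy()
        v = z[cols].var(axis=1, ddof=1).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        raw += np.maximum(a, 0.0) * (len(cols) - 1)
    raw /= (len(cols1) - 1) + (len(cols2) - 1)

    if not shrink or len(counts) == 1:
        return pd.Series(raw, index=counts.index, name="dispersion")

    # The per-transcript MoM estimate is hugely skewed at tiny n; its
    # bin-wise mean is close to unbiased while the median is biased low,
    # so the trend uses means.
    mean_expr = z.mean(axis=1).to_numpy()
    logm = np.log10(mean_expr + 1.0)
    n_bins = min(trend_bins, max(1, len(counts) // 20)) or 1
    edges = np.quantile(logm, np.linspace(0, 1, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(edges, logm, side="right") - 1, 0, n_bins - 1)
    trend = np.empty_like(raw)
    overall = float(np.mean(raw))
    for b in range(n_bins):
        mask = bin_idx == b
        trend[mask] = np.mean(raw[mask]) if mask.any() else overall
    shrunk = 0.5 * raw + 0.5 * trend
    return pd.Series(np.maximum(shrunk, 0.0), index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# Exact conditional test

def _conditional_log_pmf(s: int, r1: float, r2: float) -> np.ndarray:
    """Log pmf of the group-1 total conditional on the overall total s.

    P(S1 = k | S1 + S2 = s) for S_g ~ NB(size r_g, common p); the
    nuisance mean cancels, leaving a negative hypergeometric law.
    """
    k = np.arange(s + 1)
    logw = (
        gammaln(k + r1) - gammaln(k + 1.0)
        + gammaln(s - k + r2) - gammaln(s - k + 1.0)
    )
    return logw - logsumexp(logw)


def nb_test(
    counts_g1,
    counts_g2,
    size_factors_g1=None,
    size_factors_g2=None,
    dispersion: float = 0.0,
) -> float:
    """Exact conditional two-sided NB test for one transcript.

    Counts are divided by their size factors and the group totals
    rounded to integers; the two-sided p-value sums all conditional
    outcomes no more probable than the observed split.  An all-zero
    transcript returns p = 1 by convention.
    """
    c1 = np.asarray(counts_g1, dtype=float)
    c2 = np.asarray(counts_g2, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    sf1 = np.ones_like(c1) if size_factors_g1 is None else np.asarray(size_factors_g1, float)
    sf2 = np.ones_like(c2) if size_factors_g2 is None else np.asarray(size_factors_g2, float)
    s1 = int(round(float(np.sum(c1 / sf1))))
    s2 = int(round(float(np.sum(c2 / sf2))))
    s = s1 + s2
    if s == 0:
        return 1.0
    n1, n2 = len(c1), len(c2)
    if dispersion == 0.0:
        # Poisson limit: conditional law is Binomial(s, n1 / (n1 + n2))
        logp = binom.logpmf(np.arange(s + 1), s, n1 / (n1 + n2))
    else:
        logp = _conditional_log_pmf(s, n1 / dispersion, n2 / dispersion)
    obs = logp[s1]
    p = float(np.exp(logsumexp(logp[logp <= obs + 1e-10])))
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Driver

def run_de(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    q_threshold: float = DEFAULT_Q,
    dispersion: pd.Series | float | None = None,
) -> pd.DataFrame:
    """Differential expression over a counts table (transcripts x samples).

    Returns a DataFrame with normalised group means, log2 fold change
    (second group over first, pseudocount 1 for display only), the
    dispersion used, p, q and the direction call.
    """
    g1, g2, cols1, cols2 = _group_columns(groups, counts.columns)
    sf = size_factors(counts)
    if dispersion is None:
        disp = estimate_dispersion(counts, groups)
    elif np.isscalar(dispersion):
        disp = pd.Series(float(dispersion), index=counts.index)
    else:
        disp = pd.Series(dispersion).reindex(counts.index)
        if disp.isna().any():
            raise ValueError("dispersion series does not cover all transcripts")

    z = counts.div(sf, axis=1)
    mean1 = z[cols1].mean(axis=1)
    mean2 = z[cols2].mean(axis=1)
    log2fc = np.log2((mean2 + 1.0) / (mean1 + 1.0))

    sf1 = sf[cols1].to_numpy()
    sf2 = sf[cols2].to_numpy()
    pvals = np.array(
        [
            nb_test(counts.loc[t, cols1].to_numpy(), counts.loc[t, cols2].to_numpy(),
                    sf1, sf2, float(disp.loc[t]))
            for t in counts.index
        ]
    )
    qvals = bh_adjust(pvals)
    direction = np.where(
        qvals < q_threshold, np.where(log2fc > 0, "up", "down"), "ns"
    )
    return pd.DataFrame(
        {
            f"mean_{g1}": mean1,
            f"mean_{g2}": mean2,
            "log2fc": log2fc,
            "dispersion": disp,
            "p": pvals,
            "q": qvals,
            "direction": direction,
        },
        index=counts.index,
    )


def call_de(results: pd.DataFrame, q_threshold: float = DEFAULT_Q) -> dict[str, int]:
    """Summary counts of a DE result table (strict q < threshold)."""
    sig = results["q"] < q_threshold
    up = int((sig & (results["log2fc"] > 0)).sum())
    down = int((sig & (results["log2fc"] <= 0)).sum())
    return {
        "tested": int(len(results)),
        "up": up,
        "down": down,
        "total": up + down,
        "ns": int(len(results)) - up - down,
    }


def aggregate_to_genes(counts: pd.DataFrame, tx2gene: Mapping[str, str]) -> pd.DataFrame:
    """Sum transcript counts to gene level (for gene-granularity calls)."""
    gene_ids = [tx2gene.get(t) for t in counts.index]
    if any(g is None for g in gene_ids):
        missing = [t for t, g in zip(counts.index, gene_ids) if g is None][:3]
        raise ValueError(f"transcripts without gene assignment: {missing}")
    return counts.groupby(pd.Index(gene_ids, name="gene_id")).sum()
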