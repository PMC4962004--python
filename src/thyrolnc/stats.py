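"""Phenotype and qPCR validation statistics.

Covers the small-sample statistics used around the sequencing study:
the thyroid weight index, two-sample Student's t-tests computed from
group summaries (mean, SEM, n), and delta-delta-Ct relative expression
for qPCR validation.
"""
from __future__ import annotations

import math

from scipy.stats import t as t_dist

from .models import GroupSummary


def thyroid_index(thyroid_weight_g: float, body_weight_kg: float) -> float:
    """Thyroid weight index: gland weight over body weight (g/kg)."""
    if thyroid_weight_g <= 0 or body_weight_kg <= 0:
        raise ValueError("weights must be positive")
    return thyroid_weight_g / body_weight_kg


def ttest_summary(g1: GroupSummary, g2: GroupSummary) -> dict[str, float]:
    """Two-sample Student's t-test from summary data.

    t = (m2 - m1) / sqrt(SEM1^2 + SEM2^2), using the identity
    SEM = s / sqrt(n) so raw data are not needed; df = n1 + n2 - 2
    (pooled Student form).  Returns t, df and the two-sided p.
    """
    t = (g2.mean - g1.mean) / math.sqrt(g1.sem**2 + g2.sem**2)
    df = g1.n + g2.n - 2
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return {"t": t, "df": df, "p": min(p, 1.0)}


def ddct(
    ct_target_test: float,
    ct_reference_test: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> dict[str, float]:
    """Delta-delta-Ct relative quantification.

    ddCt = (Ct_tgt - Ct_ref)_test - (Ct_tgt - Ct_ref)_calibrator and the
    fold change is 2^(-ddCt) against the calibrator condition.
    """
    for v in (ct_target_test, ct_reference_test, ct_target_calibrator, ct_reference_calibrator):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    delta_test = ct_target_test - ct_reference_test
    delta_cal = ct_target_calibrator - ct_reference_calibrator
    ddct_value = delta_test - delta_cal
    return {"ddct": ddct_value, "fold_change": 2.0 ** (-ddct_value)}
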