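"""Negative-binomial exact test, dispersion estimation and BH adjustment."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from oracles import bh_oracle, binom_two_sided_oracle

from thyrolnc.de import (
    aggregate_to_genes,
    bh_adjust,
    call_de,
    estimate_dispersion,
    nb_test,
    run_de,
    size_factors,
)

GROUPS = {"s1": "g1", "s2": "g1", "s3": "g2", "s4": "g2"}


class TestBH:
    def test_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_rejected(self):
        for bad in ([0.0], [1.2], [-0.1], [np.nan]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_stepup_definition(self, ps):
        assert np.allclose(bh_adjust(ps), bh_oracle(ps))

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=2,
                    max_size=30))
    def test_order_preserving(self, ps):
        q = bh_adjust(ps)
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestNbTest:
    def test_identical_groups_give_p_one(self):
        assert nb_test([5, 5], [5, 5], dispersion=0.1) == 1.0

    def test_all_zero_convention(self):
        assert nb_test([0, 0], [0, 0], dispersion=0.1) == 1.0

    def test_poisson_limit_equals_exact_binomial(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            c1 = rng.integers(0, 40, size=2)
            c2 = rng.integers(0, 40, size=2)
            p = nb_test(c1, c2, dispersion=0.0)
            oracle = binom_two_sided_oracle(int(c1.sum()), int(c2.sum()), 2, 2)
            assert p == pytest.approx(oracle, rel=1e-9)

    def test_label_exchange_symmetry(self):
        p1 = nb_test([3, 9], [25, 31], dispersion=0.05)
        p2 = nb_test([25, 31], [3, 9], dispersion=0.05)
        assert p1 == pytest.approx(p2)

    def test_p_monotone_in_mean_difference(self):
        base = np.array([50, 50])
        ps = [
            nb_test(base, base + delta, dispersion=0.05)
            for delta in (0, 20, 60, 150)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_test([1], [2], dispersion=-0.1)

    def test_type_one_error_calibrated_under_null(self):
        # 2 vs 2 NB null with alpha = 0.1: rejection rate within 3 MC SE
        rng = np.random.default_rng(11)
        alpha, mu, n_sim = 0.1, 100, 2000
        size = 1.0 / alpha
        rejections = 0
        for _ in range(n_sim):
            c = rng.negative_binomial(size, size / (size + mu), size=4)
            if nb_test(c[:2], c[2:], dispersion=alpha) < 0.05:
                rejections += 1
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rejections / n_sim - 0.05) < 3 * se


class TestDispersion:
    def test_zero_when_variance_equals_mean(self):
        counts = pd.DataFrame(
            {"s1": [8], "s2": [12], "s3": [9], "s4": [11]}, index=["t"]
        )
        # within-group variance ~ mean -> MoM clamps at 0 for a single row
        d = estimate_dispersion(counts, GROUPS)
        assert d.loc["t"] <= 0.02

    def test_constant_counts_give_zero(self):
        counts = pd.DataFrame({s: [10] for s in GROUPS}, index=["t"])
        assert estimate_dispersion(counts, GROUPS).loc["t"] == 0.0

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(5)
        alpha, mu, n = 0.1, 100.0, 50
        size = 1.0 / alpha
        counts = pd.DataFrame(
            rng.negative_binomial(size, size / (size + mu), size=(400, 2 * n)),
            columns=[f"s{i}" for i in range(2 * n)],
        )
        groups = {f"s{i}": ("g1" if i < n else "g2") for i in range(2 * n)}
        d = estimate_dispersion(counts, groups)
        assert d.mean() == pytest.approx(alpha, abs=0.02)

    def test_single_sample_group_rejected(self):
        counts = pd.DataFrame({"s1": [1], "s3": [2], "s4": [3]}, index=["t"])
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_dispersion(counts, GROUPS)


class TestCallDe:
    def _results(self, qs, lfcs):
        return pd.DataFrame({"q": qs, "log2fc": lfcs,
                             "p": qs, "direction": ["x"] * len(qs)})

    def test_summary_total_is_up_plus_down(self):
        res = self._results([0.01, 0.02, 0.5, 0.04], [1.0, -1.0, 2.0, 0.5])
        s = call_de(res)
        assert s["total"] == s["up"] + s["down"] == 3
        assert s["ns"] == 1

    def test_boundary_q_is_not_significant(self):
        s = call_de(self._results([0.05], [2.0]))
        assert s["total"] == 0 and s["ns"] == 1

    def test_q_threshold_one_calls_everything(self):
        s = call_de(self._results([0.9, 0.99], [1.0, -2.0]), q_threshold=1.0)
        assert s["total"] == 2


class TestRunDe:
    def test_group_swap_negates_log2fc_and_preserves_p(self, small_bundle):
        counts = small_bundle.counts.iloc[:60]
        breeds = small_bundle.config.sample_breeds
        res = run_de(counts, breeds)
        # rename so the lexicographic group order reverses
        flipped = {s: {"jinhua": "z_group", "yorkshire": "a_group"}[b]
                   for s, b in breeds.items()}
        res2 = run_de(counts, flipped)
        assert np.allclose(res["p"], res2["p"])
        # means sum with pseudocount: log2fc flips sign
        assert np.allclose(res["log2fc"], -res2["log2fc"], atol=1e-9)

    def test_planted_de_recovery_at_two_replicates(self, default_bundle):
        truth = default_bundle.truth.table
        tested = truth.index[truth["label"] != "noise"]
        res = run_de(default_bundle.counts.loc[tested],
                     default_bundle.config.sample_breeds)
        sig = res["direction"] != "ns"
        true_de = truth.loc[tested, "true_de"]
        recall = (sig & true_de).sum() / true_de.sum()
        fdr = (sig & ~true_de).sum() / max(int(sig.sum()), 1)
        assert recall >= 0.8
        assert fdr <= 0.10
        # significant calls with finite planted effects go the right way
        finite = true_de & sig & np.isfinite(truth.loc[tested, "true_log2fc"])
        assert (
            np.sign(res.loc[finite, "log2fc"])
            == np.sign(truth.loc[tested, "true_log2fc"][finite])
        ).all()


def test_size_factors_median_of_ratios():
    counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
    sf = size_factors(counts)
    assert sf["s2"] / sf["s1"] == pytest.approx(2.0)


def test_aggregate_to_genes_sums_transcripts():
    counts = pd.DataFrame({"s1": [1, 2, 5]}, index=["t1", "t2", "t3"])
    genes = aggregate_to_genes(counts, {"t1": "g", "t2": "g", "t3": "h"})
    assert genes.at["g", "s1"] == 3 and genes.at["h", "s1"] == 5
    with pytest.raises(ValueError, match="without gene"):
        aggregate_to_genes(counts, {"t1": "g"})
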