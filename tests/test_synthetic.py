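"""Ground-truth bookkeeping and distributional checks of the generator."""
import hashlib
from pathlib import Path

import numpy as np
import pytest
from oracles import brute_longest_orf_codons

from conftest import TINY_SIM
from thyrolnc.synthetic import (
    CapacityError,
    SimulationConfig,
    plan,
    simulate,
    simulate_counts,
    write_bundle,
)


def _dir_hash(path: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(path.rglob("*")):
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()


def test_fixed_seed_gives_byte_identical_outputs(tmp_path):
    cfg = SimulationConfig(seed=7, **TINY_SIM)
    write_bundle(simulate(cfg), tmp_path / "a")
    write_bundle(simulate(cfg), tmp_path / "b")
    assert _dir_hash(tmp_path / "a") == _dir_hash(tmp_path / "b")


def test_distinct_seeds_differ(tmp_path):
    write_bundle(simulate(SimulationConfig(seed=7, **TINY_SIM)), tmp_path / "a")
    write_bundle(simulate(SimulationConfig(seed=8, **TINY_SIM)), tmp_path / "b")
    assert _dir_hash(tmp_path / "a") != _dir_hash(tmp_path / "b")


def test_truth_is_a_partition(small_bundle):
    table = small_bundle.truth.table
    sizes = table["label"].value_counts()
    cfg = small_bundle.config
    assert sizes["known_mRNA"] == cfg.n_known_mrna
    assert sizes["novel_mRNA"] == cfg.n_novel_mrna
    assert sizes["lncRNA"] == cfg.n_lncrna
    assert sizes["noise"] == cfg.n_noise
    assert sizes.sum() == len(table)
    # every emitted model maps to exactly one truth record
    for m in small_bundle.models:
        assert m.transcript_id.split(".")[-1] in table.index


def test_no_mrna_records_when_none_requested():
    cfg = SimulationConfig(
        seed=2, **{**TINY_SIM, "n_known_mrna": 0, "n_cis_pairs_within": 0,
                   "n_cis_pairs_beyond": 0, "breed_specific_fraction": 0.0,
                   "n_dominant": 0},
    )
    bundle = simulate(cfg)
    assert all(a.biotype != "mRNA" for a in bundle.annotation)


def test_capacity_error_when_chromosomes_too_small():
    with pytest.raises(CapacityError):
        plan(SimulationConfig(seed=1, **{**TINY_SIM, "chrom_length": 20_000}))


def test_planted_lncrnas_have_no_long_orf(small_bundle):
    truth = small_bundle.truth
    lnc = truth.table.index[truth.table["label"] == "lncRNA"]
    for tid in lnc:
        assert brute_longest_orf_codons(truth.designed_seqs[tid]) < 100


def test_planted_mrnas_have_one_long_orf(small_bundle):
    truth = small_bundle.truth
    coding_ids = truth.table.index[truth.table["coding"]]
    for tid in list(coding_ids)[:20]:
        assert brute_longest_orf_codons(truth.designed_seqs[tid]) >= 200


def test_planted_transcripts_satisfy_reliability_rule(small_bundle):
    truth = small_bundle.truth
    for tid, row in truth.table.iterrows():
        occ = truth.support_plan[tid]
        samples = {s for s, _ in occ}
        assemblers = {a for _, a in occ}
        reliable = len(samples) >= 2 or len(assemblers) == 2
        if row["label"] != "noise":
            assert reliable, tid
        elif row["noise_class"] == "private_singleton":
            assert len(occ) == 1 and not reliable, tid


def test_annotation_represents_every_removable_biotype(small_bundle):
    biotypes = {a.biotype for a in small_bundle.annotation}
    assert {"pseudogene", "pre_miRNA", "tRNA", "rRNA", "snoRNA"} <= biotypes


def test_annotation_loci_do_not_overlap(small_bundle):
    by_chrom = {}
    for a in small_bundle.annotation:
        by_chrom.setdefault(a.chrom, []).append((a.start, a.end))
    for ivs in by_chrom.values():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert s2 >= e1


def test_de_fraction_zero_gives_no_planted_fold_changes():
    cfg = SimulationConfig(
        seed=3, **{**TINY_SIM, "de_fraction": 0.0, "n_cis_pairs_within": 0,
                   "n_cis_pairs_beyond": 0, "breed_specific_fraction": 0.0},
    )
    truth = plan(cfg)
    assert not truth.table["true_de"].any()
    assert (truth.table["true_log2fc"] == 0).all()


class TestCountModel:
    def _moment_config(self, dispersion):
        return SimulationConfig(
            seed=5, n_chromosomes=4, chrom_length=2_500_000,
            n_known_mrna=0, n_novel_mrna=0, n_lncrna=0, n_noise=2500,
            n_noncoding_per_biotype=1, n_cis_pairs_within=0,
            n_cis_pairs_beyond=0, breed_specific_fraction=0.0, n_dominant=0,
            de_fraction=0.0, nb_dispersion=dispersion,
        )

    def test_poisson_limit_variance_equals_mean(self):
        cfg = self._moment_config(1e-12)
        truth = plan(cfg)
        counts, lib = simulate_counts(cfg, truth)
        z = counts.div(lib / lib.mean(), axis=1)  # undo depth scaling
        m = z.mean(axis=1)
        v = z.var(axis=1, ddof=1)
        ratio = (v / m).mean()
        # 10,000 draws; var of the per-transcript ratio is ~2/3 at n=4
        assert abs(ratio - 1.0) < 3 * np.sqrt(2 / 3 / len(counts))

    def test_nb_moments_recover_configured_dispersion(self):
        alpha = 0.25
        cfg = self._moment_config(alpha)
        truth = plan(cfg)
        counts, lib = simulate_counts(cfg, truth)
        z = counts.div(lib / lib.mean(), axis=1)
        m = z.mean(axis=1).to_numpy()
        v = z.var(axis=1, ddof=1).to_numpy()
        alpha_hat = np.sum((v - m) * m**2) / np.sum(m**4)  # LS slope
        assert alpha_hat == pytest.approx(alpha, abs=0.05)

    def test_fixed_seed_count_matrix_is_identical(self):
        cfg = self._moment_config(0.1)
        truth = plan(cfg)
        c1, l1 = simulate_counts(cfg, truth)
        c2, l2 = simulate_counts(cfg, truth)
        assert c1.equals(c2) and l1.equals(l2)


class TestPhenotypesAndQpcr:
    def test_summary_layout(self, small_bundle):
        summary = small_bundle.phenotype_summary
        assert set(summary.columns) == {"trait", "breed", "mean", "sem", "n"}
        assert (summary["n"] == 3).all()
        assert set(summary["breed"]) == set(small_bundle.config.breeds)

    def test_ct_values_encode_planted_fold_change(self, small_bundle):
        from thyrolnc.stats import ddct

        ct = small_bundle.qpcr_ct
        b1, b2 = small_bundle.config.breeds
        for gene, sub in ct.groupby("gene"):
            means = sub.groupby("breed")[["ct_target", "ct_reference"]].mean()
            res = ddct(
                means.at[b2, "ct_target"], means.at[b2, "ct_reference"],
                means.at[b1, "ct_target"], means.at[b1, "ct_reference"],
            )
            lfc = sub["true_log2fc"].iloc[0]
            assert np.log2(res["fold_change"]) == pytest.approx(lfc, abs=0.2)


def test_cis_pair_planting_distances(small_bundle):
    truth = small_bundle.truth
    models = truth.models
    gene_of = truth.table["gene_id"]
    locus = {
        gene_of[t]: (models[t].chrom, models[t].start, models[t].end)
        for t in truth.table.index
    }
    for _, row in truth.cis_pairs.iterrows():
        lc, ls, le = locus[row["lnc_gene_id"]]
        mc, ms, me = locus[row["mrna_gene_id"]]
        assert lc == mc
        gap = max(ms - le, ls - me)
        assert gap == row["planned_distance"]
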