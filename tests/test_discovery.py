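"""The filter cascade: coverage, structure, annotation, coding consensus."""
import pandas as pd
import pytest

from thyrolnc import discovery as dc
from thyrolnc.models import CodingVerdict, SupportRecord, TranscriptModel


def _record(key, exons=((0, 100), (200, 350)), cov=10.0, strand="+", chrom="chr1",
            gene="g"):
    model = TranscriptModel(
        transcript_id=key, gene_id=gene, chrom=chrom, strand=strand,
        exons=exons, coverage=cov,
    )
    return SupportRecord(key=key, samples={"s1", "s2"}, assemblers={"A1"},
                         representative=model, coverage=cov)


def _verdict(coding=False):
    return CodingVerdict(
        hexamer_score=-1, hexamer_coding=False,
        orf_fraction_score=-0.3, orf_fraction_coding=False,
        domain_evalue=float("inf"), domain_coding=False,
        longest_orf_codons=120 if coding else 20, orf_coding=coding,
    )


class TestCoverageFilter:
    def test_boundary_is_strict_less_than(self):
        passed, dropped = dc.filter_coverage(
            [_record("a", cov=2.9), _record("b", cov=3.0), _record("c", cov=3.1)]
        )
        assert [r.key for r in dropped] == ["a"]
        assert [r.key for r in passed] == ["b", "c"]

    def test_empty_input(self):
        assert dc.filter_coverage([]) == ([], [])


class TestStructureFilter:
    @pytest.mark.parametrize(
        "exons, kept",
        [
            (((0, 5000),), False),                 # single exon, any length
            (((0, 100), (200, 299)), False),       # 199 bp total
            (((0, 100), (200, 300)), True),        # exactly 200 bp
            (((0, 400), (500, 800), (900, 1200)), True),
        ],
    )
    def test_exon_count_and_length_boundaries(self, exons, kept):
        passed, dropped = dc.filter_structure([_record("x", exons=exons)])
        assert (len(passed) == 1) == kept

    def test_commutes_with_coverage_filter(self, small_bundle):
        from thyrolnc.merge import apply_reliability_rule, pool_models

        retained, _, _ = apply_reliability_rule(pool_models(small_bundle.models))
        a = dc.filter_structure(dc.filter_coverage(retained)[0])[0]
        b = dc.filter_coverage(dc.filter_structure(retained)[0])[0]
        assert sorted(r.key for r in a) == sorted(r.key for r in b)


class TestRemoveAnnotated:
    def _annotation(self):
        return [
            TranscriptModel("mrna1", "gm", "chr1", "+",
                            exons=((0, 100), (200, 350)), biotype="mRNA"),
            TranscriptModel("rrna1", "gr", "chr1", "+",
                            exons=((1000, 1400),), biotype="rRNA"),
        ]

    def test_intron_chain_match_labels_known_mrna(self):
        known, removed, survivors = dc.remove_annotated(
            [_record("hit", exons=((10, 100), (200, 340)))], self._annotation()
        )
        assert len(known) == 1 and known[0].matched_annotation_id == "mrna1"
        assert not removed and not survivors

    def test_same_strand_rrna_overlap_removed(self):
        known, removed, survivors = dc.remove_annotated(
            [_record("r", exons=((900, 1100), (1500, 1700)))], self._annotation()
        )
        assert len(removed) == 1
        assert removed[0].discard_reason == "annotated_noncoding_biotype"

    def test_antisense_overlap_is_not_removed(self):
        known, removed, survivors = dc.remove_annotated(
            [_record("r", exons=((900, 1100), (1500, 1700)), strand="-")],
            self._annotation(),
        )
        assert len(survivors) == 1

    def test_no_overlap_survives(self):
        known, removed, survivors = dc.remove_annotated(
            [_record("far", exons=((5000, 5200), (5400, 5600)))], self._annotation()
        )
        assert len(survivors) == 1

    def test_missing_biotype_is_configuration_error(self):
        ann = [TranscriptModel("x", "g", "chr1", "+", exons=((0, 50),))]
        with pytest.raises(ValueError, match="biotype"):
            dc.AnnotationIndex(ann)


class TestClassifySurvivors:
    def test_domain_evalue_below_threshold_makes_novel_mrna(self):
        v = _verdict(coding=False)
        v.domain_evalue, v.domain_coding = 5e-4, True
        novel, lnc = dc.classify_survivors([_record("a")], {"a": v})
        assert [c.key for c in novel] == ["a"] and not lnc

    def test_all_negative_scorers_make_candidate_lncrna(self):
        novel, lnc = dc.classify_survivors([_record("a")], {"a": _verdict(False)})
        assert [c.key for c in lnc] == ["a"] and not novel

    def test_empty_survivors(self):
        assert dc.classify_survivors([], {}) == ([], [])

    def test_missing_verdict_is_error(self):
        with pytest.raises(ValueError, match="verdict"):
            dc.classify_survivors([_record("a")], {})

    def test_consensus_monotone_under_extra_coding_evidence(self):
        lenient = _verdict(False)
        stricter = _verdict(False)
        stricter.hexamer_coding = True
        novel0, _ = dc.classify_survivors([_record("a")], {"a": lenient})
        novel1, _ = dc.classify_survivors([_record("a")], {"a": stricter})
        # flipping one scorer to coding can only move toward novel_mRNA
        assert len(novel1) >= len(novel0)


class TestRunDiscovery:
    def test_stage_counts_monotone_nonincreasing(self, default_discovery):
        counts = default_discovery["stage_counts"]["survivors"]
        assert (counts.diff().dropna() <= 0).all()

    def test_classes_partition_input(self, default_discovery):
        classified = default_discovery["classified"]
        retained = default_discovery["retained"]
        assert len(classified) == len(retained)
        assert len({c.key for c in classified}) == len(classified)

    def test_perfect_label_recovery(self, default_bundle, default_discovery):
        truth = default_bundle.truth.table
        pred = {c.key: c.label for c in default_discovery["classified"]}
        expect = {"known_mRNA": "known_mRNA", "novel_mRNA": "novel_mRNA",
                  "lncRNA": "candidate_lncRNA"}
        for key, label in zip(truth["key"], truth["label"]):
            if label in expect:
                assert pred[key] == expect[label]
            else:  # noise is either unreliable (absent) or discarded
                assert pred.get(key, "discarded") == "discarded"

    def test_all_noise_input_discards_everything(self, default_bundle):
        from thyrolnc.merge import apply_reliability_rule, pool_models

        noise_ids = set(
            default_bundle.truth.table.index[
                default_bundle.truth.table["label"] == "noise"
            ]
        )
        noise_models = [
            m for m in default_bundle.models
            if m.transcript_id.split(".")[-1] in noise_ids
        ]
        retained, _, _ = apply_reliability_rule(pool_models(noise_models))
        classified, _ = dc.run_discovery(
            retained, default_bundle.annotation, default_bundle.genome
        )
        assert classified and all(c.label == "discarded" for c in classified)
        assert all(c.discard_reason != "none" for c in classified)

    def test_external_scores_bypass_standin_scorers(self, small_bundle):
        from thyrolnc.merge import apply_reliability_rule, pool_models

        retained, _, _ = apply_reliability_rule(pool_models(small_bundle.models))
        truth = small_bundle.truth.table
        lnc_keys = set(truth.loc[truth["label"] == "lncRNA", "key"])
        # declare every true lncRNA coding via an external CNCI-like score
        scores = pd.DataFrame(
            [{"key": k, "tool": "cnci", "value": 2.0} for k in lnc_keys]
        )
        classified, _ = dc.run_discovery(
            retained, small_bundle.annotation, small_bundle.genome,
            external_scores=scores,
        )
        labels = {c.key: c.label for c in classified}
        assert all(labels[k] == "novel_mRNA" for k in lnc_keys)
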