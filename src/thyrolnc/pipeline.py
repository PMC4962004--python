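"""End-to-end pipeline driver.

Runs the synthetic study through every stage -- merge, discovery,
quantification, differential expression, cis target prediction,
homology, enrichment and phenotype statistics -- and collects a report
of per-stage counts together with the additive identities the stages
must satisfy (expressed = shared + breed-specific; DE total = up +
down; cis pairs = same + opposite direction).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from . import cis as cis_mod
from . import de as de_mod
from . import discovery as disc_mod
from . import enrich as enrich_mod
from . import homology as hom_mod
from . import merge as merge_mod
from . import quant as quant_mod
from . import stats as stats_mod
from .models import GroupSummary
from .synthetic import SimulationConfig, SyntheticBundle, simulate


@dataclass
class PipelineConfig:
    """Thresholds and paths driving a full pipeline run."""

    seed: int = 1
    min_coverage: float = 3.0
    min_exons: int = 2
    min_length: int = 200
    q_threshold: float = 0.05
    window: int = 100_000
    e_threshold: float = 1e-6
    expressed_threshold: float = 0.0
    high_threshold: float = 1000.0
    min_shared_kmers: Optional[int] = 4
    run_homology: bool = True
    outdir: Optional[str] = None
    simulation: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("min_coverage", "min_length", "q_threshold", "window",
                     "e_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def simulation_config(self) -> SimulationConfig:
        params = dict(self.simulation)
        params.setdefault("seed", self.seed)
        return SimulationConfig(**params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, cfg_hash: str,
               index: bool = False, index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage on a freshly simulated study.

    Returns a report dict; when ``config.outdir`` is set, all stage
    tables are written there with a header naming the stage and the
    config hash.
    """
    cfg_hash = config.config_hash()
    sim_config = config.simulation_config()
    bundle = simulate(sim_config)
    report: dict[str, Any] = {"config_hash": cfg_hash, "seed": config.seed}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- merge -----------------------------------------------------------
    pooled = merge_mod.pool_models(bundle.models)
    retained, dropped, drop_counts = merge_mod.apply_reliability_rule(pooled)
    report["merge"] = {
        "input_models": len(bundle.models),
        "pooled_structures": len(pooled),
        "reliable": len(retained),
        **drop_counts,
    }

    # --- discovery --------------------------------------------------------
    classified, stage_counts = disc_mod.run_discovery(
        retained, bundle.annotation, bundle.genome,
        min_coverage=config.min_coverage, min_exons=config.min_exons,
        min_length=config.min_length,
    )
    class_table = disc_mod.classification_table(classified)
    label_counts = class_table["label"].value_counts().to_dict()
    report["discovery"] = {
        "stage_counts": dict(zip(stage_counts["stage"], stage_counts["survivors"])),
        "labels": label_counts,
    }

    # Transcript bookkeeping: structure key -> counts-table transcript id.
    keys = bundle.truth.table["key"]
    key_to_tid = pd.Series(keys.index, index=keys.to_numpy())
    class_table = class_table.assign(
        transcript_id=class_table["key"].map(key_to_tid)
    )
    label_of = class_table.set_index("transcript_id")["label"]

    # --- quantification ---------------------------------------------------
    lengths = bundle.truth.table["length"]
    fpkm = quant_mod.compute_fpkm(bundle.counts, lengths, bundle.library_sizes)
    breed_map = sim_config.sample_breeds
    known_ids = [t for t in bundle.counts.index if label_of.get(t) == "known_mRNA"]
    sets = quant_mod.expression_sets(
        fpkm.loc[known_ids], breed_map,
        expressed_threshold=config.expressed_threshold,
        high_threshold=config.high_threshold,
    )
    specific_sizes = {k: len(v) for k, v in sets.items() if k.startswith("specific:")}
    report["quant"] = {
        "known_expressed": len(sets["expressed"]),
        "known_shared": len(sets["shared"]),
        **specific_sizes,
        "high_expression": len(sets["high"]),
        "identity_expressed_eq_shared_plus_specific": (
            len(sets["expressed"])
            == len(sets["shared"]) + sum(specific_sizes.values())
        ),
    }

    # --- differential expression (transcript level, one BH family) --------
    tested_ids = [
        t for t in bundle.counts.index
        if label_of.get(t) in {"known_mRNA", "novel_mRNA", "candidate_lncRNA"}
    ]
    de_results = de_mod.run_de(
        bundle.counts.loc[tested_ids], breed_map, q_threshold=config.q_threshold
    )
    de_results = de_results.assign(label=[label_of[t] for t in de_results.index])
    de_report = {}
    for label, sub in de_results.groupby("label"):
        summary = de_mod.call_de(sub, config.q_threshold)
        summary["identity_total_eq_up_plus_down"] = (
            summary["total"] == summary["up"] + summary["down"]
        )
        de_report[label] = summary
    report["de"] = de_report

    # --- cis targets (gene level) ------------------------------------------
    tx2gene = bundle.truth.table["gene_id"].to_dict()
    lnc_ids = [t for t in tested_ids if label_of[t] == "candidate_lncRNA"]
    gene_counts = de_mod.aggregate_to_genes(
        bundle.counts.loc[known_ids + lnc_ids], tx2gene
    )
    gene_de = de_mod.run_de(gene_counts, breed_map, q_threshold=config.q_threshold)
    lnc_genes = {tx2gene[t] for t in lnc_ids}
    known_genes = {tx2gene[t] for t in known_ids}
    sig = gene_de[gene_de["direction"] != "ns"]
    lnc_dirs = {g: d for g, d in sig["direction"].items() if g in lnc_genes}
    mrna_dirs = {g: d for g, d in sig["direction"].items() if g in known_genes}

    reps = {c.key: c.representative for c in classified if c.representative}
    key_of_tid = keys.to_dict()
    lnc_loci = cis_mod.gene_loci(
        reps[key_of_tid[t]] for t in lnc_ids if tx2gene[t] in lnc_dirs
    )
    mrna_loci = cis_mod.gene_loci(
        reps[key_of_tid[t]] for t in known_ids if tx2gene[t] in mrna_dirs
    )
    pairs, pair_summary = cis_mod.predict_pairs(
        lnc_loci, mrna_loci, lnc_dirs, mrna_dirs, window=config.window
    )
    pair_summary["identity_total_eq_same_plus_opposite"] = (
        pair_summary["n_pairs"]
        == pair_summary["same_direction"] + pair_summary["opposite_direction"]
    )
    report["cis"] = pair_summary

    # --- homology -----------------------------------------------------------
    if config.run_homology:
        from .gtf import spliced_sequence

        candidates = {
            t: spliced_sequence(bundle.genome, reps[key_of_tid[t]]) for t in lnc_ids
        }
        if candidates and bundle.homology_dbs:
            flags, percentages = hom_mod.classify_homology(
                candidates,
                {"human": bundle.homology_dbs["human"],
                 "mouse": bundle.homology_dbs["mouse"]},
                e_threshold=config.e_threshold,
                min_shared_kmers=config.min_shared_kmers,
            )
            aldb_flags, aldb_pct = hom_mod.classify_homology(
                candidates, {"aldb": bundle.homology_dbs["aldb"]},
                e_threshold=config.e_threshold,
                min_shared_kmers=config.min_shared_kmers,
            )
            report["homology"] = {
                "n_candidates": len(candidates),
                "percent": {**percentages, **aldb_pct},
            }
        else:
            flags = pd.DataFrame()
            report["homology"] = {"n_candidates": 0, "percent": {}}
    else:
        flags = pd.DataFrame()

    # --- enrichment -----------------------------------------------------------
    universe = sorted({tx2gene[t] for t in sets["expressed"]})
    de_known_genes = sorted(
        {tx2gene[t] for t in de_results.index
         if de_results.at[t, "direction"] != "ns"
         and label_of[t] == "known_mRNA" and tx2gene[t] in set(universe)}
    )
    term_map = bundle.term_map[bundle.term_map["gene"].isin(universe)]
    enrichment = enrich_mod.enrich_terms(de_known_genes, universe, term_map)
    report["enrich"] = {
        "n_terms_tested": int(len(enrichment)),
        "n_enriched": int(enrichment["enriched"].sum()) if len(enrichment) else 0,
        "top_terms": enrichment.head(3)["term"].tolist() if len(enrichment) else [],
    }

    # --- phenotype statistics ---------------------------------------------
    pheno = bundle.phenotype_summary
    b1, b2 = sim_config.breeds
    stats_rows = []
    for trait, sub in pheno.groupby("trait"):
        by_breed = sub.set_index("breed")
        g1 = GroupSummary(by_breed.at[b1, "mean"], by_breed.at[b1, "sem"],
                          int(by_breed.at[b1, "n"]))
        g2 = GroupSummary(by_breed.at[b2, "mean"], by_breed.at[b2, "sem"],
                          int(by_breed.at[b2, "n"]))
        res = stats_mod.ttest_summary(g1, g2)
        stats_rows.append({"trait": trait, **res})
    qpcr_rows = []
    for gene, sub in bundle.qpcr_ct.groupby("gene"):
        means = sub.groupby("breed")[["ct_target", "ct_reference"]].mean()
        res = stats_mod.ddct(
            means.at[b2, "ct_target"], means.at[b2, "ct_reference"],
            means.at[b1, "ct_target"], means.at[b1, "ct_reference"],
        )
        qpcr_rows.append({"gene": gene, **res})
    report["stats"] = {
        "phenotype_tests": stats_rows,
        "qpcr_fold_changes": qpcr_rows,
    }

    # --- optional file output ------------------------------------------------
    if outdir:
        _write_tsv(merge_mod.support_table(pooled), outdir / "support.tsv",
                   "merge", cfg_hash)
        _write_tsv(class_table, outdir / "classification.tsv", "discovery", cfg_hash)
        _write_tsv(stage_counts, outdir / "stage_counts.tsv", "discovery", cfg_hash)
        _write_tsv(fpkm, outdir / "fpkm.tsv", "quant", cfg_hash,
                   index=True, index_label="transcript_id")
        _write_tsv(de_results, outdir / "de_transcripts.tsv", "de", cfg_hash,
                   index=True, index_label="transcript_id")
        _write_tsv(gene_de, outdir / "de_genes.tsv", "de", cfg_hash,
                   index=True, index_label="gene_id")
        _write_tsv(cis_mod.pairs_table(pairs), outdir / "cis_pairs.tsv",
                   "cis", cfg_hash)
        if config.run_homology and len(flags):
            _write_tsv(flags.reset_index(names="transcript_id"),
                       outdir / "homology_flags.tsv", "homology", cfg_hash)
        _write_tsv(enrichment, outdir / "enrichment.tsv", "enrich", cfg_hash)
        _write_tsv(pd.DataFrame(stats_rows), outdir / "phenotype_tests.tsv",
                   "stats", cfg_hash)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
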