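"""Synthetic two-breed RNA-seq study generator with recorded ground truth.

Emulates the design of a two-breed (fat-type vs lean-type pig) bulk
Ribo-Zero RNA-seq comparison: two sequencing samples per breed, each
assembled independently by two assemblers; a reference annotation with
known mRNAs and five removable noncoding biotypes; planted novel mRNAs,
lncRNAs and structured noise classes; negative-binomial counts with
planted breed effects; cis lncRNA-mRNA gene pairs within and beyond the
100 kb window; phenotype panels (3 animals per breed) and qPCR Ct
tables.

Every artifact draws from its own pseudo-random stream derived from the
master seed by a fixed key, so adding one artifact never perturbs the
others, and a fixed seed yields byte-identical outputs.

Planted sequence margins: coding ORFs span 200-350 codons while
noncoding transcripts are scrubbed of any six-frame ORF reaching 80
codons and are re-sampled until the whole coding-potential consensus
calls them noncoding.  The wide margin makes the synthetic truth
perfectly separable by the discovery cascade, which is what lets label
recovery serve as an end-to-end check.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .coding import CODON_WEIGHTS, DOMAIN_LIBRARY, SENSE_CODONS, score_coding
from .gtf import write_fasta, write_gtf
from .models import TranscriptModel, structure_key
from .orf import find_orfs

# Stream keys for per-artifact RNGs
_S_STRUCT, _S_SEQ, _S_GENOME, _S_EMIT, _S_COUNTS, _S_PHENO, _S_QPCR, _S_TERMS, _S_HOMOL = range(9)

BIOTYPES_REMOVED = ("pseudogene", "pre_miRNA", "tRNA", "rRNA", "snoRNA")
NOISE_CLASSES = (
    "private_singleton", "low_coverage", "single_exon", "too_short",
    "annotated_noncoding",
)


class CapacityError(ValueError):
    """Raised when the configured chromosomes cannot hold all loci."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic two-breed experiment."""

    seed: int = 1
    n_chromosomes: int = 5
    chrom_length: int = 3_000_000
    n_known_mrna: int = 800
    n_novel_mrna: int = 300
    n_lncrna: int = 400
    n_noise: int = 500
    n_noncoding_per_biotype: int = 5
    n_samples_per_breed: int = 2
    breeds: tuple[str, str] = ("jinhua", "yorkshire")
    nb_dispersion: float = 0.05
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    window_planting: tuple[int, int] = (10_000, 150_000)
    n_cis_pairs_within: int = 4
    n_cis_pairs_beyond: int = 3
    breed_specific_fraction: float = 0.1
    n_dominant: int = 3
    mean_library_size: float = 10_000_000.0
    homology_fraction_human: float = 0.465
    homology_fraction_both: float = 0.194
    homology_fraction_mouse: float = 0.233
    homology_fraction_aldb: float = 0.647

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_samples_per_breed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_known_mrna", "n_novel_mrna", "n_lncrna", "n_noise",
                     "n_noncoding_per_biotype"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        n_pairs = self.n_cis_pairs_within + self.n_cis_pairs_beyond
        if n_pairs > min(self.n_lncrna, self.n_known_mrna):
            raise ValueError("not enough lncRNAs/mRNAs to host the planted cis pairs")

    @property
    def samples(self) -> list[str]:
        return [
            f"{breed}_{i + 1}"
            for breed in self.breeds
            for i in range(self.n_samples_per_breed)
        ]

    @property
    def sample_breeds(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.samples}


ASSEMBLERS = ("cufflinks", "scripture")


@dataclass
class SyntheticTruth:
    """Ground-truth bookkeeping for one simulated study."""

    config: SimulationConfig
    table: pd.DataFrame  # indexed by transcript_id
    models: dict[str, TranscriptModel]  # canonical model per transcript
    annotation: list[TranscriptModel]
    designed_seqs: dict[str, str]  # spliced sense-strand overlays
    support_plan: dict[str, list[tuple[str, str]]]  # canonical occurrence first
    coverage_plan: dict[str, list[float]]
    cis_pairs: pd.DataFrame


# ---------------------------------------------------------------------------
# Sequence design helpers

_AA_TO_CODONS: dict[str, list[str]] = {}


def _aa_codons() -> dict[str, list[str]]:
    if not _AA_TO_CODONS:
        from Bio.Seq import Seq

        for c in SENSE_CODONS:
            _AA_TO_CODONS.setdefault(str(Seq(c).translate()), []).append(c)
    return _AA_TO_CODONS


_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return _BASE_CODES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


_CODON_P = np.array([CODON_WEIGHTS[c] for c in SENSE_CODONS])


def _destroy_orfs(seq: str, max_codons: int, max_rounds: int = 80) -> str | None:
    """Insert stop codons until no six-frame ORF reaches ``max_codons``.

    Each insertion halves one long ORF, but the junction bases can spawn
    a fresh ATG on either strand, so convergence is not guaranteed for
    every sequence; after ``max_rounds`` the caller must resample.
    """
    for _ in range(max_rounds):
        long_orfs = [o for o in find_orfs(seq) if o.codons >= max_codons]
        if not long_orfs:
            return seq
        o = long_orfs[0]
        mid = o.start + 3 * (o.codons // 2)
        if o.strand == "+":
            seq = seq[:mid] + "TAA" + seq[mid + 3:]
        else:
            j = len(seq) - mid - 3
            seq = seq[:j] + "TTA" + seq[j + 3:]
    return None


def _design_coding_seq(rng: np.random.Generator, total_length: int,
                       plant_domain: bool) -> str:
    """Spliced mRNA sequence: UTRs around one dominant ORF of 200-350 codons."""
    n_codons = int(rng.integers(200, 351))
    cds_len = 3 * n_codons + 6  # ATG + codons + stop
    utr_total = max(total_length - cds_len, 60)
    utr5 = int(rng.integers(20, max(21, utr_total - 20)))
    utr3 = utr_total - utr5
    codons = list(rng.choice(SENSE_CODONS, size=n_codons, p=_CODON_P))
    if plant_domain:
        peptides = sorted(DOMAIN_LIBRARY.values())
        pep = peptides[int(rng.integers(len(peptides)))]
        pos = int(rng.integers(5, n_codons - len(pep) - 5))
        table = _aa_codons()
        for i, aa in enumerate(pep):
            options = table[aa]
            codons[pos + i] = options[int(rng.integers(len(options)))]
    return (
        _random_bases(rng, utr5) + "ATG" + "".join(codons) + "TAA"
        + _random_bases(rng, utr3)
    )


def _design_noncoding_seq(rng: np.random.Generator, length: int) -> str:
    """Noncoding sequence with no six-frame ORF >= 80 codons and a
    fully negative coding-potential consensus."""
    for _ in range(60):
        seq = _destroy_orfs(_random_bases(rng, length), max_codons=80)
        if seq is not None and not score_coding(seq).consensus:
            return seq
    raise RuntimeError("could not design a consensus-noncoding sequence")


# ---------------------------------------------------------------------------
# Locus structure planning

@dataclass
class _LocusSpec:
    tid: str
    gene_id: str
    label: str  # known_mRNA | novel_mRNA | lncRNA | noise
    noise_class: str = ""
    exon_lengths: list[int] = field(default_factory=list)
    intron_lengths: list[int] = field(default_factory=list)
    coverage: float = 0.0
    # filled at placement time:
    chrom: str = ""
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()

    @property
    def span(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)

    @property
    def spliced_length(self) -> int:
        return sum(self.exon_lengths)

    def place(self, chrom: str, start: int, strand: str) -> None:
        self.chrom, self.strand = chrom, strand
        exons = []
        pos = start
        for i, el in enumerate(self.exon_lengths):
            exons.append((pos, pos + el))
            pos += el
            if i < len(self.intron_lengths):
                pos += self.intron_lengths[i]
        self.exons = tuple(exons)

    def model(self) -> TranscriptModel:
        return TranscriptModel(
            transcript_id=self.tid, gene_id=self.gene_id, chrom=self.chrom,
            strand=self.strand, exons=self.exons, coverage=self.coverage,
        )


def _split_length(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list[int]:
    """Random composition of ``total`` into ``parts`` parts, each >= minimum."""
    if parts * minimum > total:
        raise ValueError("cannot split length")
    free = total - parts * minimum
    cuts = np.sort(rng.integers(0, free + 1, size=parts - 1)) if parts > 1 else np.array([], int)
    sizes = np.diff(np.concatenate([[0], cuts, [free]]))
    return [minimum + int(s) for s in sizes]


def _mrna_structure(rng: np.random.Generator) -> tuple[list[int], list[int]]:
    n_exons = int(rng.integers(3, 9))
    spliced = int(rng.integers(1150, 1700))  # holds a 200-350 codon ORF + UTRs
    exons = _split_length(rng, spliced, n_exons, 80)
    introns = [int(rng.integers(100, 1500)) for _ in range(n_exons - 1)]
    return exons, introns


def _lnc_structure(rng: np.random.Generator) -> tuple[list[int], list[int]]:
    n_exons = int(rng.integers(2, 5))
    spliced = int(rng.integers(700, 2000))
    exons = _split_length(rng, spliced, n_exons, 100)
    introns = [int(rng.integers(100, 1500)) for _ in range(n_exons - 1)]
    return exons, introns


# ---------------------------------------------------------------------------
# The planner

def plan(config: SimulationConfig) -> SyntheticTruth:
    """Lay out all loci, design sequences and record ground truth."""
    rng_struct = np.random.default_rng([config.seed, _S_STRUCT])
    rng_seq = np.random.default_rng([config.seed, _S_SEQ])

    specs: list[_LocusSpec] = []
    known: list[_LocusSpec] = []
    for i in range(config.n_known_mrna):
        exons, introns = _mrna_structure(rng_struct)
        s = _LocusSpec(
            tid=f"KNOWN{i:05d}", gene_id=f"GK{i:05d}", label="known_mRNA",
            exon_lengths=exons, intron_lengths=introns,
            coverage=float(np.round(rng_struct.uniform(5, 200), 2)),
        )
        known.append(s)
    novel: list[_LocusSpec] = []
    for i in range(config.n_novel_mrna):
        exons, introns = _mrna_structure(rng_struct)
        novel.append(_LocusSpec(
            tid=f"NOVEL{i:05d}", gene_id=f"GN{i:05d}", label="novel_mRNA",
            exon_lengths=exons, intron_lengths=introns,
            coverage=float(np.round(rng_struct.uniform(5, 200), 2)),
        ))
    lnc: list[_LocusSpec] = []
    for i in range(config.n_lncrna):
        exons, introns = _lnc_structure(rng_struct)
        lnc.append(_LocusSpec(
            tid=f"LNC{i:05d}", gene_id=f"GL{i:05d}", label="lncRNA",
            exon_lengths=exons, intron_lengths=introns,
            coverage=float(np.round(rng_struct.uniform(5, 80), 2)),
        ))
    noise: list[_LocusSpec] = []
    # the annotated-overlap class needs noncoding annotation loci to exist
    noise_classes = (
        NOISE_CLASSES if config.n_noncoding_per_biotype > 0 else NOISE_CLASSES[:-1]
    )
    for i in range(config.n_noise):
        cls = noise_classes[i % len(noise_classes)]
        if cls == "single_exon":
            exons, introns = [int(rng_struct.integers(300, 900))], []
            cov = float(np.round(rng_struct.uniform(5, 40), 2))
        elif cls == "too_short":
            total = int(rng_struct.integers(120, 180))
            exons = _split_length(rng_struct, total, 2, 50)
            introns = [int(rng_struct.integers(80, 300))]
            cov = float(np.round(rng_struct.uniform(5, 40), 2))
        elif cls == "low_coverage":
            exons, introns = _lnc_structure(rng_struct)
            cov = float(np.round(rng_struct.uniform(0.5, 2.89), 2))
        else:  # private_singleton / annotated_noncoding: ordinary structure
            exons, introns = _lnc_structure(rng_struct)
            cov = float(np.round(rng_struct.uniform(5, 40), 2))
        noise.append(_LocusSpec(
            tid=f"NOISE{i:05d}", gene_id=f"GX{i:05d}", label="noise",
            noise_class=cls, exon_lengths=exons, intron_lengths=introns,
            coverage=cov,
        ))
    specs = known + novel + lnc + noise

    nc_loci: list[_LocusSpec] = []
    for b, biotype in enumerate(BIOTYPES_REMOVED):
        for j in range(config.n_noncoding_per_biotype):
            n_exons = int(rng_struct.integers(1, 3))
            total = int(rng_struct.integers(150, 400))
            exons = _split_length(rng_struct, total, n_exons, 70)
            introns = [int(rng_struct.integers(80, 300)) for _ in range(n_exons - 1)]
            s = _LocusSpec(
                tid=f"NC_{biotype}_{j:03d}", gene_id=f"GNC_{biotype}_{j:03d}",
                label="annotation_noncoding", noise_class=biotype,
                exon_lengths=exons, intron_lengths=introns,
            )
            nc_loci.append(s)

    # --- placement groups ------------------------------------------------
    n_within = config.n_cis_pairs_within
    n_beyond = config.n_cis_pairs_beyond
    pair_plan: list[tuple[int, bool]] = [(config.window_planting[0], True)] * n_within
    pair_plan += [(config.window_planting[1], False)] * n_beyond

    anc_noise = [s for s in noise if s.noise_class == "annotated_noncoding"]
    groups: list[list[tuple[_LocusSpec, int]]] = []  # (spec, offset-in-group)
    paired_lnc = lnc[: len(pair_plan)]
    paired_mrna = known[: len(pair_plan)]
    for j, (dist, _within) in enumerate(pair_plan):
        a, b = paired_lnc[j], paired_mrna[j]
        groups.append([(a, 0), (b, a.span + dist)])
    used = set(id(s) for s in paired_lnc) | set(id(s) for s in paired_mrna)

    for i, locus in enumerate(nc_loci):
        group = [(locus, 0)]
        attached = anc_noise[i::len(nc_loci)] if nc_loci else []
        for s in attached:
            # overlap: noise first exon starts inside the locus first exon
            s.exon_lengths = s.exon_lengths.copy()
            group.append((s, 0))
            used.add(id(s))
        groups.append(group)
    for s in specs:
        if id(s) not in used:
            groups.append([(s, 0)])

    order = rng_struct.permutation(len(groups))
    groups = [groups[i] for i in order]

    cursors = {f"chr{c + 1}": 0 for c in range(config.n_chromosomes)}
    chrom_names = sorted(cursors, key=lambda c: int(c[3:]))
    for gi, group in enumerate(groups):
        chrom = chrom_names[gi % len(chrom_names)]
        gap = int(rng_struct.integers(600, 2000))
        start = cursors[chrom] + gap
        strand = "+" if rng_struct.random() < 0.5 else "-"
        end = start
        for spec, offset in group:
            spec.place(chrom, start + offset, strand)
            end = max(end, start + offset + spec.span)
        if end > config.chrom_length:
            raise CapacityError(
                f"chrom_length {config.chrom_length} too small to place all loci "
                f"(overflow on {chrom})"
            )
        cursors[chrom] = end

    # --- sequences --------------------------------------------------------
    designed: dict[str, str] = {}
    for s in known + novel:
        designed[s.tid] = _design_coding_seq(
            rng_seq, s.spliced_length, plant_domain=bool(rng_seq.random() < 0.5)
        )
    for s in lnc:
        designed[s.tid] = _design_noncoding_seq(rng_seq, s.spliced_length)

    # --- DE truth ---------------------------------------------------------
    rng_counts_plan = np.random.default_rng([config.seed, _S_COUNTS])
    pair_classes = ["up-up", "up-up", "down-down", "down-up"]
    true_de: dict[str, bool] = {}
    true_lfc: dict[str, float] = {}
    base_mean: dict[str, float] = {}
    specific_breed: dict[str, str] = {}

    pair_rows = []
    for j, (dist, within) in enumerate(pair_plan):
        cls = pair_classes[j % len(pair_classes)]
        lnc_dir, mrna_dir = cls.split("-")
        for spec, direction in ((paired_lnc[j], lnc_dir), (paired_mrna[j], mrna_dir)):
            true_de[spec.tid] = True
            true_lfc[spec.tid] = config.de_log2fc if direction == "up" else -config.de_log2fc
        pair_rows.append({
            "lnc_gene_id": paired_lnc[j].gene_id,
            "mrna_gene_id": paired_mrna[j].gene_id,
            "planned_distance": dist,
            "within_window": within,
            "direction_class": cls,
        })
    cis_pairs = pd.DataFrame(
        pair_rows, columns=["lnc_gene_id", "mrna_gene_id", "planned_distance",
                            "within_window", "direction_class"])

    n_pairs = len(pair_plan)
    eligible_specific = known[n_pairs:]
    n_specific = int(round(config.breed_specific_fraction * len(eligible_specific)))
    for i, s in enumerate(eligible_specific[:n_specific]):
        breed = config.breeds[i % 2]
        specific_breed[s.tid] = breed
        true_de[s.tid] = True
        true_lfc[s.tid] = float("inf") if breed == config.breeds[1] else float("-inf")
    dominant = {
        x.tid for x in eligible_specific[n_specific: n_specific + config.n_dominant]
    }

    for s in specs:
        if s.label == "noise":
            base_mean[s.tid] = float(rng_counts_plan.uniform(5, 50))
            true_de.setdefault(s.tid, False)
            true_lfc.setdefault(s.tid, 0.0)
            continue
        if s.tid in dominant:
            base_mean[s.tid] = float(rng_counts_plan.uniform(25_000, 60_000))
        else:
            base_mean[s.tid] = float(np.clip(rng_counts_plan.lognormal(np.log(300), 1.0), 30, 20_000))
        if s.tid not in true_de:
            if rng_counts_plan.random() < config.de_fraction:
                sign = 1.0 if rng_counts_plan.random() < 0.5 else -1.0
                true_de[s.tid] = True
                true_lfc[s.tid] = sign * config.de_log2fc
            else:
                true_de[s.tid] = False
                true_lfc[s.tid] = 0.0

    # --- truth table -------------------------------------------------------
    models = {s.tid: s.model() for s in specs}
    rows = []
    for s in specs:
        m = models[s.tid]
        rows.append({
            "transcript_id": s.tid,
            "gene_id": s.gene_id,
            "label": s.label,
            "noise_class": s.noise_class,
            "chrom": s.chrom,
            "strand": s.strand,
            "start": m.start,
            "end": m.end,
            "n_exons": m.n_exons,
            "length": m.length,
            "coding": s.label in ("known_mRNA", "novel_mRNA"),
            "coverage": s.coverage,
            "true_de": true_de[s.tid],
            "true_log2fc": true_lfc[s.tid],
            "base_mean": base_mean[s.tid],
            "specific_breed": specific_breed.get(s.tid, ""),
            "key": structure_key(m),
        })
    table = pd.DataFrame(rows).set_index("transcript_id")

    annotation = [
        TranscriptModel(
            transcript_id=f"ANN_{s.tid}", gene_id=s.gene_id, chrom=s.chrom,
            strand=s.strand, exons=s.exons, biotype="mRNA",
        )
        for s in known
    ] + [
        TranscriptModel(
            transcript_id=s.tid, gene_id=s.gene_id, chrom=s.chrom,
            strand=s.strand, exons=s.exons, biotype=s.noise_class,
        )
        for s in nc_loci
    ]

    # --- support / coverage plan ------------------------------------------
    rng_emit = np.random.default_rng([config.seed, _S_EMIT])
    samples = config.samples
    support: dict[str, list[tuple[str, str]]] = {}
    covs: dict[str, list[float]] = {}
    for s in specs:
        if s.label == "noise" and s.noise_class == "private_singleton":
            occ = [(samples[int(rng_emit.integers(len(samples)))],
                    ASSEMBLERS[int(rng_emit.integers(2))])]
        elif s.label == "noise":
            pick = rng_emit.permutation(len(samples))[:2]
            asm = ASSEMBLERS[int(rng_emit.integers(2))]
            occ = [(samples[int(p)], asm) for p in pick]
        else:
            u = rng_emit.random()
            if u < 0.5:
                occ = [(sm, a) for sm in samples for a in ASSEMBLERS]
            elif u < 0.75:
                pick = rng_emit.permutation(len(samples))[:2]
                asm = ASSEMBLERS[int(rng_emit.integers(2))]
                occ = [(samples[int(p)], asm) for p in pick]
            else:
                sm = samples[int(rng_emit.integers(len(samples)))]
                occ = [(sm, a) for a in ASSEMBLERS]
        support[s.tid] = occ
        c = [s.coverage]
        c += [float(np.round(s.coverage * rng_emit.uniform(0.5, 0.95), 3))
              for _ in occ[1:]]
        covs[s.tid] = c

    return SyntheticTruth(
        config=config, table=table, models=models, annotation=annotation,
        designed_seqs=designed, support_plan=support, coverage_plan=covs,
        cis_pairs=cis_pairs,
    )


# ---------------------------------------------------------------------------
# Public operations

def generate_reference(
    config: SimulationConfig, truth: SyntheticTruth | None = None
) -> tuple[dict[str, str], list[TranscriptModel], SyntheticTruth]:
    """Genome sequences plus reference annotation with biotypes.

    The genome is random background with the designed transcript
    sequences overlaid at their exon positions (reverse-complemented on
    the minus strand), so spliced extraction recovers them exactly.
    """
    if truth is None:
        truth = plan(config)
    rng = np.random.default_rng([config.seed, _S_GENOME])
    genome_arr: dict[str, np.ndarray] = {}
    for c in range(config.n_chromosomes):
        name = f"chr{c + 1}"
        genome_arr[name] = _BASE_CODES[
            rng.integers(0, 4, size=config.chrom_length)
        ]
    from .orf import reverse_complement

    for tid, seq in truth.designed_seqs.items():
        m = truth.models[tid]
        if m.strand == "-":
            seq = reverse_complement(seq)
        pos = 0
        arr = genome_arr[m.chrom]
        for s, e in m.exons:
            arr[s:e] = np.frombuffer(seq[pos : pos + (e - s)].encode("ascii"), np.uint8)
            pos += e - s
    genome = {
        name: arr.tobytes().decode("ascii") for name, arr in sorted(genome_arr.items())
    }
    return genome, truth.annotation, truth


def emit_transcript_models(
    config: SimulationConfig, truth: SyntheticTruth
) -> list[TranscriptModel]:
    """Per-(sample, assembler) transcript model occurrences.

    The canonical occurrence keeps the designed exon coordinates and the
    highest coverage; further occurrences of multi-exon planted
    transcripts get fuzzed terminal-exon ends (same intron chain), as
    real assemblers rarely agree on transcript ends.
    """
    rng = np.random.default_rng([config.seed, _S_EMIT, 1])
    out: list[TranscriptModel] = []
    for tid in truth.table.index:
        m = truth.models[tid]
        label = truth.table.at[tid, "label"]
        occurrences = truth.support_plan[tid]
        covs = truth.coverage_plan[tid]
        for i, (sample, assembler) in enumerate(occurrences):
            exons = list(m.exons)
            if i > 0 and m.n_exons >= 2 and label != "noise":
                ds = int(rng.integers(0, 31))
                de_ = int(rng.integers(0, 31))
                (s0, e0), (sl, el) = exons[0], exons[-1]
                exons[0] = (max(0, s0 - ds), e0)
                exons[-1] = (sl, el + de_)
            out.append(TranscriptModel(
                transcript_id=f"{sample}.{assembler}.{tid}",
                gene_id=m.gene_id, chrom=m.chrom, strand=m.strand,
                exons=tuple(exons), source_assembler=assembler,
                sample_id=sample, coverage=covs[i],
            ))
    return out


def simulate_counts(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.Series]:
    """NB fragment counts per transcript x sample, plus library sizes.

    True-DE transcripts have breed means differing by the planted
    log2 fold change; breed-specific transcripts have zero mean in the
    other breed; library depth scales every mean proportionally.
    """
    rng = np.random.default_rng([config.seed, _S_COUNTS, 1])
    samples = config.samples
    lib = pd.Series(
        np.round(rng.uniform(0.9, 1.1, size=len(samples)) * config.mean_library_size),
        index=samples, name="library_size",
    )
    depth = (lib / lib.mean()).to_numpy()
    breeds = config.breeds
    counts = np.zeros((len(truth.table), len(samples)), dtype=np.int64)
    alpha = config.nb_dispersion
    for ti, tid in enumerate(truth.table.index):
        base = truth.table.at[tid, "base_mean"]
        lfc = truth.table.at[tid, "true_log2fc"]
        specific = truth.table.at[tid, "specific_breed"]
        mean_by_breed = {}
        if specific:
            for b in breeds:
                mean_by_breed[b] = base if b == specific else 0.0
        else:
            mean_by_breed[breeds[0]] = base
            mean_by_breed[breeds[1]] = base * 2.0 ** lfc
        for si, s in enumerate(samples):
            mu = mean_by_breed[config.sample_breeds[s]] * depth[si]
            if mu <= 0:
                continue
            if alpha < 1e-9:
                counts[ti, si] = rng.poisson(mu)
            else:
                n_param = 1.0 / alpha
                p_param = n_param / (n_param + mu)
                counts[ti, si] = rng.negative_binomial(n_param, p_param)
    counts_df = pd.DataFrame(counts, index=truth.table.index.copy(), columns=samples)
    return counts_df, lib


def simulate_phenotypes_and_qpcr(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Phenotype panel (3 animals/breed) and qPCR Ct table.

    Returns (per-animal phenotypes, summary table with mean/SEM/n per
    breed, per-animal Ct table for three DE genes against a reference
    gene, calibrated on the first breed).
    """
    rng = np.random.default_rng([config.seed, _S_PHENO])
    b1, b2 = config.breeds
    panel = {
        "body_weight_kg": {b1: (29.3, 1.5), b2: (47.1, 3.3)},
        "thyroid_weight_g": {b1: (3.2, 0.11), b2: (4.9, 0.66)},
        "serum_t4_nmol_l": {b1: (30.4, 1.3), b2: (37.9, 3.0)},
    }
    n_animals = 3
    animal_rows = []
    for breed in (b1, b2):
        for a in range(n_animals):
            row = {"breed": breed, "animal": f"{breed}_{a + 1}"}
            for trait, spec in panel.items():
                mean, sd = spec[breed]
                row[trait] = float(np.round(rng.normal(mean, sd), 3))
            row["thyroid_index_g_kg"] = float(
                np.round(row["thyroid_weight_g"] / row["body_weight_kg"], 4)
            )
            animal_rows.append(row)
    animals = pd.DataFrame(animal_rows)
    traits = list(panel) + ["thyroid_index_g_kg"]
    summary_rows = []
    for trait in traits:
        for breed in (b1, b2):
            vals = animals.loc[animals["breed"] == breed, trait]
            summary_rows.append({
                "trait": trait, "breed": breed,
                "mean": float(np.round(vals.mean(), 4)),
                "sem": float(np.round(vals.std(ddof=1) / np.sqrt(len(vals)), 4)),
                "n": int(len(vals)),
            })
    summary = pd.DataFrame(summary_rows, columns=["trait", "breed", "mean", "sem", "n"])

    rng_q = np.random.default_rng([config.seed, _S_QPCR])
    de_tids = [
        t for t in truth.table.index
        if truth.table.at[t, "true_de"]
        and np.isfinite(truth.table.at[t, "true_log2fc"])
        and truth.table.at[t, "label"] != "noise"
    ][:3]
    ct_rows = []
    for tid in de_tids:
        lfc = truth.table.at[tid, "true_log2fc"]
        for breed in (b1, b2):
            rel = 1.0 if breed == b1 else 2.0 ** lfc
            for a in range(n_animals):
                ct_ref = float(np.round(20.0 + rng_q.normal(0, 0.05), 3))
                ct_tgt = float(np.round(25.0 - np.log2(rel) + rng_q.normal(0, 0.05), 3))
                ct_rows.append({
                    "gene": tid, "breed": breed, "animal": f"{breed}_{a + 1}",
                    "ct_target": ct_tgt, "ct_reference": ct_ref,
                    "true_log2fc": lfc,
                })
    ct = pd.DataFrame(
        ct_rows, columns=["gene", "breed", "animal", "ct_target", "ct_reference",
                          "true_log2fc"])
    return animals, summary, ct


def emit_term_map(config: SimulationConfig, truth: SyntheticTruth,
                  n_terms: int = 30) -> pd.DataFrame:
    """Gene-to-term map over known mRNA genes with one planted DE term."""
    rng = np.random.default_rng([config.seed, _S_TERMS])
    known = truth.table[truth.table["label"] == "known_mRNA"]
    genes = list(known["gene_id"])
    rows = []
    for g in genes:
        for t in rng.permutation(n_terms)[: int(rng.integers(1, 5))]:
            rows.append({"gene": g, "term": f"T{int(t):03d}"})
    de_genes = list(known.loc[known["true_de"], "gene_id"])
    pick_de = [de_genes[int(i)] for i in rng.permutation(len(de_genes))[:10]]
    pick_bg = [genes[int(i)] for i in rng.permutation(len(genes))[:5]]
    for g in dict.fromkeys(pick_de + pick_bg):
        rows.append({"gene": g, "term": "T_PLANTED_DE"})
    return pd.DataFrame(rows, columns=["gene", "term"]).drop_duplicates(
        ignore_index=True)


def emit_homology_dbs(
    config: SimulationConfig, truth: SyntheticTruth,
    mutation_rate: float = 0.04, n_decoys: int = 5,
) -> dict[str, dict[str, str]]:
    """Reference lncRNA sets: human-like, mouse-like and a pig-database
    stand-in, built as mutated copies of planted lncRNA subsets plus
    unrelated decoy sequences."""
    rng = np.random.default_rng([config.seed, _S_HOMOL])
    lnc_ids = [t for t in truth.table.index if truth.table.at[t, "label"] == "lncRNA"]
    n = len(lnc_ids)
    perm = [lnc_ids[int(i)] for i in rng.permutation(n)]
    n_human = int(round(config.homology_fraction_human * n))
    n_both = int(round(config.homology_fraction_both * n))
    n_mouse_only = int(round(config.homology_fraction_mouse * n)) - n_both
    human_set = perm[:n_human]
    mouse_set = perm[:n_both] + perm[n_human : n_human + max(n_mouse_only, 0)]
    n_aldb = int(round(config.homology_fraction_aldb * n))
    aldb_perm = [lnc_ids[int(i)] for i in rng.permutation(n)]
    aldb_set = aldb_perm[:n_aldb]

    def mutate(seq: str) -> str:
        arr = np.array(list(seq))
        hit = rng.random(len(arr)) < mutation_rate
        repl = np.array(list("ACGT"))[rng.integers(0, 4, size=int(hit.sum()))]
        arr[hit] = repl
        return "".join(arr)

    dbs: dict[str, dict[str, str]] = {}
    for name, members, prefix in (
        ("human", human_set, "HSALNC"),
        ("mouse", mouse_set, "MMULNC"),
        ("aldb", aldb_set, "ALDB"),
    ):
        db = {
            f"{prefix}{i:05d}": mutate(truth.designed_seqs[tid])
            for i, tid in enumerate(members)
        }
        for d in range(n_decoys):
            db[f"{prefix}_DECOY{d:03d}"] = _random_bases(rng, int(rng.integers(600, 1200)))
        dbs[name] = db
    return dbs


# ---------------------------------------------------------------------------
# Bundle + file output

@dataclass
class SyntheticBundle:
    config: SimulationConfig
    truth: SyntheticTruth
    genome: dict[str, str]
    annotation: list[TranscriptModel]
    models: list[TranscriptModel]
    counts: pd.DataFrame
    library_sizes: pd.Series
    phenotype_animals: pd.DataFrame
    phenotype_summary: pd.DataFrame
    qpcr_ct: pd.DataFrame
    term_map: pd.DataFrame
    homology_dbs: dict[str, dict[str, str]]


def simulate(config: SimulationConfig) -> SyntheticBundle:
    """Run the whole generator and return all artifacts in memory."""
    truth = plan(config)
    genome, annotation, truth = generate_reference(config, truth)
    models = emit_transcript_models(config, truth)
    counts, lib = simulate_counts(config, truth)
    animals, summary, ct = simulate_phenotypes_and_qpcr(config, truth)
    term_map = emit_term_map(config, truth)
    dbs = emit_homology_dbs(config, truth)
    return SyntheticBundle(
        config=config, truth=truth, genome=genome, annotation=annotation,
        models=models, counts=counts, library_sizes=lib,
        phenotype_animals=animals, phenotype_summary=summary, qpcr_ct=ct,
        term_map=term_map, homology_dbs=dbs,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write every artifact of a simulated study to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome, outdir / "genome.fa")
    write_gtf(bundle.annotation, outdir / "annotation.gtf")
    by_source: dict[tuple[str, str], list[TranscriptModel]] = {}
    for m in bundle.models:
        by_source.setdefault((m.sample_id, m.source_assembler), []).append(m)
    for (sample, assembler), models in sorted(by_source.items()):
        write_gtf(models, outdir / f"models.{sample}.{assembler}.gtf")
    bundle.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="transcript_id")
    bundle.library_sizes.to_frame().to_csv(
        outdir / "library_sizes.tsv", sep="\t", index_label="sample")
    bundle.truth.table.to_csv(outdir / "truth.tsv", sep="\t")
    bundle.truth.cis_pairs.to_csv(outdir / "cis_truth.tsv", sep="\t", index=False)
    bundle.phenotype_animals.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    bundle.phenotype_summary.to_csv(
        outdir / "phenotype_summary.tsv", sep="\t", index=False)
    bundle.qpcr_ct.to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
    bundle.term_map.to_csv(outdir / "term_map.tsv", sep="\t", index=False)
    for name, db in sorted(bundle.homology_dbs.items()):
        write_fasta(db, outdir / f"lncdb_{name}.fa")
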