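# Methods

This note documents the models, estimators and design choices behind
`thyrolnc`, in the spirit of the methods documentation of statsmodels or
msprime: what is computed, under which assumptions, and what the bundled
simulations can and cannot show.

## Study design being modelled

The package targets a two-breed bulk RNA-seq comparison with two
sequencing samples per breed (four libraries total), each sample
assembled independently by two transcript assemblers, and a phenotype
panel of three animals per breed. Read alignment and transcript assembly
themselves are out of scope: the pipeline starts from transcript models
(GTF with a coverage attribute), a biotyped reference annotation, genome
sequences and per-transcript fragment counts.

## Transcript identity and the reliability rule

Pooled models are deduplicated by *intron chain* on a chromosome/strand
(the field convention for transcript identity, as used by Cuffcompare):
models differing only in the ends of their terminal exons are the same
structure. Single-exon models fall back to exact exon-interval identity;
they are discarded later by the structure filter regardless. The
representative model of a structure is its highest-coverage occurrence
(ties broken by smallest transcript id), and its coverage is the maximum
over occurrences — a transcript well covered in any one sample is real.
A structure is *reliable* iff observed in ≥ 2 of the four samples or by
both assemblers; "two samples" counts across breeds.

## Filter cascade semantics

Boundaries follow strict `<`: coverage < 3 drops (3.0 passes), exonic
length < 200 bp drops (200 passes), single-exon always drops.
Annotation matching is structural, not sequence-based: an intron-chain
match against an annotated mRNA labels the transcript a known mRNA; a
same-strand exonic overlap of ≥ 1 bp with a pseudogene, pre-miRNA,
tRNA, rRNA or snoRNA locus removes it. Antisense overlap with an mRNA
does **not** remove a transcript — antisense lncRNAs are a major class.
Coordinates are 0-based half-open internally; GTF conversion happens at
the I/O edge only.

## Coding-potential consensus

Four stand-in scorers expose the decision thresholds of the tools
usually combined for this task; real tool outputs can be substituted via
an external score table, which bypasses the stand-ins entirely.

* **Hexamer score** (CNCI-like): mean log-likelihood ratio of in-frame
  hexamers of the longest ORF under a coding codon-usage background
  versus the uniform background; coding iff ≥ 0. The coding background
  is a fixed pseudo-random codon weight table generated from a constant
  seed — a reproducible package calibration constant, not a fit.
* **ORF-coverage score** (CPC-like): longest-ORF fraction of transcript
  length minus 0.5; coding iff ≥ 0.
* **Domain scan** (Pfam-like): exact-peptide search of translated ORFs
  against a small bundled toy domain library, with word-search
  expectation E = (translated residues)·(library residues)·20^(−L);
  coding iff E < 10⁻³.
* **Long-ORF rule** (PhyloCSF-slot stand-in): coding iff a complete ORF
  of ≥ 100 codons exists.

An ORF here always means ATG..in-frame-stop over all six frames; ORFs
running off the transcript end do not count. The consensus is the OR of
the four flags, so adding coding evidence can only move a transcript
from candidate lncRNA toward novel mRNA (monotone).

## FPKM and expression sets

FPKM[t,s] = count · 10⁹/(L·N) with N the *genome-wide* mapped fragments
of the sample (supplied per sample, not the table's column sum, since a
large fraction of reads maps outside annotated loci). "Expressed in a
breed" means FPKM above a threshold (default 0) in at least one sample
of the breed; this reproduces the additive identity expressed = shared +
breed₁-specific + breed₂-specific exactly. "High expression" means mean
FPKM > 1000 in either breed. No effective-length or TPM correction is
attempted.

## Differential expression

The test is an exact conditional NB test in the classic edgeR style.
Counts are divided by median-of-ratios size factors; per-group totals
are rounded to integers. Under the equal-mean null with common
dispersion α, S_g ~ NB(n_g/α, p) and the law of S₁ given S₁+S₂ = s is

P(k | s) ∝ C(k + r₁ − 1, k) · C(s − k + r₂ − 1, s − k),  r_g = n_g/α,

independent of the unknown mean. The two-sided p-value sums all
conditional outcomes no more probable than the observed split; α = 0
reduces to the exact binomial split test, and an all-zero transcript
gets p = 1 by convention.

Dispersion (α in Var = μ + αμ²) is estimated by within-group method of
moments on normalised counts, pooled over the two groups, floored at 0,
and shrunk 50/50 toward a mean-trended common value. The trend uses
**bin-wise means** over ten quantile bins of log mean expression: at two
replicates per group the per-transcript MoM distribution is extremely
right-skewed, and its median underestimates the true dispersion by
roughly a third (measured on simulations), which would make the test
anti-conservative; the bin mean is close to unbiased. Even so, with
n = 2 + 2 and estimated dispersions the realised FDR of strict
BH q < 0.05 calls fluctuates around ~0.10 on the bundled simulations
(planted recall ≈ 0.99) — a fundamental small-sample effect users
should expect in the real design too.

Benjamini–Hochberg adjustment is implemented once (`de.bh_adjust`) and
reused by the enrichment module; p-values must lie in (0, 1]. log₂ fold
changes are reported as log₂((m₂+1)/(m₁+1)) on normalised means — the
pseudocount is display-only and never enters the test. Both transcript-
and gene-level (summed counts) granularities are exposed, since lncRNA
results are commonly quoted at both levels.

## Cis target prediction

Pairs are formed at gene level (union of transcript intervals per gene
id) between DE lncRNA genes and DE mRNA genes only — restricting to
DE × DE is the false-positive control of the original design. Distance
is the gap between gene-body intervals, strand-agnostic, 0 when
overlapping, with the 100 kb boundary inclusive; signed distance is
positive when the mRNA lies rightward (plus-strand convention) of the
lncRNA. Direction classes concatenate the two DE directions; the
summary reports each class plus the same/opposite rollup, which always
satisfies total = same + opposite.

## Homology

Local alignment uses exact Smith–Waterman (via Biopython's C
PairwiseAligner) under match +1, mismatch −2, gap open −5 (charged on
the first gapped position), extension −2 — no heuristic seeding in the
default path. Significance uses the Karlin–Altschul form
E = K·m·n·e^(−λS) with K = 0.711 and λ = 1.37 shipped as named
constants: a stand-in calibration for this scoring scheme, not a
re-derivation, and not expected to reproduce NCBI blastn E-values
exactly. The similarity flag threshold is E < 10⁻⁶. An optional k-mer
prefilter (k = 11, blastn's default word size; ≥ 4 shared words) skips
hopeless pairs; alignments reaching the E-threshold under this scheme
need long near-exact stretches, so at default settings the prefilter
does not change flags (asserted in tests on the bundled corpus).

## Enrichment

Default: upper-tail hypergeometric p = P(X ≥ k) per term over a
configurable universe (the expressed known-mRNA genes in the pipeline),
BH-corrected, enriched iff adjusted p < 0.05 (strict). The optional
length-bias mode fits a monotone DE-probability curve on gene length by
isotonic regression, normalises it to mean-1 weights, and replaces the
null with Wallenius' noncentral hypergeometric whose odds are the mean
weight inside the term over the mean weight outside; uniform weights
recover the central hypergeometric exactly. No GO DAG propagation or
pathway topology is modelled.

## Phenotype statistics

The two-sample t-test is computed from summaries via s/√n = SEM:
t = (m₂−m₁)/√(SEM₁²+SEM₂²) with pooled df = n₁+n₂−2. The pooled form
(not Welch) reproduces the published worked examples at n = 3 + 3.
ΔΔCt relative expression is fold = 2^(−ΔΔCt) with
ΔΔCt = (Ct_tgt−Ct_ref)_test − (Ct_tgt−Ct_ref)_calibrator.

## The synthetic-data generator

The generator's defaults *are* the study conditions: 2 breeds × 2
samples, two assemblers, 3 animals per breed for phenotypes, and a
default scale of 2,000 transcripts (800 known mRNAs, 300 novel mRNAs,
400 lncRNAs, 500 structured noise) on five 3 Mb chromosomes. Each
artifact draws from its own RNG stream keyed off the master seed, so
outputs are byte-identical for a fixed seed and adding an artifact never
perturbs the others.

Loci are placed non-overlapping (real genomes overlap; non-overlap makes
the annotation-removal truth unambiguous). Coverage is emitted directly
as a transcript attribute rather than simulated from reads, because the
cascade consumes a coverage number, not reads. Planted coding ORFs span
200–350 codons sampled from the coding codon table (half carry a toy
domain peptide); noncoding sequences are scrubbed of any six-frame ORF
reaching 80 codons and re-sampled until the whole consensus calls them
noncoding. The 80-codon margin, well under the 100-codon decision line,
is what makes perfect label recovery a meaningful end-to-end check
rather than a coin flip; stop-codon insertion can occasionally create
new ATGs at the junctions, so the scrubber is round-capped with
resampling. Noise transcripts cycle through five classes — assembler-
private singletons, coverage < 3, single-exon, < 200 bp, and overlap
with an annotated noncoding biotype — so every discard path is
exercised.

Counts are NB(μ_breed·depth_s, α) with α = 0.05 by default; true-DE
transcripts (10% plus all planted cis-pair members) differ between
breeds by ±2 log₂ units — a free parameter of the generator, not an
estimate of any real effect-size distribution. About 10% of known mRNAs
are breed-specific (zero mean in the other breed) and three are
"dominant" (Tg-like, > 1000 FPKM). Cis pairs are planted at exact
gene-body gaps of 10 kb (within the window) and 150 kb (decoys).
Homology reference sets are 4%-mutated copies of lncRNA subsets at the
study's observed similarity proportions (46.5% / 23.3% / 19.4% / 64.7%)
plus random decoys; the pipeline recovers the percentages by actually
aligning. qPCR Ct tables encode the planted fold changes under the
2^(−ΔΔCt) model with 0.05-cycle noise.

What the simulations do **not** emulate: read-level noise, positional
coverage biases, overlapping genes, isoform mixtures per locus,
assembler-specific fragmentation, GC/length biases in counting, and
lncRNA homology at realistic (much lower) sequence identity. Passing
tests therefore demonstrate correctness of the algorithms under the
stated models, not robustness to every artefact of real libraries.

## Numerical choices and degenerate inputs

Size factors fall back to 1 when no row is all-positive. Conditional
pmfs are computed in log space and normalised by logsumexp; the
"no more probable" comparison uses a 10⁻¹⁰ relative guard against ties
lost to rounding. Empty inputs return empty outputs rather than errors
wherever a set result is meaningful; malformed GTF rows, missing
coverage, unknown samples, non-positive lengths and p-values outside
(0, 1] raise with the offending record named. Problem sizes in the test
suite and acceptance script (2,000-transcript studies, 5,000-transcript
nulls, 1,000 BH vectors) were chosen as the package's own desk-scale
defaults; all complete in about a minute on one CPU.
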