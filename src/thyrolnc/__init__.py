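"""thyrolnc: lncRNA and novel-mRNA discovery for two-breed bulk RNA-seq.

The package implements, as a tested reusable pipeline, the transcript
pooling and reliability filtering, the multi-stage noncoding-candidate
filter cascade with coding-potential consensus, FPKM quantification,
negative-binomial differential expression, 100 kb cis target
prediction, homology classification, term enrichment and the phenotype
statistics of a two-breed thyroid transcriptome comparison, together
with a synthetic-data generator carrying full ground truth.
"""
from importlib import resources

import pandas as pd

from .models import (
    AlignmentHit,
    CisPair,
    ClassifiedTranscript,
    CodingVerdict,
    GroupSummary,
    SupportRecord,
    TranscriptModel,
    structure_key,
)
from .pipeline import PipelineConfig, run_pipeline
from .synthetic import SimulationConfig, SyntheticBundle, simulate

__version__ = "0.1.0"

__all__ = [
    "AlignmentHit",
    "CisPair",
    "ClassifiedTranscript",
    "CodingVerdict",
    "GroupSummary",
    "PipelineConfig",
    "SimulationConfig",
    "SupportRecord",
    "SyntheticBundle",
    "TranscriptModel",
    "load_phenotype_table",
    "run_pipeline",
    "simulate",
    "structure_key",
    "__version__",
]


def load_phenotype_table() -> pd.DataFrame:
    """Bundled phenotype summaries of the two-breed pig comparison.

    Body and thyroid measurements (mean, SEM, n = 3 castrated animals
    per breed at 120 days) for the fat-type Jinhua and lean-type
    Yorkshire breeds, used by the worked statistics examples.
    """
    path = resources.files("thyrolnc").joinpath("data/thyroid_phenotypes.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")
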