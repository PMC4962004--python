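"""Shared fixtures: simulated studies at two scales, plus small helpers."""
from __future__ import annotations

import pytest
from hypothesis import settings

from thyrolnc.synthetic import SimulationConfig, simulate

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

SMALL_SIM = dict(
    n_chromosomes=3,
    chrom_length=800_000,
    n_known_mrna=60,
    n_novel_mrna=20,
    n_lncrna=30,
    n_noise=25,
    n_noncoding_per_biotype=2,
    n_cis_pairs_within=2,
    n_cis_pairs_beyond=1,
)

TINY_SIM = dict(
    n_chromosomes=1,
    chrom_length=300_000,
    n_known_mrna=8,
    n_novel_mrna=4,
    n_lncrna=5,
    n_noise=5,
    n_noncoding_per_biotype=1,
    n_cis_pairs_within=1,
    n_cis_pairs_beyond=1,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A complete simulated study at reduced scale (140 transcripts)."""
    return simulate(SimulationConfig(seed=1, **SMALL_SIM))


@pytest.fixture(scope="session")
def default_bundle():
    """The full-scale study design (~2,000 transcripts)."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_discovery(default_bundle):
    """Merged + classified transcripts of the full-scale study."""
    from thyrolnc import discovery as dc
    from thyrolnc import merge as mg

    pooled = mg.pool_models(default_bundle.models)
    retained, dropped, _ = mg.apply_reliability_rule(pooled)
    classified, stage_counts = dc.run_discovery(
        retained, default_bundle.annotation, default_bundle.genome
    )
    return {
        "pooled": pooled,
        "retained": retained,
        "dropped": dropped,
        "classified": classified,
        "stage_counts": stage_counts,
    }
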