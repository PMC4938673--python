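"""Session-scoped simulated datasets shared across the suite.

The clean panel mirrors the target study design (96 F6 lines, 12
chromosomes, 600 scaffolds, 2.26x coverage, 1% sequencing error, no
artifacts); the artifact panel adds 2% repeat-derived SNPs and 2%
chimeric scaffolds to exercise the filters.  Seeds are fixed so every
assertion is reproducible.
"""

import pytest

import rilmap as rm
from helpers import run_pipeline_on_sim

CLEAN_SEED = 11
ARTIFACT_SEED = 7


@pytest.fixture(scope="session")
def clean_build():
    cfg = rm.SimConfig(seed=CLEAN_SEED)
    return run_pipeline_on_sim(cfg)


@pytest.fixture(scope="session")
def artifact_build():
    cfg = rm.SimConfig(
        seed=ARTIFACT_SEED, repeat_snp_fraction=0.02, chimera_fraction=0.02
    )
    return run_pipeline_on_sim(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """A light three-chromosome panel for IO and smoke tests."""
    cfg = rm.SimConfig(seed=3, n_chromosomes=3, n_scaffolds=150, n_lines=48)
    truth, reads = rm.simulate(cfg)
    return cfg, truth, reads
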