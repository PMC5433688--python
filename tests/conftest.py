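import pytest
from hypothesis import settings

from hybridweaver.pipeline import PipelineConfig, run_pipeline

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from hybridweaver.simulate import LohSpec, SimConfig, simulate_hybrid_genome


def small_config(seed: int = 7) -> SimConfig:
    """A desk-scale scenario: every event type present, seconds to run."""
    return SimConfig(
        n_genes=240,
        gene_len_codons=150,
        seed=seed,
        loh_tracts=[LohSpec(count=3, length=8)],
        n_recombinations=1,
        bir_ends=1,
        n_disablements_per_subgenome=3,
    )


@pytest.fixture(scope="session")
def small_sim():
    return simulate_hybrid_genome(small_config())


@pytest.fixture(scope="session")
def small_summary(small_sim):
    cfg = PipelineConfig(seed=7, sim=small_config())
    return run_pipeline(cfg, sim_result=small_sim)
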