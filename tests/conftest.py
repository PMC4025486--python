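"""Shared fixtures: one small synthetic dataset reused across test modules."""

import pytest

import apakit as ak


@pytest.fixture(scope="session")
def sim_ngs():
    """Default NGS-mode synthetic run: genome, models, truth, reads, truth table."""
    cfg = ak.SimConfig(seed=11)
    genome, models, truth = ak.make_genome(cfg)
    reads, read_truth = ak.simulate_reads(genome, truth, cfg)
    return cfg, genome, models, truth, reads, read_truth


@pytest.fixture(scope="session")
def pipeline_ngs(sim_ngs):
    """The full pipeline run on the shared NGS dataset."""
    cfg, genome, models, truth, reads, _ = sim_ngs
    params = ak.TailParams.for_mode("NGS")
    return ak.run_pipeline(genome, reads, params, models=models)


@pytest.fixture()
def toy_genome():
    """A tiny hand-made genome for coordinate-level unit tests."""
    #          1         2         3         4
    # 123456789012345678901234567890123456789012345678
    seq = "CCGTACGGTCGATCGGCTAGCTGGCCGTTAGCGCTTAGCGGATCGCTC"
    return {"chr1": seq * 4}  # 192 nt
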