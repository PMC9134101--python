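import pytest

from tsakit.pipeline import run_study
from tsakit.syndata import EventRequest, make_toy_genome, plant_events


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_genome(seed=1, n_chrom=2, chrom_len=50_000, n_genes=6)


@pytest.fixture(scope="session")
def planted():
    """A genome with one event of every kind plus the recorded truth."""
    genome = make_toy_genome(seed=7, n_chrom=2, chrom_len=50_000, n_genes=8)
    requests = [
        EventRequest("aeTSA_intergenic", 9),
        EventRequest("aeTSA_intron", 9),
        EventRequest("aeTSA_lncRNA", 9),
        EventRequest("aeTSA_utr", 9),
        EventRequest("aeTSA_frameshift", 9),
        EventRequest("mTSA_snv", 9),
        EventRequest("TAA_overexpressed", 9, tumor_depth=200.0, normal_depth=10.0,
                     mtec_depth=10.0),
    ]
    return plant_events(genome, requests, seed=11)


@pytest.fixture(scope="session")
def study1():
    """One full default study, shared across tests (deterministic)."""
    return run_study(1)
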