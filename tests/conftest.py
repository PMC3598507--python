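import pytest
from hypothesis import settings

from evorate.io_formats import CodonAlignment
from evorate.synthetic_data import SimulationConfig, simulate_study

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study shared across tests."""
    return simulate_study(SimulationConfig(
        n_background=60, n_essential=25, n_targets=8,
        gene_length_codons=90, seed=11))


@pytest.fixture
def make_alignment():
    def factory(rows, genome_ids=None, gene_id="g", reference_row=0):
        if genome_ids is None:
            genome_ids = [f"G{i}" for i in range(len(rows))]
        return CodonAlignment(gene_id=gene_id, genome_ids=genome_ids,
                              rows=list(rows), reference_row=reference_row)
    return factory
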