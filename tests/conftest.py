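import hypothesis
import pytest

from bowlseq.simulate import (
    SimConfig,
    TailDistribution,
    default_spikeins,
    make_gene_specs,
    random_reference,
    simulate_library,
)

hypothesis.settings.register_profile(
    "bowlseq", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("bowlseq")


@pytest.fixture(scope="session")
def small_reference():
    return random_reference(7, n_chrom=2, length=40_000)


@pytest.fixture(scope="session")
def noiseless_library(small_reference):
    """One + and one - strand gene, constant tails, no noise of any kind."""
    specs = make_gene_specs(
        small_reference,
        n_genes=2,
        site_offsets=(20,),
        usage=(1.0,),
        tail=TailDistribution("constant", 60.0, 0.0),
    )
    config = SimConfig(
        seed=11,
        genes=tuple(specs),
        reads_per_gene=10,
        non_a_rate=0.0,
        duplicate_rate=0.0,
        index_error_rate=0.0,
        cleavage_jitter_sd=0.0,
    )
    return simulate_library(config, small_reference)


@pytest.fixture(scope="session")
def noisy_library(small_reference):
    """Six genes with two sites each, all noise sources on."""
    specs = make_gene_specs(small_reference, n_genes=6)
    config = SimConfig(
        seed=13,
        genes=tuple(specs),
        spikeins=tuple(default_spikeins()),
        reads_per_gene=40,
        spike_reads=20,
    )
    return simulate_library(config, small_reference)
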