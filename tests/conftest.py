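import numpy as np
import pytest

from exocap.simulate import SimConfig, evolve_species, simulate_gene_space


@pytest.fixture(scope="session")
def small_space():
    """A small deterministic gene space shared by read-only tests."""
    config = SimConfig(seed=7, n_genes=12)
    return simulate_gene_space(config, np.random.default_rng(7))


@pytest.fixture(scope="session")
def low_divergence_species(small_space):
    rng = np.random.default_rng(11)
    return evolve_species(small_space, 0.01, 0.002, rng, species_id="low")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def exon_target_spans(space, min_length=200):
    return {
        t.target_id: (t.source_seq_id, t.span)
        for t in space.exon_targets(min_length=min_length)
    }
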