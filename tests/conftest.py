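import pytest

from phylotrx.simulate import mammal_like, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A mammal-like simulation small enough to share across tests."""
    return simulate_dataset(mammal_like(n_families=30, seed=3))


@pytest.fixture(scope="session")
def clean_dataset():
    """No duplication, loss, dropout or isoform redundancy: every family
    should sail through both ortholog-identification methods."""
    cfg = mammal_like(n_families=12, n_species=8, dup_rate=0.0,
                      loss_rate=0.0, ancient_dup_prob=0.0,
                      n_isoforms_mean=1.0, dropout_prob=0.0,
                      x_rate=0.0, indel_rate=0.0, seed=7)
    return simulate_dataset(cfg)
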