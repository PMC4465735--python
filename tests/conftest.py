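"""Shared fixtures: small synthetic datasets generated once per session."""

import numpy as np
import pytest

from anchorpipe.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def clean_dataset():
    """Six individuals, six single-copy 600 bp loci, uniform 10x coverage."""
    cfg = SimulationConfig(n_taxa=6, n_loci=6, duplicate_fraction=0.0,
                           locus_length=600, target_coverage=10.0,
                           flank_decay=0.0, error_rate=0.01, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def dup_dataset():
    """Four individuals, four root-duplicated loci (two full copies each)."""
    cfg = SimulationConfig(n_taxa=4, n_loci=4, duplicate_fraction=1.0,
                           loss_prob=0.0, secondary_duplication_prob=0.0,
                           locus_length=600, target_coverage=10.0,
                           flank_decay=0.0, error_rate=0.01, seed=17)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_assembled(clean_dataset):
    from anchorpipe.assembly import assemble_all
    return assemble_all(clean_dataset.reads_by_individual,
                        clean_dataset.references)


@pytest.fixture(scope="session")
def dup_assembled(dup_dataset):
    from anchorpipe.assembly import assemble_all
    return assemble_all(dup_dataset.reads_by_individual,
                        dup_dataset.references)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
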