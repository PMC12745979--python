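"""Shared fixtures: synthetic universes and trained desk-scale models.

Model training is the expensive step (a few minutes each on one CPU), so
trained models are session-scoped and shared between the integration and
acceptance tests that probe them.
"""

import pytest

from clmprobe.experiments import train_on_split
from clmprobe.universe import UniverseConfig, generate_universe


@pytest.fixture(scope="session")
def default_dataset():
    """The standard study universe: 4 families x 10 sequences, ~800 pairs,
    MT structure calibrated to 29% / 2.91."""
    return generate_universe(UniverseConfig(seed=0)).to_pair_dataset()


@pytest.fixture(scope="session")
def coupled_dataset():
    """Positive-control universe: families share one ancestor, so the motif
    window is the only family-discriminative signal. Sequences are longer so
    the motif is a small fraction of each sequence, as real family
    signatures are relative to full-length proteins."""
    return generate_universe(
        UniverseConfig(seed=0, motif_coupled=True, sequence_length=96)
    ).to_pair_dataset()


@pytest.fixture(scope="session")
def seq_split_model(default_dataset):
    """Sequence-partitioned model + its train/test sides (MT leakage open)."""
    return train_on_split(default_dataset, scheme="sequence", seed=0)


@pytest.fixture(scope="session")
def family_split_model(default_dataset):
    """Family-partitioned model: test families (and their scaffolds) unseen."""
    return train_on_split(default_dataset, scheme="family", seed=0)


@pytest.fixture(scope="session")
def retain0_model(default_dataset):
    """Model trained after full MT removal: train/test compounds disjoint."""
    return train_on_split(
        default_dataset, scheme="sequence", retain_mt=0.0, seed=0
    )


@pytest.fixture(scope="session")
def coupled_model(coupled_dataset):
    return train_on_split(coupled_dataset, scheme="sequence", seed=0)
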