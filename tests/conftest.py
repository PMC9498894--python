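import numpy as np
import pytest

from multiconv import ModelConfig, MPRADataset
from multiconv.simulate import SimulationSpec, consensus_motif, generate


@pytest.fixture(scope="session")
def planted_motif():
    return consensus_motif("TGACGTCA", concentration=0.9, name="planted")


@pytest.fixture(scope="session")
def tiny_dataset(planted_motif):
    """Noiseless 80-sequence dataset whose activity is one motif's max LLR."""
    spec = SimulationSpec(
        n_sequences=80,
        seq_length=30,
        planted_motifs=[(planted_motif, 1.0)],
        noise_sd=0.0,
        plant_probability=0.7,
        seed=11,
    )
    dataset, truth = generate(spec)
    return dataset, truth


@pytest.fixture
def tiny_config():
    return ModelConfig(
        n_filters=2,
        filter_length=8,
        alpha=10.0,
        dropout_rate=0.0,
        batch_size=16,
        learning_rate=0.02,
        max_epochs=5,
        early_stopping_patience=3,
        l2_factor=1e-6,
        seed=0,
    )


@pytest.fixture
def random_dataset():
    """Pure-noise dataset: background sequences with N(0, 1) activities."""
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    sequences = ["".join(bases[rng.integers(0, 4, 25)]) for _ in range(40)]
    return MPRADataset(sequences=sequences, activities=rng.normal(size=40))
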