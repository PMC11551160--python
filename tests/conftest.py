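import numpy as np
import pytest

from rna5hmc import (
    DnnConfig,
    LabeledDataset,
    RnaSequence,
    SyntheticSpec,
    generate,
)


def random_sequence(rng: np.random.Generator, length: int, sid: str = "s") -> RnaSequence:
    return RnaSequence(sid, "".join(rng.choice(list("ACGU"), size=length)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset():
    """60 sequences (30/30) with the default strong planted signal."""
    return generate(SyntheticSpec(n_pos=30, n_neg=30, seed=101))


@pytest.fixture
def fast_dnn_cfg():
    """Short-schedule training config for unit tests that only need a
    trained model, not the full 700-epoch schedule."""
    return DnnConfig(epochs=60, seed=7)


@pytest.fixture
def fasta_pair(tmp_path):
    """A small positive/negative FASTA pair on disk."""
    from rna5hmc.synthetic import write_dataset

    spec = SyntheticSpec(n_pos=20, n_neg=20, seed=303)
    return write_dataset(generate(spec), tmp_path, spec)
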