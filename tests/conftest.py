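import numpy as np
import pytest

from omicsfuse.synthetic import SyntheticSpec, generate_paired_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_paired():
    """A small, well-separated paired dataset shared by fast tests."""
    spec = SyntheticSpec(n_cells=120, n_genes=60, n_peaks=90, n_clusters=3,
                         separation=1.5, dropout_pi=0.2, seed=7)
    data, truth = generate_paired_dataset(spec)
    return data, truth, spec
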