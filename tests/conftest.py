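import numpy as np
import pytest

from neuropep import SimConfig, generate_proteome, generate_transition_report


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, n_precursors=10, n_decoys=6)


@pytest.fixture(scope="session")
def small_proteome(small_config):
    fasta, truth = generate_proteome(small_config)
    return fasta, truth


@pytest.fixture(scope="session")
def small_report(small_config, small_proteome):
    _, truth = small_proteome
    report, ms1, truth = generate_transition_report(small_config, truth)
    return report, ms1, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
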