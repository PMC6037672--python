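import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """A small planted-motif input bundle shared across CLI/pipeline tests."""
    from comotif.simulate import SimConfig, end_to_end_fixture

    outdir = tmp_path_factory.mktemp("bundle")
    config = SimConfig(seed=11, n_common=200, n_unique_1=20, n_unique_2=20,
                       n_decoy_motifs=10, chromosome_length=120_000)
    manifest = end_to_end_fixture(config, outdir)
    return outdir, config, manifest
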