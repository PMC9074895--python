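import numpy as np
import pytest

from tailscape import synthio
from tailscape.ghmm import GHMMParams


@pytest.fixture(scope="session")
def three_state() -> GHMMParams:
    return GHMMParams.default_three_state()


@pytest.fixture(scope="session")
def truth_params() -> GHMMParams:
    """Generating parameters with a realistic short initiation dwell."""
    p = GHMMParams.default_three_state().copy()
    p.transmat[0] = [0.8, 0.2, 0.0]
    p.transmat[1] = [0.0, 1 - 1 / 90, 1 / 90]
    return p


@pytest.fixture(scope="session")
def small_transcriptome():
    cfg = synthio.SynthConfig(seed=11, n_genes=60)
    return cfg, synthio.make_transcriptome(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
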