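import numpy as np
import pytest

from pbbqsar import RunConfig, run_study, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study reused by alignment/field/model tests."""
    return simulate_study(n_molecules=20, seed=11, noise_sd=0.05)


@pytest.fixture(scope="session")
def small_result(small_study):
    """Fitted pipeline on the small study (no scrambling, with design)."""
    cfg = RunConfig(n_molecules=20, n_train=15, seed=11)
    return run_study(cfg, study=small_study, scramble=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
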