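import numpy as np
import pytest

import megsurprise as ms


@pytest.fixture(scope="session")
def default_seq():
    """The default oddball block: 405 trials, deviant probability 1/3."""
    return ms.generate_oddball(405, 1.0 / 3.0, seed=7)


@pytest.fixture(scope="session")
def default_tensor(default_seq):
    """Default surprise-encoding epochs (Shannon at w=16, bump at 250 ms)."""
    return ms.simulate_epochs(default_seq, ms.SyntheticEpochSpec())


@pytest.fixture(scope="session")
def small_tensor():
    """A cheap tensor for feature/decoder plumbing tests."""
    seq = ms.generate_oddball(120, 1.0 / 3.0, seed=3)
    spec = ms.SyntheticEpochSpec(
        n_trials=120, n_channels=4, times_ms=np.linspace(-200.0, 600.0, 20),
        noise_sd=0.5, ar1_rho=0.0,
    )
    return seq, ms.simulate_epochs(seq, spec)
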