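import numpy as np
import pytest

from helpers import manual_trials


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_trial_fixture():
    """Dark forced choices, gain trials, transitions heist/heist/neutral."""
    return manual_trials(
        [
            dict(choice="dark", state="heist"),
            dict(choice="dark", state="heist"),
            dict(choice="dark", state="neutral"),
        ]
    )
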