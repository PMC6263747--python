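import numpy as np
import pytest

import symhar as sh


@pytest.fixture(scope="session")
def default_dataset():
    """The default 4-class synthetic set as (instances, labels, users)."""
    frame = sh.generate_synthetic_har(sh.default_spec(seed=42))
    return sh.frame_to_instances(frame, 250)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
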