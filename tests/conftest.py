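import numpy as np
import pytest

from anchorsearch import design, synth


@pytest.fixture
def association():
    return design.make_association_map(0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_experiment():
    """Two runs of trials, fixed seed."""
    return design.generate_experiment(2, seed=7)


@pytest.fixture
def quiet_gt():
    """Anchor-code-dominated ground truth with very low noise."""
    return synth.GroundTruth(anchor_amp=1.0, target_amp=0.0, context_amp=0.0,
                             noise_sd=1e-6, seed=3)
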