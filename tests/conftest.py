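import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pathwalker.io_formats import Sequence, SequenceSet
from pathwalker.pwm_scan import build_pwm
from pathwalker.synthetic import consensus_pwm, gen_background, random_pwm


@pytest.fixture
def dinuc_pwm():
    """A 2-position PWM with consensus AC (pseudocount 0.25)."""
    return build_pwm([[8, 0, 0, 0], [0, 8, 0, 0]], pseudocount=0.25, pwm_id="AC")


@pytest.fixture
def sharp_pwm():
    return consensus_pwm("ATGCATACG", "SHARP")


@pytest.fixture
def random_pwms():
    rng = np.random.default_rng(11)
    return [random_pwm(9, f"R{i}", seed=rng, concentration=0.7) for i in range(4)]


@pytest.fixture
def background_seqs():
    return gen_background(20, 120, seed=3)


@pytest.fixture
def tiny_seq():
    return Sequence("s1", "ACGACT")
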