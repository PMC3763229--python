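import numpy as np
import pytest

from nirspeech import (
    CONDITIONS,
    EffectSpec,
    NoiseSpec,
    generate_schedule,
    null_effects,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def full_schedule():
    """The study design: 4 runs x 25 trials, 20 per category."""
    return generate_schedule(4, 25, CONDITIONS, 20, seed=101)


@pytest.fixture
def single_run_schedule():
    """Reduced design: 1 run x 25 trials, 5 per category."""
    return generate_schedule(1, 25, CONDITIONS, 5, seed=102)


@pytest.fixture
def tiny_schedule():
    """1 run x 5 trials, each category once; onsets forced to 16..80 s."""
    return generate_schedule(1, 5, CONDITIONS, 1, seed=7)


@pytest.fixture
def quiet_noise():
    return NoiseSpec.zero()


@pytest.fixture
def flat_effects() -> EffectSpec:
    return null_effects()
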