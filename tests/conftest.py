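import numpy as np
import pytest

from ihcsynapse import PipelineConfig, get_profile, process_stack
from ihcsynapse.synth import simulate_stack


@pytest.fixture(scope="session")
def young_profile():
    return get_profile("gerbil_16k_young")


@pytest.fixture(scope="session")
def small_stack(young_profile):
    """A 3-cell young-adult stack with ground truth, shared read-only."""
    stack, truth = simulate_stack(
        young_profile, 3, rng=np.random.default_rng(42), stack_id="fixture",
        meta=dict(animal_id="Y01", age_group="young_adult", location="16kHz"),
    )
    return stack, truth


@pytest.fixture(scope="session")
def small_result(small_stack):
    stack, _ = small_stack
    return process_stack(stack, PipelineConfig())
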