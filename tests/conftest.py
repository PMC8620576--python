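import numpy as np
import pytest

from dtirank.models import ModelSpec, init_state
from dtirank.synthetic import SyntheticSpec, generate


@pytest.fixture
def tiny_data():
    """Small planted dataset shared by training/evaluation tests."""
    data, truth = generate(SyntheticSpec(n=20, m=15, k_true=3, density=0.15, seed=7))
    return data, truth


@pytest.fixture
def small_state():
    """A k=3 single-hidden-layer model with parameters pushed away from
    the ReLU kinks so finite differences are well defined."""
    spec = ModelSpec(variant="pointwise", k=3, hidden_widths=[4])
    state = init_state(spec, 6, 7, seed=11)
    rng = np.random.default_rng(5)
    for name, arr in state.param_items():
        state.set_param(name, np.asarray(arr, float) + rng.normal(0, 0.3, np.shape(arr)))
    return state
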