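import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def toy_config(activation="sigmoid", pooling="mean", seed=0, side=8):
    """A tiny net exercising every layer kind: conv → pool → dense → softmax."""
    from lungcad.network import LayerSpec, NetworkConfig

    return NetworkConfig(input_side=side, seed=seed, layers=[
        LayerSpec("conv", maps=2, kernel_size=3, activation=activation),
        LayerSpec("pool", window=2, pooling=pooling),
        LayerSpec("dense", units=4, activation="sigmoid"),
        LayerSpec("softmax_output"),
    ])


@pytest.fixture(scope="session")
def phantom_32():
    """Shared desk-scale phantom split: 400+400 train, 100+100 test, 32 px."""
    from lungcad.synthetic_data import PhantomParams, generate_dataset

    params = PhantomParams(side=32, seed=0)
    return generate_dataset(500, 500, params, seed=0)
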