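import numpy as np
import pytest
from hypothesis import settings

from eventsem.datamodel import Activity, Corpus, HyperParams
from eventsem.synthetic import GeneratorConfig, generate_corpus

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_activity():
    rng = np.random.default_rng(1)
    scenes = rng.normal(size=(10, 30))
    return Activity(id="a0", scenes=scenes, true_labels=np.zeros(10, dtype=int))


@pytest.fixture
def tiny_corpus(tiny_activity):
    rng = np.random.default_rng(2)
    other = Activity(id="a1", scenes=rng.normal(size=(8, 30)))
    return Corpus(
        activities=[tiny_activity, other],
        split={"a0": "train", "a1": "validation"},
    )


@pytest.fixture(scope="session")
def small_corpus():
    """Fast trainable corpus: 3 train / 1 validation activities."""
    return generate_corpus(GeneratorConfig(seed=2, n_train=3, n_validation=1))


@pytest.fixture
def hp():
    return HyperParams(seed=0)
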