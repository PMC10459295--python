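import numpy as np
import pytest
from hypothesis import settings

from tiradscope import net

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def micro_model():
    """Tiny 2-conv seeded model, cheap enough for numerical gradient checks."""
    return net.build_model(net.HeadConfig(backbone="micro"), seed=1)


@pytest.fixture(scope="session")
def micro_model_v2():
    return net.build_model(net.HeadConfig(version="v2", backbone="micro"), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_stack():
    """A random 3x16x16 input stack for the micro backbone."""
    r = np.random.default_rng(2)
    planes = r.random((3, 16, 16))
    planes[2] = planes[2] > 0.5
    return planes


def random_labels(n, rng):
    """Uniformly random label sets over every head axis."""
    labels = []
    for _ in range(n):
        labels.append(net.LabelSet(
            malignant=bool(rng.integers(2)),
            composition=net.V1_COMPOSITION_CLASSES[rng.integers(4)],
            echogenicity=net.ECHOGENICITY_CODE_ORDER[rng.integers(4)],
            margin=net.V1_MARGIN_CLASSES[rng.integers(4)],
            foci=frozenset(
                f for f in net.FOCI_ORDER if rng.random() < 0.3
            ),
        ))
    return labels
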