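import numpy as np
import pytest

from pollinet import GeneratorConfig, QuantNetwork, generate_study


def make_net(matrix, walk_id="w1"):
    a = np.asarray(matrix)
    plants = tuple(f"P{i}" for i in range(a.shape[0]))
    pollinators = tuple(f"B{j}" for j in range(a.shape[1]))
    return QuantNetwork(walk_id, plants, pollinators, a)


@pytest.fixture(scope="session")
def strong_study():
    """One synthetic study with a strong temperature-specialization link."""
    return generate_study(GeneratorConfig(seed=20240915))


@pytest.fixture(scope="session")
def null_study():
    """One synthetic study with no elevational structure."""
    return generate_study(GeneratorConfig.null(seed=20240916))
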